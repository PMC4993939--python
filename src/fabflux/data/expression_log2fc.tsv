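locus_tag	gene	log2fc
Eab7_2059	accA	0.4562
Eab7_0870	accB	-0.05773
Eab7_0871	accC	-0.5623
Eab7_2060	accD	-0.2811
Eab7_1760	fabD	0.9448
Eab7_1911	fabH1	0.8512
Eab7_1910	fabF	0.6942
Eab7_1895	fabG	0.8523
Eab7_2463	fabZ	0.12902
Eab7_1885	fabI	0.2969
Eab7_2235		1.3768
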