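# Methods

## The model

The package models de-novo fatty-acid synthesis in *Exiguobacterium
antarcticum* B7 as a stoichiometric network at steady state: a matrix
**S** (metabolites × reactions, signed rational coefficients, negative =
consumed) with flux vectors constrained by `S·v = 0`, reversibility signs
and capacity bounds.  Fluxes are dimensionless percentages of the
acetyl-CoA input; no kinetic parameters enter anywhere.

The enzymatic content follows the curated annotation of the organism:

* **Initiation.**  Acetyl-CoA carboxylase (AccABCD complex, EC 6.4.1.2)
  makes malonyl-CoA (R1, irreversible on thermodynamic grounds); FabD
  (R2) moves malonyl onto the acyl carrier protein; FabH1 (R3) condenses
  acetyl-CoA with malonyl-ACP into acetoacetyl-ACP.  The literal FabF C2
  condensation from acetyl-ACP is retained in the inventory (R4) but has
  no acetyl-ACP source, so it is structurally blocked; see
  "Reconstruction choices".
* **Elongation.**  Each round is condensation (FabF, irreversible),
  NADPH/H⁺ ketoreduction (FabG), dehydration (FabZ, releases H₂O) and
  NADH/H⁺ enoyl reduction (FabI), all three reductive steps reversible.
  Six rounds take the chain C4 → C16; the generator enforces the +2-carbon
  invariant per round with one CO₂ released.
* **Termination.**  The acyl-ACP desaturase (locus Eab7_2235, EC
  1.14.19.2) converts hexadecanoyl-ACP to hexadecenoyl-ACP using O₂ and a
  generic reduced electron acceptor; thioesterases release hexadecenoate
  (the product), octanoate and tetradecanoate.  Thioester hydrolysis
  liberates the carboxylate proton.
* **Boundary.**  Cytoplasm and extracellular compartment; acetyl-CoA
  enters through an extracellular pool (supply R37, uptake R39), the
  product leaves through R41/R42, O₂ and CO₂ cross the boundary through
  their extracellular species, and every cofactor pool
  (ATP/ADP/Pi/HCO₃⁻/NAD(P)(H)/H⁺/H₂O/CoA/acceptor) has a one-sided
  exchange.  Excess acetyl-CoA drains to energy metabolism (R40).

## Reconstruction choices

The published description fixes the reconstruction's end points — 54
metabolites × 59 reactions, an optimal product yield of 7.69 per 100
acetyl-CoA, 13 elementary modes of which 4 produce hexadecenoate with
yields 1 (modes entering at R2) and 0.142857 (modes entering at R1,
normalized to R1 = 1) — but not the complete reaction list, which was
distributed as supplementary spreadsheets.  The inventory here was
therefore reconciled against those printed outputs, and the following
choices are deliberate parts of that reconciliation:

* **Proton bookkeeping sets the optimum.**  One product requires 14 H⁺
  across the 7 FabG and 7 FabI steps and returns 1 H⁺ on hydrolysis: a
  net 13 H⁺ per hexadecenoate.  With every exchange capped at 100, the
  proton supply saturates before the carbon supply (8 acetyl-CoA per
  product would allow 12.5), reproducing 100/13 = 7.69.  Carbon alone
  cannot produce a 13-per-product stoichiometry in this pathway.
* **Malonyl-CoA acquisition (R43).**  Producing modes that contain FabD
  but not the carboxylase require a second malonyl-CoA source.  The
  import is modelled as energized (consuming one cytoplasmic H⁺ per
  molecule), which keeps the carboxylase route strictly optimal in the
  reference LP — without the proton cost the acc flux would be degenerate
  and unreproducible.
* **Two NADPH supplies.**  NADPH arrives either directly or from NADH via
  a soluble transhydrogenase (R33).  This doubling is what separates the
  paired elementary modes within each entry class.
* **Short-chain release sites.**  Thioesterase releases at C8 and C14
  give the network the short-chain escape routes that the cold-adaptation
  phenotype implies; the released acids leave the modelled system at the
  boundary.
* **Blocked C2 condensation.**  An independent acetyl-ACP source would
  open spurious acetyl-CoA-generating cycles through the reversible FabH1
  (verified computationally: +6 spurious modes), so acetyl-ACP is kept
  without a producer and ACP is a conserved internal pool with no
  exchange reaction.
* **Reversibility partition.**  Irreversible: carboxylase, all FabF
  condensations, the desaturase, thioesterases, transhydrogenase, and all
  exchanges/transports.  Reversible: FabD, FabH1, FabG, FabZ, FabI (21
  instances).

The builder raises on any deviation from 54 × 59, treating it as an
inventory regression.

## Flux balance analysis

`solve_fba` solves the LP with scipy's HiGHS backend at feasibility
tolerances of 1e-10, so returned vectors satisfy `‖S·v‖∞ ≤ 1e-9` with
margin.  Metabolic LPs have degenerate optima; only the objective value is
treated as contract-stable.  For reproducible flux tables a parsimonious
second stage minimizes Σ|v| with the objective pinned at its optimum,
selecting the least-total-flux vertex deterministically.  Statuses
(`optimal`/`infeasible`/`unbounded`) are always returned, never raised
silently.  Units: percent of the fixed acetyl-CoA input per unit time per
unit cell mass; the flux cap of 100 is the study's convergence convention,
not a physiological estimate.

## Elementary flux modes

Reversible reactions are split into irreversible pairs; the flux cone of
the split network is pointed and its extreme rays are exactly its EFMs.
The double-description tableau starts from the orthant generators and
imposes one steady-state row at a time (row order chosen greedily to
minimize the positive×negative combination count), with the standard
combinatorial adjacency test on zero-sets (bitmask containment).  All
arithmetic is over arbitrary-precision integers; candidate rays are
reduced by their gcd.  After the last row, split pairs are recombined by
subtraction, all-zero futile two-cycles discarded, modes with fully
reversible support canonicalized to a positive leading coefficient, and
the set ordered lexicographically by support.  Stored coefficients are
the smallest integers; `normalize_mode` rescales to any reference
reaction for yield reporting.  An intermediate-ray cap (default 200 000)
aborts with `EnumerationLimitError` beyond the intended network scale
(~60 reactions; genome-scale enumeration is out of scope).

The brute-force oracle enumerates support subsets of the split network in
increasing size with superset pruning, accepting a subset iff its
restricted matrix has a one-dimensional nullspace whose generator is
nonzero throughout and of uniform sign.  It shares only the splitting
code with the tableau path and is the equivalence reference on toy
networks (≤ ~20 split reactions).

## Expression integration

Scores per reaction: minimum subunit log₂FC for AND-combined genes
(a complex is limited by its scarcest subunit), maximum for OR-combined
isozymes; unmeasured reactions are unscored and untouched.
`apply_expression_bounds` multiplies bound magnitudes by
`min(2^score, scale_cap)` with `scale_cap ≥ 1` (default 1: pure
down-regulation).  For `transcriptome_fba` the scores are first shifted
by the maximum observed log₂FC, anchoring capacities to the most
cold-induced enzyme (the desaturase, +1.3768).  This normalized variant
is the package's design choice: the raw 2^score factors (e.g. 0.68 for
the carboxylase complex, whose score is the accC subunit's −0.5623) all
sit above the plain-FBA fluxes and would constrain nothing, whereas the
anchored mapping caps the carboxylase at 26.1 and reproduces the
qualitative cold phenotype — carboxylase flux falls from 53.8 to 26.1,
the product optimum from 7.69 to 6.30, and every last-round elongation
flux drops strictly.  The mapping is pluggable (`factor=` callable) so
absolute capping or on/off discretization can be substituted.  Because
the published analysis does not state its log₂FC-to-constraint mapping,
these transcriptome results are directional claims, not numeric targets.

## Synthetic data

The toy generators exist to give every algorithm inputs with
independently known answers: chains (one mode, uniform flux), k-fold
parallel motifs (k modes), and seeded sparse random networks
(coefficients in {−2, −1, 1, 2}, ≤ 12 reactions so the brute-force oracle
stays exhaustive).  Random networks are built around a guaranteed
uptake→secretion backbone, so draws are never vacuously dead; draws that
still admit no nonzero steady flux are resampled a bounded number of
times and then flagged degenerate.  These networks exercise the
algorithms' combinatorics, not the biology: they have no carbon
annotation, no GPRs and no compartment structure beyond the boundary, so
passing them says nothing about the curated inventory itself — that is
what the reconstruction tests and the printed-output checks are for.

## Numerical and degenerate-input policy

Exact rational arithmetic everywhere except inside the LP solver; floats
appear only in bounds, LP solutions and report tables.  Zero
stoichiometric coefficients are never stored; empty networks yield 0×0
matrices and empty reports; an empty mode enumeration input is an error.
Carbon validation exempts exchange-like reactions and reactions without
carbon-annotated species, so toy networks validate trivially.

## Known limitations

* The curated inventory is a reconciliation, not a transcription of the
  original supplementary files; where those files disagree with this
  reconstruction, the printed end points above are the quantities this
  package warrants.  Importing a converted supplementary table through
  `read_reaction_table` overrides the built-in inventory.
* Mode index labels (e.g. "modes 2, 5, 8, 11") depend on the original
  toolchain's output order and are not reproducible; the package asserts
  counts, entry classes and yields instead.
* No flux variability analysis, no biomass objective, no genome-scale
  enumeration, no kinetic or regulatory modelling.
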