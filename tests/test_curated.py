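"""The curated fatty-acid network: composition, reversibility, templates."""
from fractions import Fraction

import pytest

from fabflux import (
    build_curated_network,
    generate_elongation_round,
    reductive_half_cycle,
    stoichiometric_matrix,
    validate_carbon_balance,
)
from fabflux.curated import ACC_UPTAKE_ID, PRODUCT_SECRETION_ID


def test_dimensions_54_metabolites_59_reactions(curated):
    assert curated.shape == (54, 59)
    assert stoichiometric_matrix(curated).shape == (54, 59)


def test_construction_is_deterministic(curated):
    again = build_curated_network()
    assert again == curated
    assert again.metabolite_ids() == curated.metabolite_ids()
    assert [r.stoichiometry for r in again.reactions] == [
        r.stoichiometry for r in curated.reactions
    ]


def test_two_compartments_present(curated):
    comps = {m.compartment for m in curated.metabolites}
    assert comps == {"cytoplasm", "extracellular"}


class TestTemplateReactions:
    """The curated reactions printed in the study's summary table."""

    def test_acetyl_coa_carboxylase_equation(self, curated):
        acc = curated.reaction("R1")
        assert acc.ec_number == "6.4.1.2"
        assert not acc.reversible
        assert acc.stoichiometry == {
            "atp": -1, "accoa": -1, "hco3": -1, "adp": 1, "pi": 1, "malcoa": 1,
        }
        assert set(acc.genes) == {"Eab7_2059", "Eab7_0870", "Eab7_0871", "Eab7_2060"}
        assert acc.gene_rule == "and"

    def test_fabd_transacylase(self, curated):
        fabd = curated.reaction("R2")
        assert fabd.reversible
        assert fabd.stoichiometry == {"malcoa": -1, "acp": -1, "coa": 1, "malacp": 1}
        assert fabd.genes == ("Eab7_1760",)

    def test_fabh1_initiation(self, curated):
        r3 = curated.reaction("R3")
        assert r3.reversible
        assert r3.stoichiometry == {
            "accoa": -1, "malacp": -1, "oxo4_acp": 1, "coa": 1, "co2": 1,
        }

    def test_fabf_c2_condensation_literal(self, curated):
        r4 = curated.reaction("R4")
        assert not r4.reversible
        assert r4.stoichiometry == {
            "acacp": -1, "malacp": -1, "oxo4_acp": 1, "co2": 1, "acp": 1,
        }

    def test_c4_reduction_dehydration_enoyl_equations(self, curated):
        fabg = curated.reaction("R5")
        assert fabg.stoichiometry == {
            "oxo4_acp": -1, "nadph": -1, "h": -1, "hydroxy4_acp": 1, "nadp": 1,
        }
        fabz = curated.reaction("R6")
        assert fabz.stoichiometry == {"hydroxy4_acp": -1, "enoyl4_acp": 1, "h2o": 1}
        fabi = curated.reaction("R7")
        assert fabi.stoichiometry == {
            "enoyl4_acp": -1, "nadh": -1, "h": -1, "acyl4_acp": 1, "nad": 1,
        }
        assert all(r.reversible for r in (fabg, fabz, fabi))

    def test_desaturase_equation(self, curated):
        des = curated.reaction("R32")
        assert des.ec_number == "1.14.19.2"
        assert not des.reversible
        assert des.stoichiometry == {
            "acyl16_acp": -1, "acceptor_red": -1, "o2": -1,
            "hexadecenoyl_acp": 1, "acceptor_ox": 1, "h2o": 2,
        }
        assert des.genes == ("Eab7_2235",)


class TestReversibilityPartition:
    def test_irreversible_set(self, curated):
        irrev_enzymatic = [
            r for r in curated.reactions
            if not r.reversible and r.subsystem not in ("exchange", "transport", "release", "cofactor")
        ]
        ids = {r.id for r in irrev_enzymatic}
        # carboxylase, the FabF condensations (C2 + six rounds), desaturase
        assert ids == {"R1", "R4", "R8", "R12", "R16", "R20", "R24", "R28", "R32"}

    def test_fabd_family_reversible(self, curated):
        for rid in ("R2", "R3", "R5", "R6", "R7"):
            assert curated.reaction(rid).reversible

    def test_exchanges_irreversible(self, curated):
        for r in curated.reactions:
            if r.subsystem in ("exchange", "transport"):
                assert not r.reversible, r.id


class TestElongationExpansion:
    def test_six_rounds_give_24_reactions(self):
        rounds = [generate_elongation_round(n) for n in range(4, 16, 2)]
        assert sum(len(r) for r in rounds) == 24

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12, 14])
    def test_round_adds_two_carbons_and_releases_co2(self, n):
        cond, fabg, fabz, fabi = generate_elongation_round(n)
        assert cond.stoichiometry[f"acyl{n}_acp"] == -1
        assert cond.stoichiometry[f"oxo{n+2}_acp"] == 1
        assert cond.stoichiometry["co2"] == 1
        assert fabg.stoichiometry["nadph"] == -1 and fabg.stoichiometry["h"] == -1
        assert fabi.stoichiometry["nadh"] == -1 and fabi.stoichiometry["h"] == -1
        # net effect over the four reactions: acyl(Cn) -> acyl(Cn+2)
        net: dict[str, Fraction] = {}
        for r in (cond, fabg, fabz, fabi):
            for m, c in r.stoichiometry.items():
                net[m] = net.get(m, Fraction(0)) + c
        assert net[f"acyl{n}_acp"] == -1 and net[f"acyl{n+2}_acp"] == 1

    @pytest.mark.parametrize("bad", [3, 5, 2, 16, 0, -4])
    def test_invalid_chain_lengths_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_elongation_round(bad)

    def test_half_cycle_range_wider_than_round_range(self):
        assert len(reductive_half_cycle(16)) == 3
        with pytest.raises(ValueError):
            reductive_half_cycle(18)


class TestBoundaryStructure:
    def test_unique_acetyl_coa_uptake_and_product_secretion(self, curated):
        uptake = [
            r for r in curated.reactions
            if r.stoichiometry.get("accoa") == 1 and r.subsystem in ("exchange", "transport")
        ]
        assert [r.id for r in uptake] == [ACC_UPTAKE_ID]
        secretion = [
            r for r in curated.reactions if r.stoichiometry.get("hexadecenoate") == -1
        ]
        assert [r.id for r in secretion] == [PRODUCT_SECRETION_ID]

    def test_acyl_intermediates_have_even_carbon_counts(self, curated):
        for m in curated.metabolites:
            if m.id.endswith("_acp") and m.id not in ("malacp", "acacp"):
                pass
        for kind in ("oxo", "hydroxy", "enoyl", "acyl"):
            for n in range(4, 18, 2):
                met = curated.metabolite(f"{kind}{n}_acp")
                assert met.carbon_count == n and n % 2 == 0

    def test_elongation_reactions_carbon_balanced(self, curated):
        report = validate_carbon_balance(curated)
        assert report.ok
        elong = [r.id for r in curated.reactions if r.subsystem == "elongation"]
        assert elong and all(report.imbalances[rid] == 0 for rid in elong)

    def test_dimension_regression_guard(self, monkeypatch):
        import fabflux.curated as cur

        monkeypatch.setattr(cur, "EXPECTED_SHAPE", (53, 59))
        with pytest.raises(RuntimeError, match="regression"):
            cur.build_curated_network()
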