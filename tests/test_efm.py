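"""Elementary flux modes: enumeration, oracle equivalence, normalization."""
from fractions import Fraction

import pytest

from fabflux import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    brute_force_elementary_modes,
    enumerate_elementary_modes,
    make_chain,
    make_parallel,
    make_random,
    modes_producing,
    normalize_mode,
    stoichiometric_matrix,
)
from fabflux.efm import EnumerationLimitError

from conftest import emset_key


def _steady_state_exact(network, mode):
    S = stoichiometric_matrix(network)
    rids = network.reaction_ids()
    for i in range(S.shape[0]):
        total = sum(S[i, j] * mode.coefficient(rids[j]) for j in range(S.shape[1]))
        assert total == 0


class TestToyNetworks:
    def test_chain_has_single_uniform_mode(self):
        ems = enumerate_elementary_modes(make_chain(2))
        assert len(ems) == 1
        coeffs = set(ems[0].coefficients.values())
        assert coeffs == {Fraction(1)}

    def test_diamond_has_two_modes_both_secreting(self):
        net = make_parallel(2)
        ems = enumerate_elementary_modes(net)
        assert len(ems) == 2
        assert len(modes_producing(ems, "secretion")) == 2

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_parallel_motif_has_one_mode_per_branch(self, k):
        ems = enumerate_elementary_modes(make_parallel(k))
        assert len(ems) == k

    def test_reversible_cycle_collapses_to_no_spurious_modes(self):
        # A <-> B via two antiparallel *distinct* reactions is a genuine
        # futile cycle; the split pair of a single reversible reaction is not.
        net = MetabolicNetwork()
        net.add_metabolite(Metabolite("A"))
        net.add_metabolite(Metabolite("B"))
        net.add_reaction(Reaction("r", stoichiometry={"A": -1, "B": 1}, reversible=True))
        with_single = enumerate_elementary_modes(net)
        assert len(with_single) == 0
        net.add_reaction(Reaction("back", stoichiometry={"B": -1, "A": 1}))
        with_pair = enumerate_elementary_modes(net)
        assert len(with_pair) == 1
        assert with_pair[0].support == {"r", "back"}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            enumerate_elementary_modes(MetabolicNetwork())

    def test_mode_count_cap_enforced(self):
        with pytest.raises(EnumerationLimitError):
            enumerate_elementary_modes(make_parallel(8), max_modes=4)


class TestExactInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_modes_satisfy_steady_state_and_signs_exactly(self, seed):
        net = make_random(4, 8, 0.3, seed=seed)
        ems = enumerate_elementary_modes(net)
        for mode in ems:
            _steady_state_exact(net, mode)
            for r in net.reactions:
                if not r.reversible:
                    assert mode.coefficient(r.id) >= 0

    @pytest.mark.parametrize("seed", range(10))
    def test_no_support_contains_another(self, seed):
        net = make_random(4, 8, 0.3, seed=seed)
        supports = enumerate_elementary_modes(net).supports()
        for a in supports:
            for b in supports:
                if a is not b:
                    assert not (a < b)

    def test_canonical_order_and_scaling_deterministic(self):
        net = make_random(5, 9, 0.4, seed=11)
        a = enumerate_elementary_modes(net)
        b = enumerate_elementary_modes(net)
        assert [m.coefficients for m in a] == [m.coefficients for m in b]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_tableau_equals_brute_force_on_random_networks(self, seed):
        net = make_random(4, 8, 0.3, seed=seed)
        assert emset_key(enumerate_elementary_modes(net)) == emset_key(
            brute_force_elementary_modes(net)
        )

    def test_brute_force_size_guard(self):
        net = make_parallel(25)
        with pytest.raises(ValueError, match="split"):
            brute_force_elementary_modes(net)


class TestQueriesAndNormalization:
    def test_modes_producing_unknown_reaction_rejected(self, curated_ems):
        with pytest.raises(KeyError):
            modes_producing(curated_ems, "R999")

    def test_reaction_absent_from_all_supports_gives_empty_set(self, curated_ems):
        # the literal C2 condensation is structurally blocked
        assert len(modes_producing(curated_ems, "R4")) == 0

    def test_normalize_sets_reference_to_one(self, curated_ems):
        mode = modes_producing(curated_ems, "R41")[0]
        normed = normalize_mode(mode, "R41")
        assert normed.coefficient("R41") == 1

    def test_normalize_is_idempotent(self, curated_ems):
        mode = modes_producing(curated_ems, "R41")[0]
        once = normalize_mode(mode, "R41")
        twice = normalize_mode(once, "R41")
        assert twice is once or twice.coefficients == once.coefficients

    def test_normalize_zero_reference_flags_failure(self, curated_ems):
        mode = modes_producing(curated_ems, "R41")[0]
        # R4 is blocked, so its coefficient is zero in every mode
        out = normalize_mode(mode, "R4")
        assert out.normalization_failed
        assert out.coefficients == mode.coefficients

    def test_scaling_invariance_of_renormalization(self, curated_ems):
        mode = modes_producing(curated_ems, "R41")[0]
        via_r2 = normalize_mode(mode, "R2")
        back = normalize_mode(normalize_mode(via_r2, "R41"), "R2")
        assert back.coefficients == via_r2.coefficients


class TestCuratedCensus:
    def test_thirteen_modes(self, curated_ems):
        assert len(curated_ems) == 13

    def test_no_two_modes_share_a_support(self, curated_ems):
        supports = curated_ems.supports()
        assert len(set(supports)) == len(supports)

    def test_producing_modes_import_carbon(self, curated_ems):
        producing = modes_producing(curated_ems, "R41")
        union = frozenset().union(*(m.support for m in producing))
        assert "R39" in union or "R2" in union

    def test_exact_steady_state_on_curated_modes(self, curated, curated_ems):
        for mode in curated_ems:
            _steady_state_exact(curated, mode)
            for r in curated.reactions:
                if not r.reversible:
                    assert mode.coefficient(r.id) >= 0
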