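"""Flux balance analysis: LP correctness, bounds, degeneracy handling."""
import numpy as np
import pytest

from fabflux import (
    FBAProblem,
    FluxBalanceModel,
    MetabolicNetwork,
    Reaction,
    default_bounds,
    flux_report,
    make_chain,
    make_parallel,
    make_random,
    solve_fba,
)


class TestDefaultBounds:
    def test_irreversible_gets_0_100(self):
        r = Reaction("r", stoichiometry={"A": -1})
        assert default_bounds(r) == (0.0, 100.0)

    def test_reversible_gets_symmetric(self):
        r = Reaction("r", stoichiometry={"A": -1}, reversible=True)
        assert default_bounds(r) == (-100.0, 100.0)

    def test_explicit_bounds_win(self):
        r = Reaction("r", stoichiometry={"A": -1}, lower_bound=5.0, upper_bound=42.0)
        assert default_bounds(r) == (5.0, 42.0)


class TestProblemValidation:
    def test_unknown_objective_rejected(self):
        with pytest.raises(KeyError):
            FBAProblem(make_chain(2), "nope")

    def test_fixed_flux_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            FBAProblem(make_chain(2), "secretion", {"uptake": 250.0})


class TestToyNetworks:
    def test_chain_carries_uptake_to_secretion(self):
        net = make_chain(2)
        dist = solve_fba(FBAProblem(net, "secretion", {"uptake": 100.0}))
        assert dist.status == "optimal"
        assert dist.objective_value == pytest.approx(100.0)
        assert all(v == pytest.approx(100.0) for v in dist.fluxes.values())

    def test_zero_input_forces_zero_output(self):
        net = make_chain(3)
        dist = solve_fba(FBAProblem(net, "secretion", {"uptake": 0.0}))
        assert dist.status == "optimal"
        assert dist.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_parallel_branches_sum_to_bottleneck(self):
        net = make_parallel(3)
        dist = solve_fba(FBAProblem(net, "secretion", {"uptake": 100.0}))
        assert dist.objective_value == pytest.approx(100.0)

    def test_objective_monotone_in_upper_bound(self):
        # LP monotonicity: relaxing one bound can never lower the optimum.
        for seed in range(8):
            net = make_random(4, 8, 0.25, seed=seed)
            if net.metadata.get("degenerate"):
                continue
            base = solve_fba(FBAProblem(net, "secretion"), parsimonious=False)
            if base.status != "optimal":
                continue
            relaxed = net.copy()
            relaxed.reaction("uptake").upper_bound = 200.0
            more = solve_fba(FBAProblem(relaxed, "secretion"), parsimonious=False)
            assert more.objective_value >= base.objective_value - 1e-9

    def test_blocked_objective_gives_zero(self):
        net = make_chain(2)
        # cutting the chain isolates the secretion reaction
        cut = MetabolicNetwork(
            metabolites=list(net.metabolites),
            reactions=[r for r in net.reactions if r.id != "step1"],
        )
        dist = solve_fba(FBAProblem(cut, "secretion", {"uptake": 0.0}))
        assert dist.status == "optimal"
        assert dist.objective_value == pytest.approx(0.0, abs=1e-9)


class TestSteadyState:
    def test_residual_small_on_random_networks(self):
        for seed in range(20):
            net = make_random(4, 7, 0.3, seed=seed)
            if net.metadata.get("degenerate"):
                continue
            dist = solve_fba(FBAProblem(net, "secretion", {"uptake": 50.0}))
            if dist.status == "optimal":
                assert dist.steady_state_residual(net) <= 1e-9

    def test_reference_solution_is_steady_and_within_bounds(self, curated, reference_fba):
        assert reference_fba.steady_state_residual() <= 1e-9
        for r in curated.reactions:
            lb, ub = default_bounds(r)
            if r.id == "R39":
                lb = ub = 100.0
            v = reference_fba.fluxes[r.id]
            assert lb - 1e-9 <= v <= ub + 1e-9


class TestReferenceProblem:
    def test_independent_formulation_agrees(self, curated, reference_fba):
        """Cross-check the optimum against cobrapy on the exported SBML."""
        cobra = pytest.importorskip("cobra")
        from fabflux import write_sbml

        import os, tempfile

        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "net.xml")
            write_sbml(curated, path)
            model = cobra.io.read_sbml_model(path)
        model.reactions.get_by_id("R39").bounds = (100.0, 100.0)
        model.objective = "R41"
        sol = model.optimize()
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(
            reference_fba.objective_value, rel=1e-7
        )

    def test_parsimonious_and_plain_objectives_match(self, curated):
        model = FluxBalanceModel.reference_problem(curated)
        a = model.fit(parsimonious=True)
        b = model.fit(parsimonious=False)
        assert a.objective_value == pytest.approx(b.objective_value, rel=1e-9)

    def test_acc_route_preferred_over_malonyl_import(self, reference_fba):
        # the energized import wastes protons, so the carboxylase carries
        # all malonyl flux at the optimum
        assert reference_fba.fluxes["R43"] == pytest.approx(0.0, abs=1e-6)
        assert reference_fba.fluxes["R1"] > 50.0


class TestFluxReport:
    def test_report_ordered_and_signed(self):
        net = make_chain(2)
        dist = solve_fba(FBAProblem(net, "secretion", {"uptake": 100.0}))
        frame = flux_report(dist, net)
        assert list(frame.reaction) == [r.id for r in net.reactions]
        assert len(frame) == 4
        assert (frame.flux > 0).all()

    def test_reversible_flux_keeps_sign(self):
        net = MetabolicNetwork()
        from fabflux import Metabolite

        net.add_metabolite(Metabolite("A"))
        net.add_reaction(Reaction("in", stoichiometry={"A": 1}, subsystem="exchange"))
        net.add_reaction(
            Reaction("rev_out", stoichiometry={"A": 1}, reversible=True, subsystem="exchange")
        )
        dist = solve_fba(FBAProblem(net, "in", {"in": 5.0}))
        frame = flux_report(dist, net)
        assert frame.set_index("reaction").loc["rev_out", "flux"] == pytest.approx(-5.0)

    def test_non_optimal_report_rejected(self):
        from fabflux.fba import FluxDistribution

        with pytest.raises(ValueError):
            flux_report(FluxDistribution({}, None, "infeasible"), make_chain(1))

    def test_summary_mentions_objective(self, reference_fba):
        text = reference_fba.summary()
        assert "R41" in text and "optimal" in text
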