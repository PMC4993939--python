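"""Flux balance analysis: the steady-state linear program and its results.

The LP is ``maximize c'v subject to S v = 0, lb <= v <= ub`` with the
default capacity constraints of the study: fluxes expressed in percent of
the acetyl-CoA input, bounds [0, 100] for irreversible and [-100, 100] for
reversible reactions, and the uptake reaction fixed by an equality.

Solved with scipy's HiGHS backend.  Because optimal vertices of metabolic
LPs are routinely degenerate, only the objective value is contract-stable;
for reproducible flux vectors a parsimonious second stage (minimize total
absolute flux at the optimal objective) is applied by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .core import MetabolicNetwork, Reaction, stoichiometric_matrix

__all__ = [
    "DEFAULT_FLUX_CAP",
    "FBAProblem",
    "FluxDistribution",
    "default_bounds",
    "solve_fba",
    "flux_report",
    "FluxBalanceModel",
    "FBAResults",
]

DEFAULT_FLUX_CAP = 100.0

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


def default_bounds(reaction: Reaction, cap: float = DEFAULT_FLUX_CAP) -> tuple[float, float]:
    """Flux bounds for a reaction: explicit bounds win, else the convention
    [0, cap] for irreversible and [-cap, cap] for reversible reactions."""
    lb = reaction.lower_bound
    ub = reaction.upper_bound
    if lb is None:
        lb = -cap if reaction.reversible else 0.0
    if ub is None:
        ub = cap
    return (float(lb), float(ub))


@dataclass
class FBAProblem:
    """A flux-balance LP: network, objective reaction, fixed fluxes.

    ``fixed_fluxes`` are equality constraints (lb = ub = value), used for
    the acetyl-CoA input which the study pins at 100.
    """

    network: MetabolicNetwork
    objective_reaction: str
    fixed_fluxes: Mapping[str, float] = field(default_factory=dict)
    flux_cap: float = DEFAULT_FLUX_CAP

    def __post_init__(self) -> None:
        if not self.network.has_reaction(self.objective_reaction):
            raise KeyError(f"objective reaction {self.objective_reaction!r} not in network")
        for rid, value in self.fixed_fluxes.items():
            if not self.network.has_reaction(rid):
                raise KeyError(f"fixed-flux reaction {rid!r} not in network")
            lb, ub = default_bounds(self.network.reaction(rid), self.flux_cap)
            if not lb <= value <= ub:
                raise ValueError(
                    f"fixed flux {value} for {rid} outside its bounds [{lb}, {ub}]"
                )

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for rxn in self.network.reactions:
            if rxn.id in self.fixed_fluxes:
                v = float(self.fixed_fluxes[rxn.id])
                out.append((v, v))
            else:
                out.append(default_bounds(rxn, self.flux_cap))
        return out


@dataclass
class FluxDistribution:
    """One flux value per reaction plus the attained objective value."""

    fluxes: dict[str, float]
    objective_value: Optional[float]
    status: str
    objective_reaction: Optional[str] = None

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def steady_state_residual(self, network: MetabolicNetwork) -> float:
        """Max-norm of S v for this flux vector."""
        S = stoichiometric_matrix(network, dtype="float")
        v = np.array([self.fluxes[r.id] for r in network.reactions])
        if S.size == 0:
            return 0.0
        return float(np.max(np.abs(S @ v)))


# steady-state residuals are asserted to 1e-9, so run HiGHS well below that
_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


def _solve_lp(c, A, bounds):
    return linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                   method="highs", options=dict(_HIGHS_OPTIONS))


def solve_fba(problem: FBAProblem, parsimonious: bool = True) -> FluxDistribution:
    """Maximize the objective flux subject to steady state and bounds.

    Returns a :class:`FluxDistribution` with status ``optimal``,
    ``infeasible`` or ``unbounded``.  With ``parsimonious=True`` (default) a
    second LP minimizes the total absolute flux at the optimal objective
    value, which resolves degenerate alternate optima deterministically;
    the objective value itself is identical either way.
    """
    net = problem.network
    n = len(net.reactions)
    if n == 0:
        return FluxDistribution({}, 0.0, OPTIMAL, problem.objective_reaction)
    A = stoichiometric_matrix(net, dtype="float")
    bounds = problem.bounds()
    c = np.zeros(n)
    j_obj = net.reaction_ids().index(problem.objective_reaction)
    c[j_obj] = -1.0  # linprog minimizes
    res = _solve_lp(c, A, bounds)
    status = _STATUS.get(res.status, INFEASIBLE)
    if status != OPTIMAL:
        return FluxDistribution({}, None, status, problem.objective_reaction)
    z = -res.fun
    v = res.x
    if parsimonious:
        # minimize sum |v| with the objective pinned at its optimum:
        # variables (v, t), t >= |v|; pin via bounds on the objective column.
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A2 = np.hstack([A, np.zeros_like(A)])
        # t_i - v_i >= 0 and t_i + v_i >= 0  ->  as A_ub x <= b
        I = np.eye(n)
        A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
        b_ub = np.zeros(2 * n)
        bnds2 = list(bounds) + [(0.0, None)] * n
        bnds2[j_obj] = (z, z)
        res2 = linprog(c2, A_eq=np.hstack([A2]), b_eq=np.zeros(A.shape[0]),
                       A_ub=A_ub, b_ub=b_ub, bounds=bnds2, method="highs",
                       options=dict(_HIGHS_OPTIONS))
        if res2.status == 0:
            v = res2.x[:n]
    fluxes = {r.id: float(x) for r, x in zip(net.reactions, v)}
    return FluxDistribution(fluxes, float(z), OPTIMAL, problem.objective_reaction)


def flux_report(distribution: FluxDistribution, network: MetabolicNetwork) -> pd.DataFrame:
    """Flux table ordered by reaction index (for TSV export / bar plots)."""
    if distribution.status != OPTIMAL:
        raise ValueError(f"cannot report fluxes of a {distribution.status} solution")
    rows = [
        {"reaction": r.id, "name": r.name, "flux": distribution.fluxes[r.id]}
        for r in network.reactions
    ]
    return pd.DataFrame(rows, columns=["reaction", "name", "flux"])


class FluxBalanceModel:
    """Model object for the flux-balance LP, statsmodels style.

    >>> model = FluxBalanceModel(network, objective="R41", fixed={"R39": 100})
    >>> results = model.fit()
    >>> results.objective_value
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        objective: str,
        fixed: Optional[Mapping[str, float]] = None,
        flux_cap: float = DEFAULT_FLUX_CAP,
    ) -> None:
        self.network = network
        self.problem = FBAProblem(network, objective, dict(fixed or {}), flux_cap)

    @classmethod
    def reference_problem(cls, network: MetabolicNetwork) -> "FluxBalanceModel":
        """The study's reference LP: maximize hexadecenoate secretion (R41)
        with the acetyl-CoA uptake (R39) fixed to 100."""
        from .curated import ACC_UPTAKE_ID, PRODUCT_SECRETION_ID

        return cls(network, PRODUCT_SECRETION_ID, {ACC_UPTAKE_ID: 100.0})

    def fit(self, parsimonious: bool = True) -> "FBAResults":
        dist = solve_fba(self.problem, parsimonious=parsimonious)
        return FBAResults(self, dist)


class FBAResults:
    """Fitted FBA results: fluxes, objective, diagnostics, summary table."""

    def __init__(self, model: FluxBalanceModel, distribution: FluxDistribution) -> None:
        self.model = model
        self.distribution = distribution

    @property
    def status(self) -> str:
        return self.distribution.status

    @property
    def objective_value(self) -> Optional[float]:
        return self.distribution.objective_value

    @property
    def fluxes(self) -> dict[str, float]:
        return self.distribution.fluxes

    def flux_frame(self) -> pd.DataFrame:
        return flux_report(self.distribution, self.model.network)

    def steady_state_residual(self) -> float:
        return self.distribution.steady_state_residual(self.model.network)

    def summary(self, top: int = 15) -> str:
        p = self.model.problem
        lines = [
            "Flux Balance Analysis Results",
            "=" * 46,
            f"Network:        {self.model.network.name or 'unnamed'} "
            f"{self.model.network.shape[0]}x{self.model.network.shape[1]}",
            f"Objective:      maximize {p.objective_reaction}",
            f"Fixed fluxes:   {dict(p.fixed_fluxes) or 'none'}",
            f"Status:         {self.status}",
        ]
        if self.status == "optimal":
            lines.append(f"Objective flux: {self.objective_value:.4f}")
            lines.append(f"||S v||_inf:    {self.steady_state_residual():.2e}")
            frame = self.flux_frame()
            active = frame[frame.flux.abs() > 1e-9]
            lines.append(f"Active fluxes:  {len(active)} of {len(frame)}")
            lines.append("-" * 46)
            show = active.reindex(active.flux.abs().sort_values(ascending=False).index)
            for _, row in show.head(top).iterrows():
                lines.append(f"  {row.reaction:<6} {row.flux:>10.4f}  {row['name'][:40]}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar plot of the flux distribution (reaction index vs flux)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3.5))
        frame = self.flux_frame()
        ax.bar(range(len(frame)), frame.flux.to_numpy())
        ax.set_xticks(range(len(frame)))
        ax.set_xticklabels(frame.reaction, rotation=90, fontsize=6)
        ax.set_ylabel("flux (% of AcCoA input)")
        ax.set_xlabel("reaction")
        return ax
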