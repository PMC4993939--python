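"""Synthetic toy networks with known or brute-force-checkable properties.

These generators stand in for the curated study network wherever an
algorithm needs inputs with independently known answers: linear chains have
exactly one elementary mode, a k-fold parallel motif has exactly k, and
small seeded random networks are cross-checked against the brute-force
enumerator.  All generators are pure functions of their arguments (seed
included).
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np

from .core import CYTOPLASM, EXTRACELLULAR, MetabolicNetwork, Metabolite, Reaction

__all__ = ["make_chain", "make_parallel", "make_random"]


def _rxn(rid, stoich, reversible=False, subsystem=None):
    return Reaction(rid, rid, {m: Fraction(c) for m, c in stoich.items()},
                    reversible=reversible, subsystem=subsystem)


def make_chain(n: int) -> MetabolicNetwork:
    """Linear pathway uptake -> M1 -> ... -> Mn -> secreted product.

    All reactions irreversible with unit coefficients: the uptake feeding
    M1, the n-1 internal conversions, the export of Mn to the extracellular
    product and the product's exchange — n + 2 reactions in total, with
    exactly one elementary mode."""
    if n < 1:
        raise ValueError("chain length must be >= 1")
    net = MetabolicNetwork(name=f"chain_{n}")
    for i in range(1, n + 1):
        net.add_metabolite(Metabolite(f"M{i}", f"M{i}", CYTOPLASM))
    net.add_metabolite(
        Metabolite("product_e", "product_e", EXTRACELLULAR, is_boundary=True)
    )
    net.add_reaction(_rxn("uptake", {"M1": 1}, subsystem="exchange"))
    for i in range(1, n):
        net.add_reaction(_rxn(f"step{i}", {f"M{i}": -1, f"M{i+1}": 1}))
    net.add_reaction(_rxn("export", {f"M{n}": -1, "product_e": 1}, subsystem="transport"))
    net.add_reaction(_rxn("secretion", {"product_e": -1}, subsystem="exchange"))
    return net


def make_parallel(k: int) -> MetabolicNetwork:
    """Uptake -> A, k parallel reactions A -> B, B -> secretion.

    One elementary mode per branch; ``k=2`` is the diamond motif."""
    if k < 1:
        raise ValueError("branch count must be >= 1")
    net = MetabolicNetwork(name=f"parallel_{k}")
    net.add_metabolite(Metabolite("A", "A", CYTOPLASM))
    net.add_metabolite(Metabolite("B", "B", CYTOPLASM))
    net.add_reaction(_rxn("uptake", {"A": 1}, subsystem="exchange"))
    for i in range(1, k + 1):
        net.add_reaction(_rxn(f"branch{i}", {"A": -1, "B": 1}))
    net.add_reaction(_rxn("secretion", {"B": -1}, subsystem="exchange"))
    return net


def _admits_nonzero_flux(net: MetabolicNetwork) -> bool:
    """True if some nonzero steady-state flux within bounds exists."""
    from scipy.optimize import linprog

    from .core import stoichiometric_matrix
    from .fba import default_bounds

    S = stoichiometric_matrix(net, dtype="float")
    n = len(net.reactions)
    bounds = [default_bounds(r, 1.0) for r in net.reactions]
    c = np.zeros(n)
    c[0] = -1.0  # maximize the uptake flux
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    return bool(res.status == 0 and -res.fun > 1e-9)


def make_random(
    n_mets: int,
    n_rxns: int,
    reversible_fraction: float = 0.0,
    seed: int = 0,
    max_retries: int = 20,
) -> MetabolicNetwork:
    """Seeded sparse random network guaranteed to carry some nonzero flux.

    A connected uptake -> M1 -> ... -> Mn -> secretion backbone is laid down
    first so the network is never vacuously dead; remaining reactions get
    sparse random stoichiometries with coefficients in {-2, -1, 1, 2}.
    Draws that still admit no nonzero steady-state flux are resampled up to
    ``max_retries`` times, then flagged via ``metadata['degenerate']``.
    """
    if n_mets < 2:
        raise ValueError("need at least 2 metabolites")
    if n_rxns < n_mets + 1:
        raise ValueError("need at least n_mets + 1 reactions for the backbone")
    if n_rxns > 12:
        raise ValueError("random generator capped at 12 reactions (oracle-compatible)")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries + 1):
        net = MetabolicNetwork(
            name=f"random_{n_mets}x{n_rxns}_s{seed}",
            metadata={"seed": seed, "attempt": attempt, "degenerate": False},
        )
        mets = [f"M{i}" for i in range(1, n_mets + 1)]
        for m in mets:
            net.add_metabolite(Metabolite(m, m, CYTOPLASM))
        # backbone: uptake, chain, secretion
        net.add_reaction(_rxn("uptake", {mets[0]: 1}, subsystem="exchange"))
        for i in range(n_mets - 1):
            rev = bool(rng.random() < reversible_fraction)
            net.add_reaction(_rxn(f"step{i+1}", {mets[i]: -1, mets[i + 1]: 1}, rev))
        net.add_reaction(_rxn("secretion", {mets[-1]: -1}, subsystem="exchange"))
        extra = n_rxns - (n_mets + 1)
        made = 0
        guard = 0
        while made < extra and guard < 200:
            guard += 1
            k = int(rng.integers(2, min(4, n_mets) + 1))
            chosen = rng.choice(n_mets, size=k, replace=False)
            coeffs = rng.choice([-2, -1, 1, 2], size=k)
            if (coeffs > 0).all() or (coeffs < 0).all():
                continue  # keep every reaction a conversion, not a source/sink
            stoich = {mets[i]: int(c) for i, c in zip(chosen, coeffs)}
            rev = bool(rng.random() < reversible_fraction)
            try:
                net.add_reaction(_rxn(f"rand{made+1}", stoich, rev))
            except ValueError:
                continue
            made += 1
        if made == extra and _admits_nonzero_flux(net):
            return net
    net.metadata["degenerate"] = True
    return net
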