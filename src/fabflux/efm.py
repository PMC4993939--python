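"""Elementary flux mode enumeration in exact rational arithmetic.

An elementary flux mode (EFM) is a steady-state flux vector, sign-feasible
for the irreversible reactions, whose support (set of active reactions) is
minimal: no other admissible vector's support is strictly contained in it.
EFMs generate the flux cone and are unique up to positive scaling.

The enumerator follows the classic double-description / tableau scheme:

1. split every reversible reaction into a forward/backward irreversible
   pair, so the flux cone becomes pointed and its extreme rays are exactly
   the EFMs of the split network;
2. starting from the positive orthant's generators, impose one steady-state
   equality at a time, combining adjacent positive/negative rays
   (combinatorial adjacency test on zero-sets, held as bitmasks);
3. recombine the split pairs, discard the spurious forward/backward
   two-cycles, canonicalize scale and sign, and order deterministically.

All arithmetic is over Python integers/fractions, so steady state and
support-minimality are exact, never tolerance-based.

A brute-force enumerator over support subsets doubles as an independent
oracle for small networks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from math import gcd
from typing import Iterable, Optional

from .core import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "ElementaryMode",
    "EMSet",
    "EnumerationLimitError",
    "enumerate_elementary_modes",
    "brute_force_elementary_modes",
    "modes_producing",
    "normalize_mode",
    "ElementaryFluxModes",
    "EMResults",
]


class EnumerationLimitError(RuntimeError):
    """Raised when intermediate ray counts exceed the configured cap."""


@dataclass(frozen=True)
class ElementaryMode:
    """A support-minimal steady-state flux vector (exact rationals)."""

    coefficients: dict[str, Fraction]
    normalized_to: Optional[str] = None
    normalization_failed: bool = False

    @property
    def support(self) -> frozenset[str]:
        return frozenset(r for r, c in self.coefficients.items() if c != 0)

    def coefficient(self, rxn_id: str) -> Fraction:
        return self.coefficients.get(rxn_id, Fraction(0))

    def __getitem__(self, rxn_id: str) -> Fraction:
        return self.coefficient(rxn_id)


@dataclass
class EMSet:
    """A deterministic, canonically ordered collection of elementary modes."""

    modes: list[ElementaryMode]
    reaction_ids: list[str]
    normalization: str = "smallest positive integers"

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, i: int) -> ElementaryMode:
        return self.modes[i]

    def supports(self) -> list[frozenset[str]]:
        return [m.support for m in self.modes]

    def to_frame(self):
        import pandas as pd

        data = [
            [float(m.coefficient(r)) for r in self.reaction_ids] for m in self.modes
        ]
        return pd.DataFrame(
            data,
            columns=self.reaction_ids,
            index=[f"EM{i + 1}" for i in range(len(self.modes))],
        )


# ---------------------------------------------------------------------------
# exact linear algebra
# ---------------------------------------------------------------------------

def _rational_rref(rows: list[list[Fraction]]) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form over the rationals; returns (rref, pivot columns)."""
    mat = [list(r) for r in rows]
    n_rows = len(mat)
    n_cols = len(mat[0]) if mat else 0
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        pivot = next((i for i in range(r, n_rows) if mat[i][c] != 0), None)
        if pivot is None:
            continue
        mat[r], mat[pivot] = mat[pivot], mat[r]
        pv = mat[r][c]
        mat[r] = [x / pv for x in mat[r]]
        for i in range(n_rows):
            if i != r and mat[i][c] != 0:
                f = mat[i][c]
                mat[i] = [a - f * b for a, b in zip(mat[i], mat[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    return mat, pivots


def rational_nullspace(rows: list[list[Fraction]], n_cols: int) -> list[list[Fraction]]:
    """Basis of the rational nullspace of the matrix given as a list of rows."""
    if not rows:
        return [[Fraction(int(i == j)) for j in range(n_cols)] for i in range(n_cols)]
    rref, pivots = _rational_rref(rows)
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for f in free:
        v = [Fraction(0)] * n_cols
        v[f] = Fraction(1)
        for r, p in enumerate(pivots):
            v[p] = -rref[r][f]
        basis.append(v)
    return basis


def _reduce_int(v: list[int]) -> list[int]:
    g = 0
    for x in v:
        g = gcd(g, x)
    return [x // g for x in v] if g > 1 else v


# ---------------------------------------------------------------------------
# reversible splitting
# ---------------------------------------------------------------------------

def _split_columns(network: MetabolicNetwork) -> tuple[list[list[int]], list[tuple[int, int]]]:
    """Integer-scaled stoichiometric rows of the split (all-irreversible)
    network, plus the (original column, sign) map for each split column."""
    S = stoichiometric_matrix(network, dtype="fraction")
    cols: list[tuple[int, int]] = []
    for j, rxn in enumerate(network.reactions):
        cols.append((j, 1))
        if rxn.reversible:
            cols.append((j, -1))
    rows: list[list[int]] = []
    for i in range(S.shape[0]):
        den = 1
        for j in range(S.shape[1]):
            den = den * S[i, j].denominator // gcd(den, S[i, j].denominator)
        rows.append([int(S[i, j] * den) * s for (j, s) in cols])
    return rows, cols


def _recombine(
    split_rays: Iterable[list[int]],
    cols: list[tuple[int, int]],
    network: MetabolicNetwork,
) -> list[ElementaryMode]:
    """Map split-network rays back to the original reactions.

    Forward/backward two-cycles collapse to zero and are discarded; a mode
    whose support is entirely reversible appears twice with opposite signs
    and is canonicalized to a positive leading coefficient.
    """
    rids = network.reaction_ids()
    reversible = [r.reversible for r in network.reactions]
    out: dict[tuple, ElementaryMode] = {}
    for ray in split_rays:
        v = [0] * len(rids)
        for x, (j, s) in zip(ray, cols):
            v[j] += s * x
        if all(x == 0 for x in v):
            continue  # spurious two-cycle of a split pair
        v = _reduce_int(v)
        supp = [j for j, x in enumerate(v) if x != 0]
        if all(reversible[j] for j in supp):
            lead = v[supp[0]]
            if lead < 0:
                v = [-x for x in v]
        key = tuple(v)
        if key not in out:
            out[key] = ElementaryMode(
                {rids[j]: Fraction(v[j]) for j in supp}
            )
    return list(out.values())


def _canonical_emset(modes: list[ElementaryMode], network: MetabolicNetwork) -> EMSet:
    rids = network.reaction_ids()
    order = {r: i for i, r in enumerate(rids)}

    def key(m: ElementaryMode):
        return tuple(sorted(order[r] for r in m.support))

    return EMSet(modes=sorted(modes, key=key), reaction_ids=rids)


# ---------------------------------------------------------------------------
# double-description enumeration
# ---------------------------------------------------------------------------

def _extreme_rays(rows: list[list[int]], n: int, max_rays: int) -> list[list[int]]:
    """Extreme rays of {v >= 0 : rows . v = 0} by double description."""
    rays = [[1 if j == i else 0 for j in range(n)] for i in range(n)]
    remaining = list(range(len(rows)))
    while remaining:
        # next row: fewest positive x negative combinations (keeps growth low)
        best = best_vals = None
        best_cost = None
        for ri in remaining:
            row = rows[ri]
            vals = [
                sum(r[j] * row[j] for j in range(n) if row[j] and r[j]) for r in rays
            ]
            cost = sum(1 for v in vals if v > 0) * sum(1 for v in vals if v < 0)
            if best_cost is None or cost < best_cost:
                best, best_cost, best_vals = ri, cost, vals
                if cost == 0:
                    break
        remaining.remove(best)
        vals = best_vals
        keep = [r for r, v in zip(rays, vals) if v == 0]
        pos = [(r, v) for r, v in zip(rays, vals) if v > 0]
        neg = [(r, v) for r, v in zip(rays, vals) if v < 0]
        masks = []
        for r in rays:
            m = 0
            for j in range(n):
                if r[j] == 0:
                    m |= 1 << j
            masks.append(m)
        idmask = {id(r): m for r, m in zip(rays, masks)}
        new = list(keep)
        for rp, vp in pos:
            zp = idmask[id(rp)]
            for rn, vn in neg:
                z = zp & idmask[id(rn)]
                adjacent = True
                for r2, m2 in zip(rays, masks):
                    if r2 is rp or r2 is rn:
                        continue
                    if (z & ~m2) == 0:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                new.append(_reduce_int([vp * rn[j] - vn * rp[j] for j in range(n)]))
                if len(new) > max_rays:
                    raise EnumerationLimitError(
                        f"intermediate ray count exceeded the cap of {max_rays}"
                    )
        seen: set[tuple] = set()
        rays = []
        for r in new:
            t = tuple(r)
            if t not in seen:
                seen.add(t)
                rays.append(r)
    return rays


def enumerate_elementary_modes(
    network: MetabolicNetwork, max_modes: int = 200_000
) -> EMSet:
    """All elementary flux modes of the network, canonically ordered.

    ``max_modes`` caps the intermediate ray count of the double-description
    tableau; exceeding it raises :class:`EnumerationLimitError` rather than
    exhausting memory on networks outside this package's intended scale.
    """
    if not network.reactions:
        raise ValueError("cannot enumerate modes of an empty network")
    rows, cols = _split_columns(network)
    rays = _extreme_rays(rows, len(cols), max_modes)
    modes = _recombine(rays, cols, network)
    return _canonical_emset(modes, network)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_elementary_modes(
    network: MetabolicNetwork, max_split_reactions: int = 20
) -> EMSet:
    """Independent oracle: enumerate support subsets of the split network.

    A subset of split reactions is an elementary support iff the restricted
    stoichiometric matrix has a one-dimensional nullspace whose generator is
    strictly nonzero on the whole subset and sign-feasible.  Subsets are
    visited in order of increasing size and supersets of accepted supports
    are pruned, which makes the exhaustive sweep tractable for the toy
    networks this oracle is meant for.
    """
    rows, cols = _split_columns(network)
    n = len(cols)
    if n > max_split_reactions:
        raise ValueError(
            f"brute force limited to {max_split_reactions} split reactions, got {n}"
        )
    frac_rows = [[Fraction(x) for x in row] for row in rows]
    accepted: list[tuple[int, ...]] = []
    accepted_sets: list[frozenset[int]] = []
    rays: list[list[int]] = []
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            sset = set(subset)
            if any(a <= sset for a in accepted_sets):
                continue
            sub = [[row[j] for j in subset] for row in frac_rows]
            null = rational_nullspace(sub, size)
            if len(null) != 1:
                continue
            g = null[0]
            if any(x == 0 for x in g):
                continue  # support smaller than the subset: found earlier
            if all(x > 0 for x in g):
                pass
            elif all(x < 0 for x in g):
                g = [-x for x in g]
            else:
                continue  # not sign-feasible for an all-irreversible cone
            den = 1
            for x in g:
                den = den * x.denominator // gcd(den, x.denominator)
            ray = [0] * n
            for j, x in zip(subset, g):
                ray[j] = int(x * den)
            rays.append(_reduce_int(ray))
            accepted.append(subset)
            accepted_sets.append(frozenset(subset))
    modes = _recombine(rays, cols, network)
    return _canonical_emset(modes, network)


# ---------------------------------------------------------------------------
# queries and normalization
# ---------------------------------------------------------------------------

def modes_producing(ems: EMSet, reaction_id: str) -> EMSet:
    """Modes with a strictly positive coefficient on ``reaction_id``."""
    if reaction_id not in ems.reaction_ids:
        raise KeyError(f"unknown reaction id {reaction_id!r}")
    return EMSet(
        modes=[m for m in ems.modes if m.coefficient(reaction_id) > 0],
        reaction_ids=ems.reaction_ids,
        normalization=ems.normalization,
    )


def normalize_mode(mode: ElementaryMode, reference_reaction: str) -> ElementaryMode:
    """Scale a mode so the reference reaction's coefficient equals one.

    If the reference coefficient is zero the mode is returned unchanged with
    ``normalization_failed`` set.  Coefficients of other reactions then read
    as yields relative to the reference flux.
    """
    ref = mode.coefficient(reference_reaction)
    if ref == 0:
        return ElementaryMode(
            dict(mode.coefficients),
            normalized_to=reference_reaction,
            normalization_failed=True,
        )
    if ref == 1 and mode.normalized_to == reference_reaction:
        return mode
    return ElementaryMode(
        {r: c / ref for r, c in mode.coefficients.items()},
        normalized_to=reference_reaction,
    )


# ---------------------------------------------------------------------------
# model/results wrappers
# ---------------------------------------------------------------------------

class ElementaryFluxModes:
    """Analysis object over a network; ``fit()`` runs the enumeration."""

    def __init__(self, network: MetabolicNetwork, max_modes: int = 200_000) -> None:
        self.network = network
        self.max_modes = max_modes

    def fit(self) -> "EMResults":
        return EMResults(self, enumerate_elementary_modes(self.network, self.max_modes))


class EMResults:
    """Enumerated mode set with summary and yield reporting."""

    def __init__(self, model: ElementaryFluxModes, emset: EMSet) -> None:
        self.model = model
        self.emset = emset

    @property
    def n_modes(self) -> int:
        return len(self.emset)

    def producing(self, reaction_id: str) -> EMSet:
        return modes_producing(self.emset, reaction_id)

    def yields(self, target: str, reference: str) -> list[Fraction]:
        """Target-reaction coefficients of the producing modes whose support
        contains ``reference``, after normalizing each to reference = 1."""
        out = []
        for m in modes_producing(self.emset, target):
            if m.coefficient(reference) != 0:
                out.append(normalize_mode(m, reference).coefficient(target))
        return out

    def summary(self, target: Optional[str] = None) -> str:
        lines = [
            "Elementary Flux Mode Analysis",
            "=" * 46,
            f"Network: {self.model.network.name or 'unnamed'} "
            f"{self.model.network.shape[0]}x{self.model.network.shape[1]}",
            f"Elementary modes: {self.n_modes}",
        ]
        if target is not None:
            prod = self.producing(target)
            lines.append(f"Modes producing {target}: {len(prod)}")
            for i, m in enumerate(prod, 1):
                lines.append(
                    f"  mode {i}: support size {len(m.support)}, "
                    f"{target} coefficient {m.coefficient(target)}"
                )
        return "\n".join(lines)
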