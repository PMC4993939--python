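"""Transcriptome-constrained FBA.

Differential expression between 0 degC and 37 degC (log2 fold changes per
locus tag, RPKM-based) is mapped onto reaction capacity: a reaction's score
is the minimum subunit log2FC for enzyme complexes (AND) or the maximum for
isozymes (OR), and bound magnitudes are scaled by 2**score (an E-Flux-style
multiplicative rule).  For the reference transcriptome-FBA the scores are
first shifted by the maximum observed log2FC, so the most-induced enzyme
keeps its full capacity and every other enzyme is capped relative to it;
this normalized variant is what makes the expression data bite on the
carboxylase step (the raw 2**score factors all sit above the plain-FBA
fluxes and would leave the optimum unchanged).  The mapping is pluggable:
any callable score -> factor can be substituted.

The packaged table of curated log2FC values ships with the module
(``data/expression_log2fc.tsv``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .core import MetabolicNetwork, Reaction
from .fba import FBAProblem, FluxDistribution, solve_fba

__all__ = [
    "ExpressionRecord",
    "ExpressionParseError",
    "load_expression_table",
    "packaged_expression_table",
    "reaction_expression_score",
    "apply_expression_bounds",
    "transcriptome_fba",
]


@dataclass(frozen=True)
class ExpressionRecord:
    """One locus tag's log2 fold change (0 degC vs 37 degC)."""

    locus_tag: str
    log2fc: float
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValueError("locus_tag must be non-empty")


class ExpressionParseError(ValueError):
    """Raised when rows of an expression table cannot be parsed."""

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        msg = "; ".join(f"row {i}: {e}" for i, e in row_errors)
        super().__init__(f"unparseable expression rows: {msg}")


RowLike = Union[Mapping[str, object], Sequence[object]]


def load_expression_table(
    rows: Iterable[RowLike], strict: bool = False
) -> list[ExpressionRecord]:
    """Parse (locus_tag, gene, log2fc) rows into records.

    Accepts mappings with ``locus_tag``/``gene``/``log2fc`` keys or plain
    sequences in that order.  Rows with a non-numeric log2fc are recorded as
    row-level errors: with ``strict=False`` (default) they are skipped with
    a warning, with ``strict=True`` an :class:`ExpressionParseError` lists
    them.  Duplicate locus tags are rejected.
    """
    records: list[ExpressionRecord] = []
    errors: list[tuple[int, str]] = []
    seen: set[str] = set()
    for i, row in enumerate(rows):
        if isinstance(row, Mapping):
            locus = str(row.get("locus_tag", "") or "")
            gene = row.get("gene") or None
            raw = row.get("log2fc")
        else:
            seq = list(row)
            locus = str(seq[0]) if seq else ""
            gene = (str(seq[1]) or None) if len(seq) > 2 else None
            raw = seq[-1] if seq else None
        if not locus:
            errors.append((i, "missing locus_tag"))
            continue
        if locus in seen:
            errors.append((i, f"duplicate locus_tag {locus}"))
            continue
        try:
            value = float(raw)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            errors.append((i, f"non-numeric log2fc {raw!r}"))
            continue
        if value != value:  # NaN
            errors.append((i, f"non-numeric log2fc {raw!r}"))
            continue
        seen.add(locus)
        records.append(ExpressionRecord(locus, value, str(gene) if gene else None))
    if errors:
        if strict:
            raise ExpressionParseError(errors)
        warnings.warn(f"skipped {len(errors)} unparseable expression rows", stacklevel=2)
    return records


def packaged_expression_table() -> list[ExpressionRecord]:
    """The curated log2FC table shipped with the package (11 loci)."""
    import csv

    path = resources.files("fabflux").joinpath("data/expression_log2fc.tsv")
    with path.open() as fh:
        return load_expression_table(csv.DictReader(fh, delimiter="\t"), strict=True)


def reaction_expression_score(
    reaction: Reaction, records: Iterable[ExpressionRecord]
) -> Optional[float]:
    """Combine subunit log2FCs onto one reaction.

    AND-combined genes (complex subunits) take the minimum — the least
    expressed subunit limits the complex; OR-combined genes (isozymes) take
    the maximum.  Reactions with no measured gene have no score.
    """
    by_locus = {r.locus_tag: r.log2fc for r in records}
    values = [by_locus[g] for g in reaction.genes if g in by_locus]
    if not values:
        return None
    return min(values) if reaction.gene_rule == "and" else max(values)


def eflux_factor(score: float, scale_cap: float = 1.0) -> float:
    """Multiplicative bound factor min(2**score, scale_cap * ...).

    The factor is capped at ``scale_cap`` (>= 1), so down-regulation always
    tightens bounds while up-regulation can relax them at most ``scale_cap``
    fold.
    """
    if scale_cap < 1.0:
        raise ValueError("scale_cap must be >= 1")
    return min(2.0 ** score, scale_cap)


def apply_expression_bounds(
    network: MetabolicNetwork,
    records: Iterable[ExpressionRecord],
    scale_cap: float = 1.0,
    factor: Callable[[float, float], float] = eflux_factor,
) -> MetabolicNetwork:
    """Return a copy of the network with expression-scaled flux bounds.

    Each scored reaction's bound magnitudes are multiplied by
    ``factor(score, scale_cap)``: the upper bound in the forward direction
    and, for reversible reactions, the lower bound symmetrically.  Unscored
    reactions keep their bounds; the input network is never mutated.
    """
    from .fba import default_bounds

    records = list(records)
    scaled = network.copy()
    for rxn in scaled.reactions:
        score = reaction_expression_score(rxn, records)
        if score is None:
            continue
        f = factor(score, scale_cap)
        lb, ub = default_bounds(rxn)
        rxn.upper_bound = ub * f
        rxn.lower_bound = lb * f if rxn.reversible else lb
    return scaled


def transcriptome_fba(
    network: MetabolicNetwork,
    records: Iterable[ExpressionRecord],
    objective: Optional[str] = None,
    fixed: Optional[Mapping[str, float]] = None,
    normalize_to_max: bool = True,
    scale_cap: float = 1.0,
    parsimonious: bool = True,
) -> FluxDistribution:
    """Solve the reference FBA under expression-scaled bounds.

    By default the objective and fixed fluxes are the study's reference
    problem (maximize hexadecenoate secretion R41 with acetyl-CoA uptake R39
    fixed at 100).  With ``normalize_to_max`` (default) scores are shifted
    by the maximum log2FC before the 2**score rule, anchoring all capacities
    to the most cold-induced enzyme.
    """
    from .curated import ACC_UPTAKE_ID, PRODUCT_SECRETION_ID

    records = list(records)
    if normalize_to_max and records:
        shift = max(r.log2fc for r in records)
        records = [
            ExpressionRecord(r.locus_tag, r.log2fc - shift, r.gene) for r in records
        ]
    constrained = apply_expression_bounds(network, records, scale_cap=scale_cap)
    if objective is None:
        objective = PRODUCT_SECRETION_ID
    if fixed is None:
        fixed = {ACC_UPTAKE_ID: 100.0}
    problem = FBAProblem(constrained, objective, dict(fixed))
    return solve_fba(problem, parsimonious=parsimonious)
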