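"""Core data model: metabolites, reactions, networks, stoichiometric matrices.

Stoichiometric coefficients are stored as exact :class:`fractions.Fraction`
values so that steady-state and support-minimality tests (elementary-mode
analysis) can be decided without floating-point tolerance.  Conversion to
floats happens only inside the LP solver.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

Number = Union[int, Fraction]

CYTOPLASM = "cytoplasm"
EXTRACELLULAR = "extracellular"


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``carbon_count`` tracks acyl-chain carbons for ACP-bound intermediates
    (and the small carbon carriers they exchange carbon with); it is ``None``
    for species whose carbon content is not modelled.  ``is_boundary`` marks
    species that sit at the system boundary (exchanged with the environment).
    """

    id: str
    name: str = ""
    compartment: str = CYTOPLASM
    carbon_count: Optional[int] = None
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")
        if self.carbon_count is not None and self.carbon_count < 0:
            raise ValueError(f"negative carbon_count on {self.id}")
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """A stoichiometric conversion with bounds and gene association.

    ``stoichiometry`` maps metabolite id to a signed rational coefficient
    (negative = consumed, positive = produced).  ``genes`` is a list of locus
    tags combined with ``gene_rule`` (``"and"`` for subunits of one complex,
    ``"or"`` for isozymes).  Bounds of ``None`` mean "use the network default"
    ([0, 100] irreversible, [-100, 100] reversible; see :mod:`fabflux.fba`).
    """

    id: str
    name: str = ""
    stoichiometry: Mapping[str, Fraction] = field(default_factory=dict)
    reversible: bool = False
    lower_bound: Optional[float] = None
    upper_bound: Optional[float] = None
    genes: Sequence[str] = field(default_factory=tuple)
    gene_rule: str = "and"
    ec_number: Optional[str] = None
    subsystem: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.name:
            self.name = self.id
        coeffs = {}
        for met, c in dict(self.stoichiometry).items():
            c = Fraction(c)
            if c == 0:
                raise ValueError(f"zero coefficient for {met} in {self.id}")
            coeffs[met] = c
        if not coeffs:
            raise ValueError(f"empty stoichiometry in reaction {self.id}")
        self.stoichiometry = coeffs
        self.genes = tuple(self.genes)
        if self.gene_rule not in ("and", "or"):
            raise ValueError(f"gene_rule must be 'and' or 'or', got {self.gene_rule!r}")
        if not self.reversible and self.lower_bound is not None and self.lower_bound < 0:
            raise ValueError(
                f"irreversible reaction {self.id} cannot have a negative lower bound"
            )
        if (
            self.lower_bound is not None
            and self.upper_bound is not None
            and self.lower_bound > self.upper_bound
        ):
            raise ValueError(f"lower bound exceeds upper bound in {self.id}")

    @property
    def substrates(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def equation(self, arrow_reversible: str = "<->", arrow_irreversible: str = "->") -> str:
        """Human-readable equation string, e.g. ``atp + accoa -> adp + malcoa``."""

        def side(terms: Mapping[str, Fraction]) -> str:
            parts = []
            for met in terms:
                c = terms[met]
                parts.append(met if c == 1 else f"{c} {met}")
            return " + ".join(parts)

        arrow = arrow_reversible if self.reversible else arrow_irreversible
        return f"{side(self.substrates)} {arrow} {side(self.products)}".strip()


class MetabolicNetwork:
    """An ordered collection of metabolites and reactions.

    The network owns the row/column ordering of the stoichiometric matrix:
    rows follow ``metabolites``, columns follow ``reactions``.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        name: str = "",
        metadata: Optional[dict] = None,
    ) -> None:
        self.name = name
        self.metadata = dict(metadata or {})
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self._met_index:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self._rxn_index:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self._met_index]
        if missing:
            raise KeyError(
                f"reaction {rxn.id} references undeclared metabolites: {missing}"
            )
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)
        return rxn

    # -- lookup -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.metabolites), len(self.reactions))

    def copy(self) -> "MetabolicNetwork":
        import copy as _copy

        net = MetabolicNetwork(name=self.name, metadata=_copy.deepcopy(self.metadata))
        for m in self.metabolites:
            net.add_metabolite(_copy.deepcopy(m))
        for r in self.reactions:
            net.add_reaction(_copy.deepcopy(r))
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        if self.shape != other.shape:
            return False
        for a, b in zip(self.metabolites, other.metabolites):
            if (a.id, a.compartment, a.carbon_count, a.is_boundary) != (
                b.id,
                b.compartment,
                b.carbon_count,
                b.is_boundary,
            ):
                return False
        for a, b in zip(self.reactions, other.reactions):
            if (a.id, a.stoichiometry, a.reversible, a.lower_bound, a.upper_bound) != (
                b.id,
                b.stoichiometry,
                b.reversible,
                b.lower_bound,
                b.upper_bound,
            ):
                return False
        return True

    def __repr__(self) -> str:
        m, r = self.shape
        return f"<MetabolicNetwork {self.name or 'unnamed'}: {m} metabolites x {r} reactions>"


def stoichiometric_matrix(network: MetabolicNetwork, dtype: str = "fraction"):
    """The metabolites x reactions matrix of signed coefficients.

    Entry (i, j) is the coefficient of metabolite i in reaction j: negative
    for consumed, positive for produced, zero where absent.  With
    ``dtype="fraction"`` an object array of exact rationals is returned;
    ``dtype="float"`` gives a float64 array for numerical work.
    """
    n_m, n_r = network.shape
    if dtype == "float":
        S = np.zeros((n_m, n_r), dtype=float)
    elif dtype == "fraction":
        S = np.empty((n_m, n_r), dtype=object)
        S.fill(Fraction(0))
    else:
        raise ValueError("dtype must be 'fraction' or 'float'")
    midx = {m.id: i for i, m in enumerate(network.metabolites)}
    for j, rxn in enumerate(network.reactions):
        for met, c in rxn.stoichiometry.items():
            S[midx[met], j] = float(c) if dtype == "float" else c
    return S


@dataclass
class CarbonBalanceReport:
    """Per-reaction carbon bookkeeping over carbon-annotated species."""

    imbalances: dict[str, Fraction]
    exempt: list[str]

    @property
    def violations(self) -> dict[str, Fraction]:
        return {r: d for r, d in self.imbalances.items() if d != 0}

    @property
    def ok(self) -> bool:
        return not self.violations


def _is_exchange_like(network: MetabolicNetwork, rxn: Reaction) -> bool:
    """Exchange/transport/release reactions are exempt from carbon balance.

    A reaction is exchange-like if it touches a boundary-flagged species, or
    is explicitly labelled as an exchange/transport/release subsystem.
    """
    if rxn.subsystem in ("exchange", "transport", "release"):
        return True
    return any(network.metabolite(m).is_boundary for m in rxn.stoichiometry)


def validate_carbon_balance(network: MetabolicNetwork) -> CarbonBalanceReport:
    """Check that internal reactions conserve the tracked carbon count.

    Only species with a ``carbon_count`` annotation participate; a reaction
    with no annotated species (e.g. a toy network without carbon bookkeeping)
    is exempt, as are exchange-like reactions, where carbon legitimately
    enters or leaves the system.
    """
    imbalances: dict[str, Fraction] = {}
    exempt: list[str] = []
    for rxn in network.reactions:
        if _is_exchange_like(network, rxn):
            exempt.append(rxn.id)
            continue
        tracked = [
            (c, network.metabolite(m).carbon_count)
            for m, c in rxn.stoichiometry.items()
            if network.metabolite(m).carbon_count is not None
        ]
        if not tracked:
            exempt.append(rxn.id)
            continue
        imbalances[rxn.id] = sum((c * n for c, n in tracked), Fraction(0))
    return CarbonBalanceReport(imbalances=imbalances, exempt=exempt)
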