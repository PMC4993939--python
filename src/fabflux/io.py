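"""Interchange formats: SBML (Level 3 + fbc) and plain-text reaction tables.

SBML I/O goes through python-libsbml.  Species carry their compartment and
boundary flag natively; the acyl-chain carbon annotation travels in the
species notes.  Flux bounds are written as fbc flux-bound parameters —
shared default parameters when a reaction uses the study's default bounds,
dedicated parameters when bounds were set explicitly — so a round trip
restores exactly what was set.  Gene associations become fbc gene products
with AND/OR associations.

The reaction-table format is a TSV with one reaction per row
(``id, name, equation, lower_bound, upper_bound, genes, gene_rule,
ec_number, subsystem``).  Equations accept the arrow dialects ``=>``/``<=>``,
``->``/``<->`` and the typographic ``⇒``/``⇔``; output always uses
``->``/``<->``.  Metabolite ids ending in ``_e`` are placed in the
extracellular compartment.  All exports are deterministic, so identical
inputs produce byte-identical files.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import libsbml

from .core import (
    CYTOPLASM,
    EXTRACELLULAR,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    stoichiometric_matrix,
)

__all__ = [
    "NetworkDocument",
    "ReactionTableError",
    "SBMLReadError",
    "write_sbml",
    "read_sbml",
    "read_reaction_table",
    "write_reaction_table",
    "write_matrix_tsv",
    "write_matrix_triplets",
]

_DEFAULT_LB_IRREV = "fab_default_lb_irreversible"
_DEFAULT_LB_REV = "fab_default_lb_reversible"
_DEFAULT_UB = "fab_default_ub"
_DEFAULT_CAP = 100.0


@dataclass
class NetworkDocument:
    """A network plus the provenance of where it came from."""

    network: MetabolicNetwork
    provenance: str = "built"
    metadata: dict = field(default_factory=dict)


class SBMLReadError(ValueError):
    pass


class ReactionTableError(ValueError):
    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _check(value, message: str):
    if value is None:
        raise RuntimeError(f"libsbml returned None: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise RuntimeError(f"libsbml error {value}: {message}")
    return value


def _notes(pairs: dict[str, str]) -> str:
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'


def _parse_notes(raw: Optional[str]) -> dict[str, str]:
    if not raw:
        return {}
    out = {}
    for m in re.finditer(r"<p>\s*([^:<]+):\s*([^<]*)</p>", raw):
        out[m.group(1).strip()] = m.group(2).strip()
    return out


def write_sbml(network: MetabolicNetwork, destination: Union[str, Path]) -> NetworkDocument:
    """Write the network as SBML Level 3 Version 1 with the fbc package."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    _check(model, "create model")
    model.setId(network.name or "metabolic_network")
    mplug = model.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = []
    for m in network.metabolites:
        if m.compartment not in compartments:
            compartments.append(m.compartment)
    if not compartments:
        compartments = [CYTOPLASM]
    for cid in compartments:
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(bool(m.is_boundary))
        if m.carbon_count is not None:
            sp.setNotes(_notes({"carbon_count": str(m.carbon_count)}), True)

    # shared default-bound parameters + dedicated explicit ones
    def _param(pid: str, value: float):
        if model.getParameter(pid) is not None:
            return pid
        p = model.createParameter()
        p.setId(pid)
        p.setValue(float(value))
        p.setConstant(True)
        return pid

    _param(_DEFAULT_LB_IRREV, 0.0)
    _param(_DEFAULT_LB_REV, -_DEFAULT_CAP)
    _param(_DEFAULT_UB, _DEFAULT_CAP)

    gene_ids: dict[str, str] = {}

    def _gene_product(locus: str) -> str:
        if locus not in gene_ids:
            gp = mplug.createGeneProduct()
            gid = "G_" + re.sub(r"\W", "_", locus)
            gp.setId(gid)
            gp.setLabel(locus)
            gene_ids[locus] = gid
        return gene_ids[locus]

    for r in network.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(bool(r.reversible))
        rx.setFast(False)
        for met, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(met)
            ref.setStoichiometry(float(abs(coeff)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        if r.lower_bound is None:
            rplug.setLowerFluxBound(_DEFAULT_LB_REV if r.reversible else _DEFAULT_LB_IRREV)
        else:
            rplug.setLowerFluxBound(_param(f"lb_{r.id}", r.lower_bound))
        if r.upper_bound is None:
            rplug.setUpperFluxBound(_DEFAULT_UB)
        else:
            rplug.setUpperFluxBound(_param(f"ub_{r.id}", r.upper_bound))
        if r.genes:
            assoc = rplug.createGeneProductAssociation()
            if len(r.genes) == 1:
                ref = assoc.createGeneProductRef()
                ref.setGeneProduct(_gene_product(r.genes[0]))
            else:
                op = (
                    assoc.createAnd() if r.gene_rule == "and" else assoc.createOr()
                )
                for locus in r.genes:
                    ref = op.createGeneProductRef()
                    ref.setGeneProduct(_gene_product(locus))
        notes = {}
        if r.ec_number:
            notes["ec_number"] = r.ec_number
        if r.subsystem:
            notes["subsystem"] = r.subsystem
        if notes:
            rx.setNotes(_notes(notes), True)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(destination)):
        raise IOError(f"could not write SBML to {destination}")
    return NetworkDocument(network, provenance=f"sbml:{destination}")


def _association_genes(assoc) -> tuple[list[str], str]:
    if assoc is None:
        return [], "and"
    if isinstance(assoc, libsbml.GeneProductRef):
        return [assoc.getGeneProduct()], "and"
    rule = "or" if isinstance(assoc, libsbml.FbcOr) else "and"
    genes: list[str] = []
    for i in range(assoc.getNumAssociations()):
        sub, _ = _association_genes(assoc.getAssociation(i))
        genes.extend(sub)
    return genes, rule


def read_sbml(source: Union[str, Path]) -> NetworkDocument:
    """Read an SBML file back into a :class:`MetabolicNetwork`.

    Bounds pointing at the shared default parameters come back as ``None``
    (the fba module's defaults apply); explicit bounds are restored as set.
    Malformed documents raise :class:`SBMLReadError` naming the offending
    element.
    """
    doc = libsbml.readSBMLFromFile(str(source))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLReadError(f"SBML parse error: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise SBMLReadError("document contains no model element")
    net = MetabolicNetwork(name=model.getId() or "")
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        notes = _parse_notes(sp.getNotesString())
        carbon = notes.get("carbon_count")
        net.add_metabolite(
            Metabolite(
                sp.getId(),
                sp.getName() or sp.getId(),
                sp.getCompartment() or CYTOPLASM,
                int(carbon) if carbon is not None else None,
                bool(sp.getBoundaryCondition()),
            )
        )
    gene_labels = {}
    mplug = model.getPlugin("fbc")
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    def _bound(pid: Optional[str]) -> Optional[float]:
        if not pid or pid in (_DEFAULT_LB_IRREV, _DEFAULT_LB_REV, _DEFAULT_UB):
            return None
        p = model.getParameter(pid)
        if p is None:
            raise SBMLReadError(f"flux bound references missing parameter {pid!r}")
        return float(p.getValue())

    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: dict[str, Fraction] = {}
        for refs, sign in ((rx.getListOfReactants(), -1), (rx.getListOfProducts(), 1)):
            for j in range(len(refs)):
                ref = refs.get(j)
                sid = ref.getSpecies()
                if model.getSpecies(sid) is None:
                    raise SBMLReadError(
                        f"reaction {rx.getId()!r} references undeclared species {sid!r}"
                    )
                c = Fraction(ref.getStoichiometry()).limit_denominator(10**6) * sign
                stoich[sid] = stoich.get(sid, Fraction(0)) + c
        stoich = {m: c for m, c in stoich.items() if c != 0}
        rplug = rx.getPlugin("fbc")
        lb = ub = None
        genes: list[str] = []
        rule = "and"
        if rplug is not None:
            lb = _bound(rplug.getLowerFluxBound())
            ub = _bound(rplug.getUpperFluxBound())
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gids, rule = _association_genes(gpa.getAssociation())
                genes = [gene_labels.get(g, g) for g in gids]
        notes = _parse_notes(rx.getNotesString())
        net.add_reaction(
            Reaction(
                rx.getId(),
                rx.getName() or rx.getId(),
                stoich,
                reversible=bool(rx.getReversible()),
                lower_bound=lb,
                upper_bound=ub,
                genes=genes,
                gene_rule=rule,
                ec_number=notes.get("ec_number"),
                subsystem=notes.get("subsystem"),
            )
        )
    return NetworkDocument(net, provenance=f"sbml:{source}")


# ---------------------------------------------------------------------------
# reaction tables
# ---------------------------------------------------------------------------

_ARROWS = [
    ("<=>", True), ("<->", True), ("⇔", True),
    ("=>", False), ("->", False), ("⇒", False),
]

_TERM_RE = re.compile(r"^(?:(\d+(?:/\d+)?(?:\.\d+)?)\s+)?(\S+)$")


def _parse_side(text: str, sign: int, stoich: dict[str, Fraction]) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"cannot parse term {term!r}")
        coeff = Fraction(m.group(1)) if m.group(1) else Fraction(1)
        met = m.group(2)
        stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``2 A + B -> C`` style equations; returns (stoichiometry, reversible)."""
    for arrow, reversible in _ARROWS:
        if arrow in text:
            left, right = text.split(arrow, 1)
            stoich: dict[str, Fraction] = {}
            _parse_side(left, -1, stoich)
            _parse_side(right, +1, stoich)
            stoich = {m: c for m, c in stoich.items() if c != 0}
            if not stoich:
                raise ValueError("equation has no net conversion")
            return stoich, reversible
    raise ValueError(f"no reaction arrow found in {text!r}")


_TABLE_COLUMNS = [
    "id", "name", "equation", "lower_bound", "upper_bound",
    "genes", "gene_rule", "ec_number", "subsystem",
]


def _compartment_of(met_id: str) -> str:
    return EXTRACELLULAR if met_id.endswith("_e") else CYTOPLASM


def read_reaction_table(source: Union[str, Path]) -> NetworkDocument:
    """Read a TSV reaction table into a network.

    Metabolites are created on first reference; ids ending in ``_e`` are
    extracellular and flagged as boundary species.  Unparseable rows raise
    :class:`ReactionTableError` with the offending line number.
    """
    path = Path(source)
    lines = path.read_text().splitlines()
    if not lines:
        raise ReactionTableError(1, "empty reaction table")
    header = lines[0].rstrip("\n").split("\t")
    if "id" not in header or "equation" not in header:
        raise ReactionTableError(1, "header must contain 'id' and 'equation' columns")
    net = MetabolicNetwork(name=path.stem)
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        values = line.split("\t")
        row = {k: (values[i].strip() if i < len(values) else "") for i, k in enumerate(header)}
        try:
            stoich, reversible = parse_equation(row["equation"])
        except ValueError as exc:
            raise ReactionTableError(ln, str(exc)) from exc
        if not row["id"]:
            raise ReactionTableError(ln, "missing reaction id")
        for met in stoich:
            if met not in net.metabolite_ids():
                comp = _compartment_of(met)
                net.add_metabolite(
                    Metabolite(met, met, comp, is_boundary=(comp == EXTRACELLULAR))
                )
        genes = tuple(g for g in row.get("genes", "").split(";") if g)
        try:
            net.add_reaction(
                Reaction(
                    row["id"],
                    row.get("name") or row["id"],
                    stoich,
                    reversible=reversible,
                    lower_bound=float(row["lower_bound"]) if row.get("lower_bound") else None,
                    upper_bound=float(row["upper_bound"]) if row.get("upper_bound") else None,
                    genes=genes,
                    gene_rule=row.get("gene_rule") or "and",
                    ec_number=row.get("ec_number") or None,
                    subsystem=row.get("subsystem") or None,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ReactionTableError(ln, str(exc)) from exc
    return NetworkDocument(net, provenance=f"table:{source}")


def write_reaction_table(network: MetabolicNetwork, destination: Union[str, Path]) -> None:
    """Write the TSV reaction table (deterministic, byte-stable)."""
    rows = ["\t".join(_TABLE_COLUMNS)]
    for r in network.reactions:
        rows.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    r.equation(),
                    "" if r.lower_bound is None else repr(float(r.lower_bound)),
                    "" if r.upper_bound is None else repr(float(r.upper_bound)),
                    ";".join(r.genes),
                    r.gene_rule,
                    r.ec_number or "",
                    r.subsystem or "",
                ]
            )
        )
    Path(destination).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# matrix exports
# ---------------------------------------------------------------------------

def write_matrix_tsv(network: MetabolicNetwork, destination: Union[str, Path]) -> None:
    """Dense stoichiometric matrix as TSV (rows metabolites, cols reactions)."""
    S = stoichiometric_matrix(network, dtype="fraction")
    lines = ["\t".join([""] + network.reaction_ids())]
    for i, m in enumerate(network.metabolites):
        lines.append("\t".join([m.id] + [str(S[i, j]) for j in range(S.shape[1])]))
    Path(destination).write_text("\n".join(lines) + "\n")


def write_matrix_triplets(network: MetabolicNetwork, destination: Union[str, Path]) -> None:
    """Sparse coordinate-triplet export: metabolite, reaction, coefficient."""
    lines = ["metabolite\treaction\tcoefficient"]
    for r in network.reactions:
        for met in r.stoichiometry:
            lines.append(f"{met}\t{r.id}\t{r.stoichiometry[met]}")
    Path(destination).write_text("\n".join(lines) + "\n")
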