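"""Curated fatty-acid biosynthesis network of *Exiguobacterium antarcticum* B7.

The network covers de-novo fatty-acid synthesis from acetyl-CoA: carboxylation
to malonyl-CoA (AccABCD complex), transfer onto the acyl carrier protein
(FabD), chain initiation (FabH1), six elongation rounds of the
condensation/reduction/dehydration/enoyl-reduction cycle (FabF, FabG, FabZ,
FabI) growing the acyl-ACP chain from C4 to C16, desaturation of
hexadecanoyl-ACP to hexadecenoyl-ACP (locus Eab7_2235), and release of
hexadecenoic acid, the target product of the cold-adaptation analysis.

The published description fixes the end points of the reconstruction — a
54-metabolite x 59-reaction matrix, an optimal hexadecenoate yield of
7.69 per 100 acetyl-CoA, and a census of 13 elementary flux modes of which
4 produce hexadecenoate — but not the full reaction list.  The inventory
here was reconciled against those outputs; every choice that was open is
described in the module docstrings and the methods note (docs/methods.md).
Noteworthy reconciliation choices:

* Protons are balanced.  Each reduction step (FabG, FabI) consumes one
  H+; thioester hydrolysis on product release liberates one.  The net
  proton demand of one hexadecenoate is therefore 14 - 1 = 13, and with
  every exchange capped at 100 this proton budget — not the carbon budget —
  is what limits the optimal yield to 100/13 = 7.69.
* Malonyl-CoA can also be acquired from the boundary through an energized
  (proton-consuming) import, which is what allows elementary modes that
  enter the pathway at FabD (R2) without running the carboxylase (R1).
* NADPH is supplied either directly or from NADH via a soluble
  transhydrogenase.
* Acyl-ACP thioesterases release octanoate (C8) and tetradecanoate (C14)
  in addition to the C16:1 product, giving the network its short-chain
  escape routes.
* Excess acetyl-CoA drains to energy metabolism (the uptake is fixed while
  the proton budget limits synthesis, so a drain is required for
  feasibility).
* The literal C2 condensation of FabF (acetyl-ACP + malonyl-ACP) is kept in
  the inventory as printed, but acetyl-ACP has no producing reaction, so the
  reaction is structurally blocked; initiation proceeds through FabH1.
"""
from __future__ import annotations

from fractions import Fraction
from typing import Optional, Sequence

from .core import (
    CYTOPLASM,
    EXTRACELLULAR,
    MetabolicNetwork,
    Metabolite,
    Reaction,
)

__all__ = [
    "ACYL_KINDS",
    "CURATED_METABOLITES",
    "CURATED_REACTIONS",
    "EXPECTED_SHAPE",
    "build_curated_network",
    "generate_elongation_round",
    "reductive_half_cycle",
    "ACC_UPTAKE_ID",
    "PRODUCT_SECRETION_ID",
    "ACC_CARBOXYLASE_ID",
    "FABD_ID",
]

EXPECTED_SHAPE = (54, 59)

ACC_CARBOXYLASE_ID = "R1"   # acetyl-CoA carboxylase (AccABCD)
FABD_ID = "R2"              # malonyl-CoA:ACP transacylase
ACC_UPTAKE_ID = "R39"       # acetyl-CoA uptake, fixed to 100 in the reference FBA
PRODUCT_SECRETION_ID = "R41"  # hexadecenoate secretion, the FBA objective

ACYL_KINDS = ("oxo", "hydroxy", "enoyl", "acyl")

_ACYL_NAMES = {
    ("oxo", 4): "acetoacetyl-ACP",
    ("hydroxy", 4): "(R)-3-hydroxybutanoyl-ACP",
    ("enoyl", 4): "but-2-enoyl-ACP",
    ("acyl", 4): "butyryl-ACP",
}

_CHAIN_NAMES = {
    4: "butanoyl", 6: "hexanoyl", 8: "octanoyl", 10: "decanoyl",
    12: "dodecanoyl", 14: "tetradecanoyl", 16: "hexadecanoyl",
}

# Gene-protein-reaction data from the curated annotation.  The acetyl-CoA
# carboxylase is a four-subunit complex (AND rule); all other enzymes are
# single gene products.
GPR = {
    "acc": (("Eab7_2059", "Eab7_0870", "Eab7_0871", "Eab7_2060"), "and", "6.4.1.2"),
    "fabD": (("Eab7_1760",), "and", "2.3.1.39"),
    "fabH1": (("Eab7_1911",), "and", "2.3.1.180"),
    "fabF": (("Eab7_1910",), "and", "2.3.1.179"),
    "fabG": (("Eab7_1895",), "and", "1.1.1.100"),
    "fabZ": (("Eab7_2463",), "and", "4.2.1.59"),
    "fabI": (("Eab7_1885",), "and", "1.3.1.10"),
    "desaturase": (("Eab7_2235",), "and", "1.14.19.2"),
}


def _acyl_id(kind: str, n: int) -> str:
    return f"{kind}{n}_acp"


def _acyl_name(kind: str, n: int) -> str:
    if (kind, n) in _ACYL_NAMES:
        return _ACYL_NAMES[(kind, n)]
    chain = _CHAIN_NAMES[n]
    return {
        "oxo": f"3-oxo{chain}-ACP",
        "hydroxy": f"(R)-3-hydroxy{chain}-ACP",
        "enoyl": f"trans-2-{chain[:-2]}enoyl-ACP",
        "acyl": f"{chain}-ACP",
    }[kind]


def _met(mid, name, compartment=CYTOPLASM, carbon=None, boundary=False) -> Metabolite:
    return Metabolite(mid, name, compartment, carbon, boundary)


def curated_metabolites() -> list[Metabolite]:
    """The 54 species of the curated model, in matrix row order."""
    mets = [
        _met("atp", "ATP"),
        _met("adp", "ADP"),
        _met("pi", "orthophosphate"),
        _met("hco3", "bicarbonate", carbon=1),
        _met("co2", "CO2", carbon=1),
        _met("accoa", "acetyl-CoA", carbon=2),
        _met("malcoa", "malonyl-CoA", carbon=3),
        _met("coa", "coenzyme A", carbon=0),
        _met("acp", "acyl carrier protein", carbon=0),
        _met("malacp", "malonyl-ACP", carbon=3),
        _met("acacp", "acetyl-ACP", carbon=2),
        _met("nadph", "NADPH"),
        _met("nadp", "NADP+"),
        _met("nadh", "NADH"),
        _met("nad", "NAD+"),
        _met("h", "H+"),
        _met("h2o", "H2O"),
        _met("o2", "O2"),
        _met("acceptor_red", "reduced electron acceptor"),
        _met("acceptor_ox", "oxidized electron acceptor"),
        _met("hexadecenoyl_acp", "hexadecenoyl-ACP", carbon=16),
        _met("hexadecenoate", "hexadecenoic acid", carbon=16),
    ]
    for n in range(4, 18, 2):
        for kind in ACYL_KINDS:
            mets.append(_met(_acyl_id(kind, n), _acyl_name(kind, n), carbon=n))
    mets += [
        _met("accoa_e", "acetyl-CoA (extracellular)", EXTRACELLULAR, carbon=2, boundary=True),
        _met("hexadecenoate_e", "hexadecenoic acid (extracellular)", EXTRACELLULAR,
             carbon=16, boundary=True),
        _met("o2_e", "O2 (extracellular)", EXTRACELLULAR, boundary=True),
        _met("co2_e", "CO2 (extracellular)", EXTRACELLULAR, carbon=1, boundary=True),
    ]
    return mets


def _gpr_reaction(rid, name, stoich, key=None, reversible=False, subsystem=None) -> Reaction:
    genes, rule, ec = GPR[key] if key else ((), "and", None)
    return Reaction(
        rid, name, {m: Fraction(c) for m, c in stoich.items()},
        reversible=reversible, genes=genes, gene_rule=rule, ec_number=ec,
        subsystem=subsystem,
    )


def reductive_half_cycle(chain_length: int, ids: Optional[Sequence[str]] = None) -> list[Reaction]:
    """FabG/FabZ/FabI trio reducing 3-oxoacyl-ACP(Cn) to acyl-ACP(Cn).

    This is the reductive half of one elongation round: NADPH-dependent
    ketoreduction, dehydration releasing water, and NADH-dependent enoyl
    reduction.  All three steps are reversible.
    """
    n = chain_length
    if n % 2 or not 4 <= n <= 16:
        raise ValueError(f"chain_length must be an even integer in [4, 16], got {n}")
    if ids is None:
        ids = (f"fabG_C{n}", f"fabZ_C{n}", f"fabI_C{n}")
    g, z, i = ids
    return [
        _gpr_reaction(
            g, f"3-oxoacyl-ACP reductase (C{n})",
            {_acyl_id("oxo", n): -1, "nadph": -1, "h": -1,
             _acyl_id("hydroxy", n): 1, "nadp": 1},
            key="fabG", reversible=True, subsystem="elongation",
        ),
        _gpr_reaction(
            z, f"3-hydroxyacyl-ACP dehydratase (C{n})",
            {_acyl_id("hydroxy", n): -1, _acyl_id("enoyl", n): 1, "h2o": 1},
            key="fabZ", reversible=True, subsystem="elongation",
        ),
        _gpr_reaction(
            i, f"enoyl-ACP reductase (C{n})",
            {_acyl_id("enoyl", n): -1, "nadh": -1, "h": -1,
             _acyl_id("acyl", n): 1, "nad": 1},
            key="fabI", reversible=True, subsystem="elongation",
        ),
    ]


def generate_elongation_round(
    chain_length: int, ids: Optional[Sequence[str]] = None
) -> list[Reaction]:
    """One full elongation round starting from acyl-ACP(C ``chain_length``).

    Returns four reactions: the irreversible FabF condensation with
    malonyl-ACP (adding two carbons and releasing CO2 and the spent ACP of
    the growing chain's partner) followed by the reversible FabG/FabZ/FabI
    reductive half-cycle on the extended chain.  The net effect is
    acyl-ACP(Cn) -> acyl-ACP(Cn+2).
    """
    n = chain_length
    if n % 2 or not 4 <= n <= 14:
        raise ValueError(f"chain_length must be an even integer in [4, 14], got {n}")
    m = n + 2
    if ids is None:
        ids = (f"fabF_C{m}", f"fabG_C{m}", f"fabZ_C{m}", f"fabI_C{m}")
    cond = _gpr_reaction(
        ids[0], f"3-oxoacyl-ACP synthase II (C{n}->C{m})",
        {_acyl_id("acyl", n): -1, "malacp": -1,
         _acyl_id("oxo", m): 1, "co2": 1, "acp": 1},
        key="fabF", subsystem="elongation",
    )
    return [cond] + reductive_half_cycle(m, ids=ids[1:])


def _exchange(rid, name, stoich, subsystem="exchange") -> Reaction:
    return Reaction(rid, name, {m: Fraction(c) for m, c in stoich.items()},
                    reversible=False, subsystem=subsystem)


def curated_reactions() -> list[Reaction]:
    """The 59 reactions of the curated model, in matrix column order."""
    rxns: list[Reaction] = []
    add = rxns.append

    # R1-R4: the committed steps and chain initiation (Table-2 equations).
    add(_gpr_reaction(
        "R1", "acetyl-CoA carboxylase",
        {"atp": -1, "accoa": -1, "hco3": -1, "adp": 1, "pi": 1, "malcoa": 1},
        key="acc", subsystem="initiation",
    ))
    add(_gpr_reaction(
        "R2", "malonyl-CoA:ACP transacylase",
        {"malcoa": -1, "acp": -1, "coa": 1, "malacp": 1},
        key="fabD", reversible=True, subsystem="initiation",
    ))
    add(_gpr_reaction(
        "R3", "3-oxoacyl-ACP synthase III (initiation)",
        {"accoa": -1, "malacp": -1, "oxo4_acp": 1, "coa": 1, "co2": 1},
        key="fabH1", reversible=True, subsystem="initiation",
    ))
    # The literal FabF C2 condensation; acetyl-ACP has no producing reaction
    # in this reconstruction, so the reaction is retained but carries no flux.
    add(_gpr_reaction(
        "R4", "3-oxoacyl-ACP synthase II (C2 condensation)",
        {"acacp": -1, "malacp": -1, "oxo4_acp": 1, "co2": 1, "acp": 1},
        key="fabF", subsystem="initiation",
    ))

    # R5-R7: reductive half-cycle on the C4 primer.
    k = 5
    for r in reductive_half_cycle(4, ids=(f"R{k}", f"R{k+1}", f"R{k+2}")):
        add(r)
    k += 3
    # R8-R31: six elongation rounds C4 -> C16.
    for n in range(4, 16, 2):
        for r in generate_elongation_round(n, ids=tuple(f"R{k+i}" for i in range(4))):
            add(r)
        k += 4
    assert k == 32

    # R32: acyl-ACP desaturase (Eab7_2235).
    add(_gpr_reaction(
        "R32", "acyl-ACP desaturase",
        {"acyl16_acp": -1, "acceptor_red": -1, "o2": -1,
         "hexadecenoyl_acp": 1, "acceptor_ox": 1, "h2o": 2},
        key="desaturase", subsystem="desaturation",
    ))
    # R33: soluble transhydrogenase, the alternative NADPH supply.
    add(Reaction(
        "R33", "NAD(P) transhydrogenase",
        {"nadh": Fraction(-1), "nadp": Fraction(-1),
         "nad": Fraction(1), "nadph": Fraction(1)},
        subsystem="cofactor",
    ))
    # R34/R35: acyl-ACP thioesterases releasing the short/medium-chain free
    # acids (octanoate, tetradecanoate).  The free acids leave the modelled
    # system on release, so these reactions are boundary releases.
    add(Reaction(
        "R34", "acyl-ACP thioesterase (octanoate release)",
        {"acyl8_acp": Fraction(-1), "h2o": Fraction(-1),
         "acp": Fraction(1), "h": Fraction(1)},
        subsystem="release",
    ))
    add(Reaction(
        "R35", "acyl-ACP thioesterase (tetradecanoate release)",
        {"acyl14_acp": Fraction(-1), "h2o": Fraction(-1),
         "acp": Fraction(1), "h": Fraction(1)},
        subsystem="release",
    ))
    # R36: thioesterase releasing the C16:1 product into the cytoplasm.
    add(Reaction(
        "R36", "acyl-ACP thioesterase (hexadecenoate release)",
        {"hexadecenoyl_acp": Fraction(-1), "h2o": Fraction(-1),
         "hexadecenoate": Fraction(1), "acp": Fraction(1), "h": Fraction(1)},
        subsystem="release",
    ))

    # R37-R59: exchanges and transports.  R39 is the acetyl-CoA uptake fixed
    # to 100 in the reference FBA; R41 carries the hexadecenoate product.
    add(_exchange("R37", "acetyl-CoA supply", {"accoa_e": 1}))
    add(_exchange("R38", "ATP exchange", {"atp": 1}))
    add(_exchange("R39", "acetyl-CoA uptake", {"accoa_e": -1, "accoa": 1},
                  subsystem="transport"))
    add(_exchange("R40", "acetyl-CoA drain to energy metabolism", {"accoa": -1}))
    add(_exchange("R41", "hexadecenoate secretion",
                  {"hexadecenoate": -1, "hexadecenoate_e": 1}, subsystem="transport"))
    add(_exchange("R42", "hexadecenoate exchange", {"hexadecenoate_e": -1}))
    add(_exchange("R43", "malonyl-CoA acquisition (energized import)",
                  {"h": -1, "malcoa": 1}))
    add(_exchange("R44", "bicarbonate exchange", {"hco3": 1}))
    add(_exchange("R45", "NADPH exchange", {"nadph": 1}))
    add(_exchange("R46", "NADH exchange", {"nadh": 1}))
    add(_exchange("R47", "H+ exchange", {"h": 1}))
    add(_exchange("R48", "O2 supply", {"o2_e": 1}))
    add(_exchange("R49", "O2 uptake", {"o2_e": -1, "o2": 1}, subsystem="transport"))
    add(_exchange("R50", "reduced acceptor exchange", {"acceptor_red": 1}))
    add(_exchange("R51", "ADP exchange", {"adp": -1}))
    add(_exchange("R52", "orthophosphate exchange", {"pi": -1}))
    add(_exchange("R53", "CoA exchange", {"coa": -1}))
    add(_exchange("R54", "NADP+ exchange", {"nadp": -1}))
    add(_exchange("R55", "NAD+ exchange", {"nad": -1}))
    add(_exchange("R56", "oxidized acceptor exchange", {"acceptor_ox": -1}))
    add(_exchange("R57", "H2O exchange", {"h2o": -1}))
    add(_exchange("R58", "CO2 export", {"co2": -1, "co2_e": 1}, subsystem="transport"))
    add(_exchange("R59", "CO2 exchange", {"co2_e": -1}))
    return rxns


CURATED_METABOLITES = tuple(m.id for m in curated_metabolites())
CURATED_REACTIONS = tuple(r.id for r in curated_reactions())


def build_curated_network() -> MetabolicNetwork:
    """Build the curated 54 x 59 fatty-acid biosynthesis network.

    The construction is deterministic: repeated calls return identical
    orderings and coefficients.  A :class:`RuntimeError` is raised if the
    inventory ever deviates from the expected 54 x 59 dimensions, since that
    signals a regression in the curated reaction list.
    """
    net = MetabolicNetwork(
        metabolites=curated_metabolites(),
        reactions=curated_reactions(),
        name="E_antarcticum_B7_fab",
        metadata={"organism": "Exiguobacterium antarcticum B7",
                  "pathway": "fatty acid biosynthesis"},
    )
    if net.shape != EXPECTED_SHAPE:
        raise RuntimeError(
            f"curated inventory regression: expected {EXPECTED_SHAPE}, got {net.shape}"
        )
    return net
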