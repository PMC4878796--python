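"""The Wnt/β-catenin signaling network as a Petri net.

Biology, coarse-grained
-----------------------
β-catenin (gene symbol CTNNB1) is produced constitutively and, in the
resting cell, captured and degraded by the *destruction complex* (DC:
AXIN, APC, CK1, GSK3).  An extracellular WNT ligand binds its receptors
FZD and LRP (t1); DVL joins the receptor complex (t2) and sequesters
AXIN to the membrane, forming the *signalosome* (t3), which dissociates
slowly (t4, rate 0.1 = once per 10 steps).  Sequestration of AXIN starves
DC formation (t5), so β-catenin accumulates, translocates to the nucleus
and binds TCF/LEF (t10; needs 3 tokens, consumes 1), activating
transcription of the negative feedback gene AXIN2 (t11), which can
replenish the cytoplasmic AXIN pool.  The DC binds β-catenin (t6) and
degrades it, after which the complex is either reused (t7) or falls
apart into its components (t8).  β-catenin itself is expressed every
step (t9) through the standard gene-expression motif: the gene place
holds one token that is required and re-produced, never consumed.

The wildtype net has 18 places, 11 transitions and 41 arcs.  Scenario
knobs: initial WNT tokens (stimulation, 0–5), initial GSK3 tokens
(inhibition, 5 = wildtype, 0 = complete inhibition), the t11→AXIN
feedback weight (0 = off … 0.15 = maximal, three transfers per 20
steps), and the t5→DC production weight (1 = wildtype; 0.2/0.1/0.05/0
emulate APC-inactivating mutations of increasing severity — in mutant
mode t5 gains four return arcs of weight 1−w so that each component is
only *net*-consumed once per 1/w firings).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

from .core import Arc, PetriNet, Weight, as_weight

__all__ = [
    "PLACES",
    "TRANSITIONS",
    "BETA_CATENIN_PLACES",
    "WntScenario",
    "build_wnt_net",
    "total_beta_catenin",
]

#: The 18 places: genes, proteins and complexes of the pathway.
PLACES: tuple[str, ...] = (
    "WNT",
    "FZD",
    "LRP",
    "WNT_FZD_LRP",
    "DVL",
    "WNT_FZD_LRP_DVL",
    "AXIN",
    "signalosome",
    "APC",
    "CK1",
    "GSK3",
    "DC",
    "DC_CTNNB1",
    "CTNNB1_gene",
    "CTNNB1_protein",
    "TCF_LEF",
    "TCF_LEF_CTNNB1",
    "AXIN2_gene",
)

#: The 11 transitions, in mechanistic order.
TRANSITIONS: tuple[str, ...] = tuple(f"t{i}" for i in range(1, 12))

#: Places whose tokens are β-catenin in some form (free, DC-bound, TCF-bound).
BETA_CATENIN_PLACES: tuple[str, ...] = ("CTNNB1_protein", "DC_CTNNB1", "TCF_LEF_CTNNB1")


@dataclass
class WntScenario:
    """One named simulation condition.

    Defaults are the wildtype baseline: no WNT stimulus, full GSK3,
    feedback off, normal DC production, 100 steps × 100 replicates.
    """

    initial_wnt: int = 0
    initial_gsk3: int = 5
    axin2_feedback_weight: Weight = 0
    apc_dc_production_weight: Weight = 1
    steps: int = 100
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= int(self.initial_wnt) <= 5):
            raise ValueError("initial_wnt must be an integer in 0..5")
        if not (0 <= int(self.initial_gsk3) <= 5):
            raise ValueError("initial_gsk3 must be an integer in 0..5")
        self.initial_wnt = int(self.initial_wnt)
        self.initial_gsk3 = int(self.initial_gsk3)
        self.axin2_feedback_weight = as_weight(self.axin2_feedback_weight)
        if not (0 <= self.axin2_feedback_weight <= Fraction(3, 20)):
            raise ValueError("axin2_feedback_weight must lie in [0, 0.15]")
        self.apc_dc_production_weight = as_weight(self.apc_dc_production_weight)
        if not (0 <= self.apc_dc_production_weight <= 1):
            raise ValueError("apc_dc_production_weight must lie in [0, 1]")
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")


def build_wnt_net(scenario: WntScenario | None = None) -> PetriNet:
    """Construct the pathway net for one scenario.

    The wildtype net has exactly 18 places, 11 transitions and 41 arcs —
    the t11→AXIN feedback arc is always present (at weight 0 it is
    inert and does not affect execution).  APC-mutant mode
    (``apc_dc_production_weight < 1``) adds four component-return arcs
    on t5 with weight ``1 − w``, for 45 arcs.
    """
    s = scenario or WntScenario()
    one = Fraction(1)
    tenth = Fraction(1, 10)
    w_dc = s.apc_dc_production_weight
    w_fb = s.axin2_feedback_weight

    arcs: list[Arc] = [
        # t1: WNT + FZD + LRP -> WNT/FZD/LRP
        Arc("WNT", "t1"), Arc("FZD", "t1"), Arc("LRP", "t1"),
        Arc("t1", "WNT_FZD_LRP"),
        # t2: WNT/FZD/LRP + DVL -> WNT/FZD/LRP/DVL
        Arc("WNT_FZD_LRP", "t2"), Arc("DVL", "t2"),
        Arc("t2", "WNT_FZD_LRP_DVL"),
        # t3: WNT/FZD/LRP/DVL + AXIN -> signalosome
        Arc("WNT_FZD_LRP_DVL", "t3"), Arc("AXIN", "t3"),
        Arc("t3", "signalosome"),
        # t4: slow signalosome dissociation, once per 10 steps
        Arc("signalosome", "t4", tenth),
        Arc("t4", "WNT_FZD_LRP_DVL", tenth), Arc("t4", "AXIN", tenth),
        # t5: AXIN + APC + CK1 + GSK3 -> destruction complex
        Arc("AXIN", "t5"), Arc("APC", "t5"), Arc("CK1", "t5"), Arc("GSK3", "t5"),
        Arc("t5", "DC", w_dc),
        # t6: DC captures beta-catenin
        Arc("DC", "t6"), Arc("CTNNB1_protein", "t6"),
        Arc("t6", "DC_CTNNB1"),
        # t7: degradation, complex reused
        Arc("DC_CTNNB1", "t7"), Arc("t7", "DC"),
        # t8: degradation, complex dissociates
        Arc("DC_CTNNB1", "t8"),
        Arc("t8", "AXIN"), Arc("t8", "APC"), Arc("t8", "CK1"), Arc("t8", "GSK3"),
        # t9: constitutive beta-catenin expression (gene-expression motif)
        Arc("CTNNB1_gene", "t9"),
        Arc("t9", "CTNNB1_gene"), Arc("t9", "CTNNB1_protein"),
        # t10: nuclear translocation + TCF/LEF binding (needs 3, consumes 1;
        # TCF/LEF is catalytic: read-arc pair)
        Arc("CTNNB1_protein", "t10", 3), Arc("TCF_LEF", "t10"),
        Arc("t10", "CTNNB1_protein", 2), Arc("t10", "TCF_LEF"),
        Arc("t10", "TCF_LEF_CTNNB1"),
        # t11: AXIN2 transcription (gene motif; activator complex is
        # required but not consumed); feedback arc to AXIN, possibly inert
        Arc("TCF_LEF_CTNNB1", "t11"), Arc("AXIN2_gene", "t11"),
        Arc("t11", "TCF_LEF_CTNNB1"), Arc("t11", "AXIN2_gene"),
        Arc("t11", "AXIN", w_fb),
    ]
    if w_dc < 1:
        # mutant mode: components are returned at rate 1-w, so the net
        # consumption matches the reduced DC production rate
        ret = one - w_dc
        arcs += [
            Arc("t5", "AXIN", ret), Arc("t5", "APC", ret),
            Arc("t5", "CK1", ret), Arc("t5", "GSK3", ret),
        ]

    marking = {
        "WNT": s.initial_wnt,
        "FZD": 5, "LRP": 5, "DVL": 5,
        "AXIN": 5, "APC": 5, "CK1": 5,
        "GSK3": s.initial_gsk3,
        "TCF_LEF": 1, "CTNNB1_gene": 1, "AXIN2_gene": 1,
        # complexes and free beta-catenin start empty
    }
    return PetriNet(
        places=PLACES,
        transitions=TRANSITIONS,
        arcs=tuple(arcs),
        initial_marking=marking,
        name="wnt_beta_catenin",
    )


def total_beta_catenin(marking: Mapping[str, int]) -> int:
    """Total β-catenin: free + DC-bound + TCF/LEF-bound tokens."""
    return sum(marking[p] for p in BETA_CATENIN_PLACES)
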