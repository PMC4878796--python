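"""Maximally parallel, stochastic token-game execution.

Semantics
---------
Time advances in discrete steps.  Within one step the engine fires as
many transitions (with multiplicity) as the marking allows — *maximal
parallelism* — building the step's firing multiset by iterated random
reservation:

1. among the transitions enabled against the tokens not yet reserved in
   this step, draw one uniformly at random;
2. reserve its input tokens and increment its firing count;
3. repeat until no transition is enabled against the residual tokens.

Competition for a shared input place is therefore resolved by an
unbiased draw, and after the loop terminates no further transition could
fire: the multiset is maximal by construction.

Integer arc weights are token counts per firing.  A fractional weight
``w = p/q`` is a *firing rate*: each firing adds ``w`` to that arc's
credit accumulator, and a token is transferred whenever the accumulated
credit reaches 1 (the integer part is transferred, the remainder kept).
Credit is exact rational arithmetic, so a continuously enabled
transition with ``w = p/q`` transfers exactly ``p`` tokens in every
``q`` consecutive steps — ``0.1`` is "once every 10 steps", ``0.15``
"three times every 20 steps" — with no drift, ever.  Because per-firing
credit is only well defined at one firing per step, any transition
carrying a fractional arc is capped at a single firing per step.
Enabling across a fractional input arc requires ``ceil(w)`` (i.e. one)
token: the transition waits on a real token even on steps where none is
consumed.

All tokens produced in step *k* become visible — and consumable — only
at step *k+1* (end-of-step production), the standard maximal-step
convention.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .core import PetriNet, validate_net

__all__ = [
    "EngineState",
    "Trace",
    "EnsembleSummary",
    "initial_state",
    "enabled",
    "sample_step_firing",
    "apply_firing",
    "simulate",
    "run_ensemble",
    "replicate_seed",
]

logger = logging.getLogger(__name__)

ZERO = Fraction(0)


# ---------------------------------------------------------------------------
# compiled net: index-based structures for the hot loop
# ---------------------------------------------------------------------------

class _Compiled:
    """Pre-resolved arc lists per transition, indexed over places.

    Zero-weight arcs are inert (no enabling requirement, no transfer)
    and are dropped here, so a feedback arc "switched off" at weight 0
    leaves the executed net — and hence the random number stream —
    bit-identical to a net without the arc.
    """

    def __init__(self, net: PetriNet):
        issues = validate_net(net)
        if issues:
            raise ValueError("invalid net: " + "; ".join(issues))
        self.net = net
        self.place_index = {p: i for i, p in enumerate(net.places)}
        self.trans_index = {t: i for i, t in enumerate(net.transitions)}
        self.transitions = list(net.transitions)
        n_t = len(self.transitions)
        self.thresholds: list[list[tuple[int, int]]] = [[] for _ in range(n_t)]
        self.in_int: list[list[tuple[int, int]]] = [[] for _ in range(n_t)]
        self.out_int: list[list[tuple[int, int]]] = [[] for _ in range(n_t)]
        # fractional arcs get a credit slot: (slot, place, weight)
        self.in_frac: list[list[tuple[int, int, Fraction]]] = [[] for _ in range(n_t)]
        self.out_frac: list[list[tuple[int, int, Fraction]]] = [[] for _ in range(n_t)]
        self.frac_arcs: list[tuple[str, str]] = []  # slot -> (source, target)
        self.has_frac = [False] * n_t
        self.cap_one = [False] * n_t

        for arc in net.arcs:
            if arc.weight == 0:
                continue
            if arc.source in self.trans_index:  # output arc
                ti = self.trans_index[arc.source]
                pi = self.place_index[arc.target]
                if arc.is_fractional:
                    slot = len(self.frac_arcs)
                    self.frac_arcs.append((arc.source, arc.target))
                    self.out_frac[ti].append((slot, pi, arc.weight))
                    self.has_frac[ti] = True
                else:
                    self.out_int[ti].append((pi, int(arc.weight)))
            else:  # input arc
                ti = self.trans_index[arc.target]
                pi = self.place_index[arc.source]
                self.thresholds[ti].append((pi, math.ceil(arc.weight)))
                if arc.is_fractional:
                    slot = len(self.frac_arcs)
                    self.frac_arcs.append((arc.source, arc.target))
                    self.in_frac[ti].append((slot, pi, arc.weight))
                    self.has_frac[ti] = True
                else:
                    self.in_int[ti].append((pi, int(arc.weight)))

        # fractional credit is only well defined at one firing per step;
        # a source transition with no input arcs must also be capped or
        # the reservation loop would never terminate.
        for ti in range(n_t):
            self.cap_one[ti] = self.has_frac[ti] or not self.thresholds[ti]

    def marking_list(self, marking: Mapping[str, int]) -> list[int]:
        return [marking[p] for p in self.net.places]

    def marking_dict(self, values: Sequence[int]) -> dict[str, int]:
        return dict(zip(self.net.places, values))

    def credit_list(self, ledger: Mapping[tuple[str, str], Fraction]) -> list[Fraction]:
        return [ledger.get(key, ZERO) for key in self.frac_arcs]

    def credit_dict(self, values: Sequence[Fraction]) -> dict[tuple[str, str], Fraction]:
        return {key: v for key, v in zip(self.frac_arcs, values)}

    # -- one step -----------------------------------------------------------

    def sample(self, marking: list[int], rng: np.random.Generator) -> dict[int, int]:
        """Iterated random reservation; returns transition index -> count."""
        unreserved = marking.copy()
        counts: dict[int, int] = {}
        n_t = len(self.transitions)
        while True:
            candidates = [
                ti
                for ti in range(n_t)
                if not (self.cap_one[ti] and counts.get(ti, 0) >= 1)
                and all(unreserved[pi] >= need for pi, need in self.thresholds[ti])
            ]
            if not candidates:
                return counts
            ti = candidates[int(rng.integers(len(candidates)))]
            for pi, need in self.thresholds[ti]:
                unreserved[pi] -= need
            counts[ti] = counts.get(ti, 0) + 1

    def apply(
        self,
        marking: list[int],
        credit: list[Fraction],
        counts: Mapping[int, int],
    ) -> tuple[list[int], list[Fraction]]:
        new = marking.copy()
        credit = credit.copy()
        for ti, k in counts.items():
            for pi, w in self.in_int[ti]:
                new[pi] -= w * k
            for slot, pi, w in self.in_frac[ti]:
                c = credit[slot] + w * k
                moved = math.floor(c)
                credit[slot] = c - moved
                new[pi] -= moved
            for pi, w in self.out_int[ti]:
                new[pi] += w * k
            for slot, pi, w in self.out_frac[ti]:
                c = credit[slot] + w * k
                moved = math.floor(c)
                credit[slot] = c - moved
                new[pi] += moved
        if any(v < 0 for v in new):
            raise RuntimeError(
                "internal consistency error: reservation produced a negative marking"
            )
        return new, credit


# ---------------------------------------------------------------------------
# public state / result containers
# ---------------------------------------------------------------------------

@dataclass
class EngineState:
    """Marking, per-arc fractional credit, step counter and RNG of one run."""

    marking: dict[str, int]
    credit: dict[tuple[str, str], Fraction]
    step_index: int
    rng: np.random.Generator


def initial_state(net: PetriNet, seed: int) -> EngineState:
    """Fresh state: initial marking, zero credit everywhere, seeded RNG."""
    return EngineState(
        marking=dict(net.initial_marking),
        credit={},
        step_index=0,
        rng=np.random.default_rng(seed),
    )


@dataclass
class Trace:
    """One run: ``markings[k]`` is the state after step *k* (index 0 =
    initial marking) and ``firings[k]`` the firing counts of step *k+1*."""

    markings: list[dict[str, int]]
    firings: list[dict[str, int]]

    @property
    def steps(self) -> int:
        return len(self.firings)

    def observable(self, fn: Callable[[Mapping[str, int]], float]) -> np.ndarray:
        return np.array([fn(m) for m in self.markings], dtype=float)

    def to_frame(self):
        """Long/tidy table with columns step, place, tokens."""
        import pandas as pd

        records = [
            {"step": k, "place": p, "tokens": n}
            for k, m in enumerate(self.markings)
            for p, n in m.items()
        ]
        return pd.DataFrame.from_records(records)


@dataclass
class EnsembleSummary:
    """Per-step mean and sample standard deviation of one observable."""

    observable: str
    steps: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    replicates: int
    base_seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "step": self.steps,
                "observable": self.observable,
                "mean": self.mean,
                "sd": self.sd,
            }
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def enabled(
    net: PetriNet,
    state: EngineState,
    t: str,
    reservations: Optional[Mapping[str, int]] = None,
) -> bool:
    """Is transition ``t`` enabled against the unreserved part of the marking?

    Each integer input arc requires its weight in tokens; a fractional
    input arc requires ``ceil(weight)`` — one real token — even though
    consumption only happens when credit reaches 1.
    """
    comp = _Compiled(net)
    if t not in comp.trans_index:
        raise KeyError(f"unknown transition {t!r}")
    ti = comp.trans_index[t]
    reservations = reservations or {}
    return all(
        state.marking[net.places[pi]] - reservations.get(net.places[pi], 0) >= need
        for pi, need in comp.thresholds[ti]
    )


def sample_step_firing(net: PetriNet, state: EngineState) -> dict[str, int]:
    """Draw one maximal firing multiset for the current step.

    Consumes randomness from ``state.rng``.  On return, no transition is
    enabled against the residual unreserved marking (maximality), and
    transitions carrying a fractional arc appear at most once.
    """
    comp = _Compiled(net)
    counts = comp.sample(comp.marking_list(state.marking), state.rng)
    return {comp.transitions[ti]: k for ti, k in counts.items()}


def apply_firing(net: PetriNet, state: EngineState, firing: Mapping[str, int]) -> EngineState:
    """Execute a firing multiset; returns the state at the next step boundary.

    Productions land in the returned state only (end-of-step), so
    nothing produced here was consumable when ``firing`` was sampled.
    """
    comp = _Compiled(net)
    counts = {comp.trans_index[t]: k for t, k in firing.items()}
    marking, credit = comp.apply(
        comp.marking_list(state.marking), comp.credit_list(state.credit), counts
    )
    return EngineState(
        marking=comp.marking_dict(marking),
        credit=comp.credit_dict(credit),
        step_index=state.step_index + 1,
        rng=state.rng,
    )


def simulate(net: PetriNet, steps: int, seed: int) -> Trace:
    """Run ``steps`` maximally parallel steps from the initial marking.

    A pure function of ``(net, steps, seed)``: identical arguments give
    bit-identical traces.  The credit ledger starts at zero.
    """
    if steps <= 0:
        raise ValueError("steps must be a positive integer")
    comp = _Compiled(net)
    rng = np.random.default_rng(seed)
    marking = comp.marking_list(net.initial_marking)
    credit = [ZERO] * len(comp.frac_arcs)
    markings = [comp.marking_dict(marking)]
    firings: list[dict[str, int]] = []
    for k in range(steps):
        counts = comp.sample(marking, rng)
        marking, credit = comp.apply(marking, credit, counts)
        markings.append(comp.marking_dict(marking))
        firings.append({comp.transitions[ti]: c for ti, c in counts.items()})
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug("step %d: fired %s", k + 1, firings[-1])
    return Trace(markings=markings, firings=firings)


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Seed of replicate ``replicate``: a plain counter, ``base_seed + r``."""
    return int(base_seed) + int(replicate)


def run_ensemble(
    net: PetriNet,
    steps: int,
    replicates: int,
    base_seed: int,
    observable: Callable[[Mapping[str, int]], float],
    observable_name: str = "observable",
) -> EnsembleSummary:
    """Repeat :func:`simulate` and summarise an observable per step.

    Replicate ``r`` runs with seed ``base_seed + r``.  The standard
    deviation is the sample SD (``ddof=1``); with a single replicate it
    is reported as 0 and a warning is emitted.
    """
    if replicates <= 0:
        raise ValueError("replicates must be a positive integer")
    values = np.empty((replicates, steps + 1), dtype=float)
    for r in range(replicates):
        trace = simulate(net, steps, replicate_seed(base_seed, r))
        values[r] = trace.observable(observable)
    mean = values.mean(axis=0)
    if replicates == 1:
        warnings.warn(
            "sample standard deviation is undefined for a single replicate; reporting 0",
            stacklevel=2,
        )
        sd = np.zeros(steps + 1)
    else:
        sd = values.std(axis=0, ddof=1)
    return EnsembleSummary(
        observable=observable_name,
        steps=np.arange(steps + 1),
        mean=mean,
        sd=sd,
        replicates=replicates,
        base_seed=int(base_seed),
    )
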