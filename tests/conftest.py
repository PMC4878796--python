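"""Shared fixtures: small nets and an independent brute-force oracle.

The oracle enumerates every maximal firing multiset reachable by the
reservation semantics, working directly on dict markings with its own
bookkeeping — it shares no code with the engine it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import pytest

from wntpetri.core import Arc, PetriNet


def enumerate_maximal_firings(net: PetriNet, marking: dict) -> set[frozenset]:
    """All maximal firing multisets from ``marking``, as frozensets of
    (transition, count) pairs.  Brute force over reservation orders."""
    thresholds: dict[str, list[tuple[str, int]]] = {t: [] for t in net.transitions}
    capped: dict[str, bool] = {t: False for t in net.transitions}
    for arc in net.arcs:
        if arc.weight == 0:
            continue
        fractional = arc.weight.denominator != 1
        if arc.target in thresholds:  # input arc
            thresholds[arc.target].append((arc.source, math.ceil(arc.weight)))
            if fractional:
                capped[arc.target] = True
        elif fractional:  # fractional output arc
            capped[arc.source] = True
    for t in net.transitions:
        if not thresholds[t]:
            capped[t] = True

    results: set[frozenset] = set()
    seen: set[tuple] = set()

    def recurse(avail: dict, counts: dict) -> None:
        key = (tuple(sorted(avail.items())), tuple(sorted(counts.items())))
        if key in seen:
            return
        seen.add(key)
        enabled = [
            t
            for t in net.transitions
            if not (capped[t] and counts.get(t, 0) >= 1)
            and all(avail[p] >= need for p, need in thresholds[t])
        ]
        if not enabled:
            results.add(frozenset(counts.items()))
            return
        for t in enabled:
            nxt = dict(avail)
            for p, need in thresholds[t]:
                nxt[p] -= need
            recurse(nxt, {**counts, t: counts.get(t, 0) + 1})

    recurse(dict(marking), {})
    return results


def make_chain(weight, tokens: int = 100) -> PetriNet:
    """source --w--> t --w--> sink, the minimal rate-semantics fixture."""
    weight = Fraction(weight) if not isinstance(weight, Fraction) else weight
    return PetriNet(
        places=("source", "sink"),
        transitions=("t",),
        arcs=(Arc("source", "t", weight), Arc("t", "sink", weight)),
        initial_marking={"source": tokens},
        name="chain",
    )


def transfer_steps(trace, place: str = "sink") -> list[int]:
    """Steps at which ``place`` gained at least one token."""
    levels = [m[place] for m in trace.markings]
    return [k for k in range(1, len(levels)) if levels[k] > levels[k - 1]]


@pytest.fixture
def oracle():
    return enumerate_maximal_firings


@pytest.fixture
def chain_net():
    return make_chain


@pytest.fixture
def wildtype_net():
    from wntpetri import WntScenario, build_wnt_net

    return build_wnt_net(WntScenario())
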