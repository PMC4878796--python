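"""Structural data model for place/transition Petri nets.

A Petri net is a bipartite directed graph: *places* hold integer token
counts (the marking), *transitions* consume tokens from their input
places and produce tokens in their output places when they fire, and
weighted *arcs* connect the two node classes.  Arc weights are stored as
exact rationals (:class:`fractions.Fraction`) because fractional weights
encode firing rates — e.g. a weight of ``1/10`` means "one token every
ten firings" — and that periodicity must hold exactly, without floating
point drift, over arbitrarily long runs.

This module contains no execution logic; see :mod:`wntpetri.engine` for
the token-game semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Union

__all__ = [
    "Weight",
    "as_weight",
    "Arc",
    "PetriNet",
    "validate_net",
    "inputs_of",
    "outputs_of",
]

Weight = Union[int, float, str, Fraction]


def as_weight(value: Weight) -> Fraction:
    """Coerce a user-facing weight to an exact :class:`Fraction`.

    Floats are interpreted through their decimal literal (``0.1`` becomes
    ``1/10``, not the nearest binary double), which is what a modeller
    writing ``weight=0.1`` means.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):
        raise TypeError("boolean is not a valid arc weight")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(str(value))
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as an arc weight")


@dataclass(frozen=True)
class Arc:
    """A weighted directed edge between a place and a transition.

    Exactly one endpoint must be a place and the other a transition
    (bipartiteness); this is checked by :func:`validate_net`, not by the
    constructor, so that invalid nets can be built and then reported on.
    """

    source: str
    target: str
    weight: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "weight", as_weight(self.weight))

    @property
    def is_fractional(self) -> bool:
        """True if the weight is a non-integer rational (a rate, not a count)."""
        return self.weight.denominator != 1


@dataclass
class PetriNet:
    """A place/transition net with an initial marking.

    ``initial_marking`` is completed with zeros for unmentioned places at
    construction time, so every place always has a defined token count.
    Instances are treated as immutable by the rest of the package.
    """

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    arcs: tuple[Arc, ...]
    initial_marking: dict[str, int] = field(default_factory=dict)
    name: str = "net"

    def __post_init__(self) -> None:
        self.places = tuple(self.places)
        self.transitions = tuple(self.transitions)
        self.arcs = tuple(
            a if isinstance(a, Arc) else Arc(*a) for a in self.arcs
        )
        marking = {p: 0 for p in self.places}
        marking.update({p: int(v) for p, v in self.initial_marking.items()})
        self.initial_marking = marking


def _incident(net: PetriNet, t: str) -> tuple[set[tuple[str, Fraction]], set[tuple[str, Fraction]]]:
    if t not in net.transitions:
        raise KeyError(f"unknown transition {t!r}")
    ins = {(a.source, a.weight) for a in net.arcs if a.target == t}
    outs = {(a.target, a.weight) for a in net.arcs if a.source == t}
    return ins, outs


def inputs_of(net: PetriNet, t: str) -> set[tuple[str, Fraction]]:
    """Input places of transition ``t`` with their exact arc weights."""
    return _incident(net, t)[0]


def outputs_of(net: PetriNet, t: str) -> set[tuple[str, Fraction]]:
    """Output places of transition ``t`` with their exact arc weights."""
    return _incident(net, t)[1]


def validate_net(net: PetriNet) -> list[str]:
    """Check every structural invariant and return the violations found.

    An empty list means the net is valid.  Checked invariants:

    * non-empty, unique node names; place and transition name spaces disjoint
    * every arc runs between one place and one transition (bipartite),
      with both endpoints declared in the net
    * no duplicate arc (same ordered source→target pair)
    * weights are positive; a weight of exactly 0 is tolerated on
      transition→place arcs only, where it is inert (used to switch a
      feedback arc off without changing the net's shape)
    * the marking assigns a non-negative integer to every place

    The function never raises on an invalid net — it reports.
    """
    issues: list[str] = []
    place_set = set(net.places)
    trans_set = set(net.transitions)

    for name in list(net.places) + list(net.transitions):
        if not isinstance(name, str) or not name:
            issues.append(f"empty or non-string node name {name!r}")
    if len(place_set) != len(net.places):
        issues.append("duplicate place names")
    if len(trans_set) != len(net.transitions):
        issues.append("duplicate transition names")
    overlap = place_set & trans_set
    if overlap:
        issues.append(f"names used as both place and transition: {sorted(overlap)}")

    seen: set[tuple[str, str]] = set()
    for arc in net.arcs:
        src_is_place = arc.source in place_set
        src_is_trans = arc.source in trans_set
        tgt_is_place = arc.target in place_set
        tgt_is_trans = arc.target in trans_set
        if not (src_is_place or src_is_trans):
            issues.append(f"arc {arc.source}->{arc.target}: unknown source node")
            continue
        if not (tgt_is_place or tgt_is_trans):
            issues.append(f"arc {arc.source}->{arc.target}: unknown target node")
            continue
        if src_is_place == tgt_is_place:
            kind = "place" if src_is_place else "transition"
            issues.append(
                f"arc {arc.source}->{arc.target}: bipartiteness violated ({kind}->{kind})"
            )
        key = (arc.source, arc.target)
        if key in seen:
            issues.append(f"duplicate arc {arc.source}->{arc.target}")
        seen.add(key)
        if arc.weight < 0:
            issues.append(f"arc {arc.source}->{arc.target}: negative weight {arc.weight}")
        elif arc.weight == 0 and src_is_place:
            issues.append(
                f"arc {arc.source}->{arc.target}: zero weight on an input arc"
            )

    for place in net.places:
        count = net.initial_marking.get(place)
        if count is None:
            issues.append(f"place {place}: missing marking entry")
        elif not isinstance(count, int) or count < 0:
            issues.append(f"place {place}: marking {count!r} is not a non-negative integer")
    for key in net.initial_marking:
        if key not in place_set:
            issues.append(f"marking entry for unknown place {key!r}")

    return issues
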