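"""PNML interchange, scenario files, and random fixture nets.

PNML dialect: the ISO/IEC 15909-2 place/transition net layout
(``<place>`` with ``<initialMarking>``, ``<transition>``, ``<arc>`` with
an ``<inscription>``).  Stock P/T tools assume integer inscriptions;
fractional firing-rate weights are serialised as exact decimal strings
(``0.15``) — readable but non-standard — or as ``p/q`` when the weight
has no finite decimal expansion.  The reader accepts integers, decimal
strings and ``p/q`` forms, with and without the PNML namespace.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from fractions import Fraction
from pathlib import Path
from typing import Union

import numpy as np

from .core import Arc, PetriNet, validate_net

__all__ = [
    "PnmlError",
    "read_pnml",
    "write_pnml",
    "random_net",
    "load_scenario",
]

PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"


class PnmlError(ValueError):
    """Malformed or structurally invalid PNML input."""


def _format_weight(weight: Fraction) -> str:
    if weight.denominator == 1:
        return str(weight.numerator)
    # finite decimal expansion iff the denominator is 2^a * 5^b
    den = weight.denominator
    for base in (2, 5):
        while den % base == 0:
            den //= base
    if den == 1:
        return _decimal_string(weight)
    return f"{weight.numerator}/{weight.denominator}"


def _decimal_string(weight: Fraction) -> str:
    """Exact decimal expansion for denominators of the form 2^a 5^b."""
    num, den = weight.numerator, weight.denominator
    exp = 0
    while den % 2 == 0:
        den //= 2
        num *= 5
        exp += 1
    while den % 5 == 0:
        den //= 5
        num *= 2
        exp += 1
    assert den == 1
    text = str(num).rjust(exp + 1, "0")
    return f"{text[:-exp]}.{text[-exp:]}" if exp else text


def _parse_weight(text: str, arc_id: str) -> Fraction:
    try:
        if "/" in text:
            num, den = text.split("/")
            return Fraction(int(num), int(den))
        return Fraction(text.strip())
    except (ValueError, ZeroDivisionError) as exc:
        raise PnmlError(f"arc {arc_id!r}: unreadable inscription {text!r}") from exc


def write_pnml(net: PetriNet, path: Union[str, Path]) -> None:
    """Serialise a valid net to PNML; refuses structurally invalid nets.

    Element order follows the net's declared node order, so repeated
    writes of the same net are byte-identical.
    """
    issues = validate_net(net)
    if issues:
        raise PnmlError("refusing to write invalid net: " + "; ".join(issues))
    root = ET.Element("pnml", xmlns=PNML_NS)
    net_el = ET.SubElement(root, "net", id=net.name, type=f"{PNML_NS}/ptnet")
    page = ET.SubElement(net_el, "page", id="page0")
    for place in net.places:
        el = ET.SubElement(page, "place", id=place)
        ET.SubElement(ET.SubElement(el, "name"), "text").text = place
        tokens = net.initial_marking[place]
        if tokens:
            ET.SubElement(ET.SubElement(el, "initialMarking"), "text").text = str(tokens)
    for trans in net.transitions:
        el = ET.SubElement(page, "transition", id=trans)
        ET.SubElement(ET.SubElement(el, "name"), "text").text = trans
    for i, arc in enumerate(net.arcs):
        el = ET.SubElement(
            page, "arc", id=f"a{i}", source=arc.source, target=arc.target
        )
        ET.SubElement(ET.SubElement(el, "inscription"), "text").text = _format_weight(
            arc.weight
        )
    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_pnml(path: Union[str, Path]) -> PetriNet:
    """Parse a PNML file into a validated :class:`PetriNet`.

    Fractional inscriptions are parsed exactly (``"0.15"`` → ``3/20``).
    Raises :class:`PnmlError` naming the offending element on malformed
    or non-bipartite input.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise PnmlError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()

    places: list[str] = []
    transitions: list[str] = []
    arcs: list[Arc] = []
    marking: dict[str, int] = {}
    net_name = "net"

    def walk(el):
        yield el
        for child in el:
            yield from walk(child)

    for el in walk(root):
        tag = _local(el.tag)
        if tag == "net":
            net_name = el.get("id", net_name)
        elif tag == "place":
            pid = el.get("id")
            if not pid:
                raise PnmlError("place element without id")
            places.append(pid)
            for sub in walk(el):
                if _local(sub.tag) == "initialMarking":
                    text = "".join(
                        t.text or "" for t in walk(sub) if _local(t.tag) == "text"
                    )
                    try:
                        marking[pid] = int(text.strip())
                    except ValueError as exc:
                        raise PnmlError(
                            f"place {pid!r}: unreadable initial marking {text!r}"
                        ) from exc
        elif tag == "transition":
            tid = el.get("id")
            if not tid:
                raise PnmlError("transition element without id")
            transitions.append(tid)
        elif tag == "arc":
            aid = el.get("id", "?")
            source, target = el.get("source"), el.get("target")
            if not source or not target:
                raise PnmlError(f"arc {aid!r}: missing source/target")
            weight = Fraction(1)
            for sub in walk(el):
                if _local(sub.tag) == "inscription":
                    text = "".join(
                        t.text or "" for t in walk(sub) if _local(t.tag) == "text"
                    )
                    weight = _parse_weight(text, aid)
            arcs.append(Arc(source, target, weight))

    place_set, trans_set = set(places), set(transitions)
    for i, arc in enumerate(arcs):
        for end, node in (("source", arc.source), ("target", arc.target)):
            if node not in place_set and node not in trans_set:
                raise PnmlError(f"arc a{i}: unknown {end} node {node!r}")
        if (arc.source in place_set) == (arc.target in place_set):
            raise PnmlError(
                f"arc a{i} ({arc.source}->{arc.target}): not place<->transition"
            )

    net = PetriNet(
        places=tuple(places),
        transitions=tuple(transitions),
        arcs=tuple(arcs),
        initial_marking=marking,
        name=net_name,
    )
    issues = validate_net(net)
    if issues:
        raise PnmlError("invalid net in PNML: " + "; ".join(issues))
    return net


# ---------------------------------------------------------------------------
# random fixture nets for engine property tests
# ---------------------------------------------------------------------------

def random_net(
    n_places: int,
    n_transitions: int,
    max_tokens: int = 3,
    seed: int = 0,
    conservative: bool = False,
) -> PetriNet:
    """A small random connected bipartite net with integer weights ≤ 3.

    Every transition has at least one input arc.  In ``conservative``
    mode each transition's input weight sum equals its output weight
    sum, so the total token count is invariant under execution — used
    for conservation property tests.
    """
    if n_places < 1 or n_transitions < 1:
        raise ValueError("need at least one place and one transition")
    rng = np.random.default_rng(seed)
    places = tuple(f"p{i}" for i in range(n_places))
    transitions = tuple(f"t{i}" for i in range(n_transitions))
    pairs: set[tuple[str, str]] = set()
    arcs: list[Arc] = []

    def add(source: str, target: str, weight: int) -> None:
        if (source, target) not in pairs:
            pairs.add((source, target))
            arcs.append(Arc(source, target, weight))

    # backbone chain p0-t0-p1-t1-... keeps the net connected and gives
    # every transition one input and one output
    for i, t in enumerate(transitions):
        w = int(rng.integers(1, 4))
        src = places[i % n_places]
        dst = places[(i + 1) % n_places]
        add(src, t, w)
        add(t, dst, w if conservative else int(rng.integers(1, 4)))
    # a few random extra arcs
    for _ in range(int(rng.integers(0, n_places + n_transitions))):
        p = places[int(rng.integers(n_places))]
        t = transitions[int(rng.integers(n_transitions))]
        w = int(rng.integers(1, 4))
        if conservative:
            # only balanced read-arc pairs keep every transition conserving
            if (p, t) not in pairs and (t, p) not in pairs:
                add(p, t, w)
                add(t, p, w)
        elif rng.integers(2):
            add(p, t, w)
        else:
            add(t, p, w)
    marking = {p: int(rng.integers(0, max_tokens + 1)) for p in places}
    net = PetriNet(places, transitions, tuple(arcs), marking, name=f"random{seed}")
    assert not validate_net(net)
    return net


# ---------------------------------------------------------------------------
# scenario config files
# ---------------------------------------------------------------------------

def load_scenario(path: Union[str, Path]):
    """Read a :class:`~wntpetri.wnt.WntScenario` from a YAML or JSON file."""
    import yaml

    from .wnt import WntScenario

    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    return WntScenario(**data)
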