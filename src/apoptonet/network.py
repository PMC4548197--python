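"""Signed-threshold Boolean network definitions and file formats.

A network is a directed graph whose vertices carry binary states and whose
edges carry a sign (+1 activation, -1 inhibition).  Vertex flags control the
update rule applied by :mod:`apoptonet.dynamics`:

``is_input``
    The vertex has no regulators inside the network; its state is clamped to
    a condition value for the whole simulation (growth factor, death ligand,
    overexpressed heat-shock proteins).
``is_self_degrading``
    The protein decays when its net regulatory input is not strictly
    positive (zero input drives the vertex OFF instead of holding it).
``is_constitutive``
    The protein is basally synthesised: a constant +1 is added to its input
    sum, so it is ON unless actively inhibited.  Used for proteins such as
    IkB and BAD that are present by default and removed by signalling.

Persistence gates implement delayed regulation: the outgoing influence of a
watched vertex along the scoped edges only counts once the watched vertex
has been ON for a required number of consecutive time steps.

File formats
------------
* Interaction file: one edge per line, ``SOURCE<TAB>+|-<TAB>TARGET``,
  ``#`` comments allowed (a signed SIF dialect).
* Rule config (YAML): keys ``order``, ``inputs``, ``self_degrading``,
  ``constitutive``, ``gates`` (list of ``{watched, threshold, targets}``).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "VertexSpec",
    "EdgeSpec",
    "GateRule",
    "NetworkSpec",
    "Overlay",
    "load_network",
    "load_overlay",
    "write_network",
    "validate_network",
    "apply_variant",
    "apoptosis_network",
    "hsp_overlay",
    "HSP_NAMES",
]

ASSET_DIR = Path(__file__).parent / "networks"
HSP_NAMES = ("HSP27", "HSP40", "HSP70", "HSP90")


@dataclass(frozen=True)
class VertexSpec:
    """One protein (or stimulus) in the network."""

    name: str
    index: int
    is_input: bool = False
    is_self_degrading: bool = False
    is_constitutive: bool = False
    display_name: str | None = None

    @property
    def label(self) -> str:
        return self.display_name or self.name


@dataclass(frozen=True)
class EdgeSpec:
    """A signed regulatory interaction ``source -> target``."""

    source: str
    target: str
    sign: int  # +1 activation, -1 inhibition


@dataclass(frozen=True)
class GateRule:
    """Persistence gate on the outgoing influence of ``watched_vertex``.

    ``targets`` lists the target vertices of the scoped outgoing edges.
    Two trigger modes exist:

    * ``sustained`` — the scoped edges contribute while the watched vertex
      has been ON for at least ``threshold`` consecutive steps;
    * ``pulse`` — the scoped edges contribute exactly at the step where the
      consecutive-ON run reaches ``threshold`` (a one-shot trigger per run).
    """

    watched_vertex: str
    threshold: int
    targets: tuple[str, ...]
    mode: str = "sustained"


@dataclass(frozen=True)
class NetworkSpec:
    """A validated signed-threshold Boolean network."""

    vertices: tuple[VertexSpec, ...]
    edges: tuple[EdgeSpec, ...]
    gates: tuple[GateRule, ...] = ()
    name: str = "network"

    def __post_init__(self) -> None:
        problems = validate_network(self)
        if problems:
            raise ValueError("invalid network: " + "; ".join(problems))

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.vertices)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown vertex {name!r}") from None

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.vertices if v.is_input)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.vertices if not v.is_input)


def _vertex_problems(net: NetworkSpec) -> list[str]:
    out = []
    seen = set()
    for i, v in enumerate(net.vertices):
        if not v.name:
            out.append(f"vertex at position {i} has an empty name")
        if v.name in seen:
            out.append(f"duplicate vertex name {v.name!r}")
        seen.add(v.name)
        if v.index != i:
            out.append(f"vertex {v.name!r}: index {v.index} != position {i}")
        if v.is_input and v.is_self_degrading:
            out.append(f"input vertex {v.name!r} marked self-degrading")
    return out


def validate_network(net: NetworkSpec) -> list[str]:
    """Return a list of invariant violations (empty iff the network is valid)."""
    out = _vertex_problems(net)
    names = {v.name for v in net.vertices}
    inputs = {v.name for v in net.vertices if v.is_input}
    seen_pairs = set()
    for e in net.edges:
        if e.sign not in (+1, -1):
            out.append(f"edge {e.source}->{e.target}: sign {e.sign} not in {{+1,-1}}")
        for endpoint in (e.source, e.target):
            if endpoint not in names:
                out.append(f"edge {e.source}->{e.target}: unknown vertex {endpoint!r}")
        if (e.source, e.target) in seen_pairs:
            out.append(f"duplicate edge {e.source}->{e.target}")
        seen_pairs.add((e.source, e.target))
        if e.target in inputs:
            out.append(f"edge {e.source}->{e.target}: inputs cannot be regulated")
    for g in net.gates:
        if g.threshold < 1:
            out.append(f"gate on {g.watched_vertex}: threshold {g.threshold} < 1")
        if g.mode not in ("sustained", "pulse"):
            out.append(f"gate on {g.watched_vertex}: unknown mode {g.mode!r}")
        if g.watched_vertex not in names:
            out.append(f"gate watches unknown vertex {g.watched_vertex!r}")
        for t in g.targets:
            if (g.watched_vertex, t) not in seen_pairs:
                out.append(f"gate on {g.watched_vertex}: no edge to {t!r} to scope")
    return out


def load_network(interactions: str | Path, rules: str | Path) -> NetworkSpec:
    """Load a network from an interaction file plus a rule-config file."""
    interactions, rules = Path(interactions), Path(rules)
    cfg = yaml.safe_load(rules.read_text())
    order: Sequence[str] = cfg["order"]
    inputs = set(cfg.get("inputs", ()))
    selfdeg = set(cfg.get("self_degrading", ()))
    constitutive = set(cfg.get("constitutive", ()))

    edges = []
    for lineno, raw in enumerate(interactions.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3 or parts[1] not in ("+", "-"):
            raise ValueError(f"{interactions.name}:{lineno}: malformed line {raw!r}")
        src, sign, tgt = parts
        for v in (src, tgt):
            if v not in order:
                raise ValueError(
                    f"{interactions.name}:{lineno}: vertex {v!r} missing from order list")
        edges.append(EdgeSpec(src, tgt, +1 if sign == "+" else -1))

    vertices = tuple(
        VertexSpec(
            name=n,
            index=i,
            is_input=n in inputs,
            is_self_degrading=n in selfdeg,
            is_constitutive=n in constitutive,
            display_name=cfg.get("display_names", {}).get(n),
        )
        for i, n in enumerate(order)
    )
    gates = tuple(
        GateRule(g["watched"], int(g["threshold"]), tuple(g["targets"]),
                 g.get("mode", "sustained"))
        for g in cfg.get("gates", ())
    )
    return NetworkSpec(vertices, tuple(edges), gates, name=cfg.get("name", interactions.stem))


def write_network(net: NetworkSpec, interactions: str | Path, rules: str | Path) -> None:
    """Write a network back to the interaction + rule-config formats."""
    lines = [f"{e.source}\t{'+' if e.sign > 0 else '-'}\t{e.target}" for e in net.edges]
    Path(interactions).write_text("\n".join(lines) + "\n")
    cfg = {
        "name": net.name,
        "order": list(net.names),
        "inputs": [v.name for v in net.vertices if v.is_input],
        "self_degrading": [v.name for v in net.vertices if v.is_self_degrading],
        "constitutive": [v.name for v in net.vertices if v.is_constitutive],
        "gates": [
            {"watched": g.watched_vertex, "threshold": g.threshold,
             "targets": list(g.targets), "mode": g.mode}
            for g in net.gates
        ],
    }
    display = {v.name: v.display_name for v in net.vertices if v.display_name}
    if display:
        cfg["display_names"] = display
    Path(rules).write_text(yaml.safe_dump(cfg, sort_keys=False))


@dataclass(frozen=True)
class Overlay:
    """An additive network extension: new vertices plus edges onto the base.

    Unlike :class:`NetworkSpec`, overlay edges may reference vertices that
    only exist in the base network, so overlays are validated on merge.
    """

    vertices: tuple[VertexSpec, ...] = ()
    edges: tuple[EdgeSpec, ...] = ()
    gates: tuple[GateRule, ...] = ()
    name: str = "overlay"


def apply_variant(net: NetworkSpec, overlay: Overlay) -> NetworkSpec:
    """Merge an additive overlay (extra vertices and edges) into a network.

    Overlay vertices are appended after the base order; overlay edges may
    reference vertices of either network.  Used for the heat-shock-protein
    extensions, whose HSP vertices are clamp-only inputs.
    """
    known = set(net.names) | {v.name for v in overlay.vertices}
    for e in overlay.edges:
        if e.source not in known or e.target not in known:
            raise ValueError(f"overlay edge {e.source}->{e.target}: unknown vertex")
    vertices = list(net.vertices) + [
        replace(v, index=net.n + j) for j, v in enumerate(overlay.vertices)
        if v.name not in net.names
    ]
    edges = list(net.edges) + [e for e in overlay.edges if e not in net.edges]
    gates = tuple(net.gates) + tuple(g for g in overlay.gates if g not in net.gates)
    return NetworkSpec(tuple(vertices), tuple(edges), gates,
                       name=f"{net.name}+{overlay.name}")


def apoptosis_network() -> NetworkSpec:
    """The curated 21-vertex / 37-edge neuronal apoptosis network."""
    return load_network(ASSET_DIR / "apoptosis_v1.sif", ASSET_DIR / "apoptosis_v1.rules.yaml")


def load_overlay(interactions: str | Path, rules: str | Path) -> Overlay:
    """Load an overlay; edge endpoints need not appear in the order list."""
    interactions, rules = Path(interactions), Path(rules)
    cfg = yaml.safe_load(rules.read_text())
    order: Sequence[str] = cfg.get("order", [])
    inputs = set(cfg.get("inputs", ()))
    selfdeg = set(cfg.get("self_degrading", ()))
    constitutive = set(cfg.get("constitutive", ()))
    edges = []
    for lineno, raw in enumerate(interactions.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3 or parts[1] not in ("+", "-"):
            raise ValueError(f"{interactions.name}:{lineno}: malformed line {raw!r}")
        src, sign, tgt = parts
        edges.append(EdgeSpec(src, tgt, +1 if sign == "+" else -1))
    vertices = tuple(
        VertexSpec(n, i, is_input=n in inputs, is_self_degrading=n in selfdeg,
                   is_constitutive=n in constitutive)
        for i, n in enumerate(order)
    )
    gates = tuple(
        GateRule(g["watched"], int(g["threshold"]), tuple(g["targets"]),
                 g.get("mode", "sustained"))
        for g in cfg.get("gates", ())
    )
    return Overlay(vertices, tuple(edges), gates, name=cfg.get("name", interactions.stem))


def hsp_overlay(name: str) -> Overlay:
    """Overlay adding one heat-shock protein and its inhibitory edges."""
    key = name.lower()
    if name.upper() not in HSP_NAMES:
        raise KeyError(f"unknown HSP {name!r}; expected one of {HSP_NAMES}")
    return load_overlay(ASSET_DIR / f"{key}_overlay.sif",
                        ASSET_DIR / f"{key}_overlay.rules.yaml")
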