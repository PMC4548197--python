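"""Attractor detection, exhaustive basin enumeration, and a brute-force oracle.

An attractor here is the state a trajectory occupies at the end of the
simulation horizon (15 synchronous steps for the curated network, matching
its longest path).  Because gated edges carry hidden consecutive-ON
counters, two classes arise:

* **stable** — the state is fixed regardless of persistence-gate history:
  the synchronous map leaves it unchanged both with every counter
  saturated and with every gated edge silent.  Started from such a state
  the network never leaves it.
* **transient** — a pending or spent gate event can still move the state:
  trajectories sit in it for a while (or are cut off by the horizon while
  passing through it), but it is not a point of rest.

``find_attractor`` additionally flags period>1 endpoints of a single
trajectory as ``unresolved`` (the curated network produces only
singletons).

``enumerate_attractors`` sweeps every assignment of the free (non-clamped)
vertices; ``brute_force_attractors`` builds the explicit successor graph
over extended states (bits plus counters) and extracts terminal strongly
connected components — the independent oracle used in tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import CompiledNet, Trajectory, batch_simulate
from .network import NetworkSpec

__all__ = ["Attractor", "EnumerationResult", "find_attractor",
           "enumerate_attractors", "brute_force_attractors",
           "gated_successor", "is_robust_fixed_point"]


@dataclass(frozen=True)
class Attractor:
    """A singleton attractor state under one clamp condition."""

    state_string: str
    period: int
    stability: str                      # "stable" | "transient" | "unresolved"
    condition: tuple[tuple[str, int], ...]
    basin_size: int | None = None

    def bit(self, net: NetworkSpec, name: str) -> int:
        return int(self.state_string[net.index(name)])


@dataclass(frozen=True)
class EnumerationResult:
    """All attractors and basin sizes for one clamp condition."""

    condition: tuple[tuple[str, int], ...]
    attractors: tuple[Attractor, ...]
    total_states: int
    network: NetworkSpec

    def basin_fraction(self, a: Attractor) -> Fraction:
        return Fraction(a.basin_size, self.total_states)

    def to_frame(self) -> pd.DataFrame:
        cond = dict(self.condition)
        rows = [
            {"basin": a.basin_size, **cond, "state": a.state_string,
             "period": a.period, "stability": a.stability}
            for a in self.attractors
        ]
        return pd.DataFrame(rows).sort_values("basin", ascending=False,
                                              ignore_index=True)


def gated_successor(net: NetworkSpec, bits, clamps: Mapping[str, int],
                    counters: str = "saturated") -> tuple[int, ...]:
    """One synchronous step under a fixed persistence-counter regime.

    ``counters="saturated"``: every run is long — sustained gates of ON
    watched vertices are open, pulse triggers have already fired.
    ``counters="reset"``: no run has reached any threshold — every gated
    edge is silent.
    """
    cn = CompiledNet(net)
    S = np.asarray(bits, dtype=np.int16)[None, :]
    W = S @ cn.adjacency + cn.bias
    if counters == "saturated":
        for (si, sg, ti, w, thr, mode) in cn.gated_edges:
            if mode == "sustained" and S[0, w] == 1:
                W[:, ti] += sg * S[:, si]
    elif counters != "reset":
        raise ValueError("counters must be 'saturated' or 'reset'")
    nxt = np.where(W > 0, 1, np.where(W < 0, 0,
                   np.where(cn.self_degrading[None, :], 0, S)))
    for name, val in clamps.items():
        nxt[0, net.index(name)] = val
    return tuple(int(x) for x in nxt[0])


def is_robust_fixed_point(net: NetworkSpec, state_string: str,
                          clamps: Mapping[str, int]) -> bool:
    """True iff the state is fixed regardless of persistence-gate history.

    A state held indefinitely has saturated counters; a state entered
    afresh has none.  A *stable* attractor must be fixed in both regimes —
    no pending gate event can push it anywhere.
    """
    bits = tuple(int(c) for c in state_string)
    return (gated_successor(net, bits, clamps, "saturated") == bits
            and gated_successor(net, bits, clamps, "reset") == bits)


def _codes(block: np.ndarray) -> np.ndarray:
    n = block.shape[-1]
    pw = (1 << np.arange(n - 1, -1, -1)).astype(np.int64)
    return block.astype(np.int64) @ pw


def find_attractor(traj: Trajectory) -> Attractor:
    """Identify the endpoint attractor of a single trajectory.

    The attractor is the final state; its period is 1 if the last update
    left it unchanged, otherwise the shortest cycle length detectable in
    the trajectory tail (flagged unresolved).  Stability is the robust
    fixed-point test (fixed under both counter regimes).
    """
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least two states")
    bits = traj.bit_matrix()
    codes = _codes(bits)
    n = traj.network.n
    clamps = dict(traj.states[0].clamps)
    final = int(codes[-1])
    string = format(final, f"0{n}b")
    if codes[-1] == codes[-2]:
        stability = ("stable" if is_robust_fixed_point(
            traj.network, string, clamps) else "transient")
        return Attractor(string, 1, stability,
                         tuple(sorted(clamps.items())))
    period = 1
    for p in range(2, len(codes)):
        if codes[-1] == codes[-1 - p]:
            period = p
            break
    return Attractor(string, period, "unresolved",
                     tuple(sorted(clamps.items())))


def _free_block(net: NetworkSpec, clamps: Mapping[str, int],
                words: np.ndarray) -> np.ndarray:
    free = [i for i in range(net.n) if net.vertices[i].name not in clamps]
    nf = len(free)
    S = np.zeros((len(words), net.n), dtype=np.int8)
    for j, v in enumerate(free):
        S[:, v] = (words >> (nf - 1 - j)) & 1
    for name, val in clamps.items():
        S[:, net.index(name)] = val
    return S


def enumerate_attractors(net: NetworkSpec, condition: Mapping[str, int],
                         steps: int = 15, max_free: int = 24
                         ) -> EnumerationResult:
    """Exhaustively enumerate attractors and basins under one clamp condition.

    Every assignment of the free vertices is simulated for ``steps``
    synchronous updates; identical endpoint states are pooled and their
    basins summed.  Initial states are generated in integer order of the
    free-bit word, which has no effect on the result.
    """
    cn = CompiledNet(net)
    clamps = dict(condition)
    cn.resolve_clamps(clamps)
    free = [v.name for v in net.vertices if v.name not in clamps]
    nf = len(free)
    if nf > max_free:
        raise ValueError(f"{nf} free vertices; exhaustive sweep capped at {max_free}")
    total = 1 << nf
    counts: dict[int, int] = {}
    chunk = 1 << 18
    for start in range(0, total, chunk):
        words = np.arange(start, min(start + chunk, total), dtype=np.int64)
        S0 = _free_block(net, clamps, words)
        block = batch_simulate(S0, clamps, cn, steps=steps)
        final = _codes(block)[-1]
        for code, cnt in zip(*np.unique(final, return_counts=True)):
            counts[int(code)] = counts.get(int(code), 0) + int(cnt)
    cond = tuple(sorted(clamps.items()))
    attractors = []
    for code, basin in sorted(counts.items(), key=lambda kv: -kv[1]):
        string = format(code, f"0{net.n}b")
        stability = ("stable" if is_robust_fixed_point(net, string, clamps)
                     else "transient")
        attractors.append(Attractor(string, 1, stability, cond, basin_size=basin))
    return EnumerationResult(cond, tuple(attractors), total, net)


# ---------------------------------------------------------------------------
# brute-force oracle over extended states


def brute_force_attractors(net: NetworkSpec, condition: Mapping[str, int],
                           max_bits: int = 12) -> EnumerationResult:
    """Oracle: terminal SCCs of the explicit extended-state transition graph.

    Extended states are (bits, counters) with counters capped one past the
    largest gate threshold, which is exact because gates only compare the
    counter against their threshold.  Intended for networks with at most
    ``max_bits`` free vertices.
    """
    from .dynamics import _advance

    cn = CompiledNet(net)
    clamps = dict(condition)
    clamp_idx = cn.resolve_clamps(clamps)
    free = [i for i in range(net.n) if net.vertices[i].name not in clamps]
    if len(free) > max_bits:
        raise ValueError("state space too large for the brute-force oracle")
    caps = {}
    for (_, _, _, w, thr, _mode) in cn.gated_edges:
        caps[w] = max(thr + 1, caps.get(w, 0))
    watched = cn.watched

    def succ(node):
        bits, cnts = node
        S = np.array([bits], dtype=np.int8)
        counters = {w: np.array([c], dtype=np.int16)
                    for w, c in zip(watched, cnts)}
        nxt = _advance(cn, S, counters, clamp_idx)
        ncnt = tuple(min(int(counters[w][0]), caps[w]) for w in watched)
        return tuple(int(x) for x in nxt[0]), ncnt

    init_nodes = []
    for word in range(1 << len(free)):
        bits = [0] * net.n
        for j, v in enumerate(free):
            bits[v] = (word >> (len(free) - 1 - j)) & 1
        for i, val in clamp_idx.items():
            bits[i] = val
        bits = tuple(bits)
        cnts = tuple(min(bits[w], caps[w]) for w in watched)
        init_nodes.append((bits, cnts))

    G = nx.DiGraph()
    frontier = list(dict.fromkeys(init_nodes))
    seen = set(frontier)
    while frontier:
        node = frontier.pop()
        nxt = succ(node)
        G.add_edge(node, nxt)
        if nxt not in seen:
            seen.add(nxt)
            frontier.append(nxt)

    sccs = list(nx.strongly_connected_components(G))
    node_scc = {node: i for i, comp in enumerate(sccs) for node in comp}
    terminal = {
        i for i, comp in enumerate(sccs)
        if all(node_scc[s] == i for node in comp for s in G.successors(node))
    }
    reach: dict[tuple, int] = {}

    def terminal_of(node):
        path = []
        while node not in reach:
            idx = node_scc[node]
            if idx in terminal:
                reach[node] = idx
                break
            path.append(node)
            node = next(iter(G.successors(node)))
        for p in path:
            reach[p] = reach[node]
        return reach[node]

    basin: dict[int, int] = {}
    for node in init_nodes:
        idx = terminal_of(node)
        basin[idx] = basin.get(idx, 0) + 1

    cond = tuple(sorted(clamps.items()))
    attractors = []
    for idx, count in sorted(basin.items(), key=lambda kv: -kv[1]):
        comp = sccs[idx]
        states = {b for (b, _) in comp}
        rep = min(states)
        attractors.append(Attractor(
            "".join(map(str, rep)), len(comp),
            "stable" if len(comp) == 1 else "unresolved", cond,
            basin_size=count))
    return EnumerationResult(cond, tuple(attractors), 1 << len(free), net)
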