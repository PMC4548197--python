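"""Synchronous signed-threshold dynamics with persistence gates.

The update rule for vertex *i* at time *t*:

.. math::

    W_i(t) = b_i + \\sum_j a_{ij} S_j(t)

where the sum runs over incoming edges whose persistence gates are open,
``a_ij`` is the edge sign and ``b_i`` is 1 for constitutive vertices and 0
otherwise.  Then

* ``S_i(t+1) = 1`` if ``W > 0``,
* ``S_i(t+1) = 0`` if ``W < 0``,
* ``S_i(t+1) = S_i(t)`` if ``W = 0`` and *i* is not self-degrading,
* ``S_i(t+1) = 0`` if ``W <= 0`` and *i* is self-degrading.

Clamped vertices (inputs and perturbed vertices) keep their clamped value
at every step.  A persistence gate on vertex *v* with threshold *m* opens
while *v* has been ON for at least *m* consecutive steps, counting an
initially-ON vertex as a run of length 1.

All vertices are updated simultaneously from the time-*t* state; the
consecutive-ON counters are then advanced from the freshly written state.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import NetworkSpec

__all__ = ["ExtendedState", "Trajectory", "step", "simulate", "batch_simulate",
           "compiled", "CompiledNet"]


@dataclass(frozen=True)
class ExtendedState:
    """Binary state vector plus the consecutive-ON counters of gated vertices."""

    bits: tuple[int, ...]
    counters: Mapping[str, int]
    clamps: Mapping[str, int]

    def as_string(self) -> str:
        return "".join(map(str, self.bits))


@dataclass(frozen=True)
class Trajectory:
    """States of one synchronous run; ``states[t]`` is the state at time t."""

    states: tuple[ExtendedState, ...]
    network: NetworkSpec

    def __len__(self) -> int:
        return len(self.states)

    def bit_matrix(self) -> np.ndarray:
        return np.array([s.bits for s in self.states], dtype=np.int8)

    def to_frame(self):
        """One row per step, one column per vertex (debugging/CSV export)."""
        import pandas as pd
        df = pd.DataFrame(self.bit_matrix(), columns=self.network.names)
        df.index.name = "step"
        return df


class CompiledNet:
    """Network compiled to arrays for vectorised updates.

    ``adjacency`` holds the ungated signed adjacency (A[src, tgt]); gated
    edges are kept separate with their watched vertex and threshold.
    """

    def __init__(self, net: NetworkSpec):
        n = net.n
        self.net = net
        self.adjacency = np.zeros((n, n), dtype=np.int16)
        self.gated_edges: list[tuple[int, int, int, int, int, str]] = []
        gate_of: dict[tuple[str, str], tuple[int, int, str]] = {}
        for g in net.gates:
            for t in g.targets:
                gate_of[(g.watched_vertex, t)] = (
                    net.index(g.watched_vertex), g.threshold, g.mode)
        for e in net.edges:
            si, ti = net.index(e.source), net.index(e.target)
            gate = gate_of.get((e.source, e.target))
            if gate is None:
                self.adjacency[si, ti] += e.sign
            else:
                self.gated_edges.append((si, e.sign, ti, *gate))
        self.bias = np.array([1 if v.is_constitutive else 0 for v in net.vertices],
                             dtype=np.int16)
        self.self_degrading = np.array([v.is_self_degrading for v in net.vertices])
        self.watched = sorted({w for (_, _, _, w, _, _) in self.gated_edges})
        self.input_idx = [i for i, v in enumerate(net.vertices) if v.is_input]

    def resolve_clamps(self, clamps: Mapping[str, int]) -> dict[int, int]:
        out = {}
        for name, val in clamps.items():
            out[self.net.index(name)] = int(val)
        missing = [i for i in self.input_idx if i not in out]
        if missing:
            names = [self.net.vertices[i].name for i in missing]
            raise ValueError(f"no clamp value given for input vertices {names}")
        return out


def compiled(net: NetworkSpec) -> CompiledNet:
    return CompiledNet(net)


def _advance(cn: CompiledNet, S: np.ndarray, counters: dict[int, np.ndarray],
             clamp_idx: Mapping[int, int]) -> np.ndarray:
    """One synchronous step on a (M, N) block; counters updated in place."""
    W = S.astype(np.int16) @ cn.adjacency + cn.bias
    for (si, sg, ti, w, thr, mode) in cn.gated_edges:
        open_ = (counters[w] >= thr) if mode == "sustained" else (counters[w] == thr)
        W[:, ti] += sg * S[:, si].astype(np.int16) * open_
    nxt = np.where(W > 0, 1,
                   np.where(W < 0, 0,
                            np.where(cn.self_degrading[None, :], 0, S))).astype(np.int8)
    for i, val in clamp_idx.items():
        nxt[:, i] = val
    for w in cn.watched:
        counters[w] = np.minimum((counters[w] + 1) * nxt[:, w], np.int16(32767))
    return nxt


def _init_counters(cn: CompiledNet, S: np.ndarray) -> dict[int, np.ndarray]:
    return {w: S[:, w].astype(np.int16).copy() for w in cn.watched}


def batch_simulate(initial_bits: np.ndarray, clamps: Mapping[str, int],
                   net: NetworkSpec | CompiledNet, steps: int = 15) -> np.ndarray:
    """Run a block of initial states under one clamp assignment.

    Parameters
    ----------
    initial_bits : (M, N) array of 0/1
    clamps : vertex name -> clamped value (must cover all inputs)
    steps : number of synchronous updates

    Returns
    -------
    (steps+1, M, N) int8 array of states; ``[0]`` is the clamped initial block.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    cn = net if isinstance(net, CompiledNet) else CompiledNet(net)
    S = np.asarray(initial_bits, dtype=np.int8)
    if S.ndim != 2 or S.shape[1] != cn.net.n:
        raise ValueError(f"initial block must be (M, {cn.net.n})")
    clamp_idx = cn.resolve_clamps(clamps)
    S = S.copy()
    for i, val in clamp_idx.items():
        S[:, i] = val
    counters = _init_counters(cn, S)
    out = np.empty((steps + 1, *S.shape), dtype=np.int8)
    out[0] = S
    for t in range(steps):
        S = _advance(cn, S, counters, clamp_idx)
        out[t + 1] = S
    return out


def simulate(initial_bits: Sequence[int], clamps: Mapping[str, int],
             net: NetworkSpec, steps: int = 15) -> Trajectory:
    """Run one trajectory and return it with per-step counters attached."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    cn = CompiledNet(net)
    S = np.asarray(initial_bits, dtype=np.int8)[None, :]
    if S.shape[1] != net.n:
        raise ValueError(f"expected {net.n} bits, got {S.shape[1]}")
    clamp_idx = cn.resolve_clamps(clamps)
    S = S.copy()
    for i, val in clamp_idx.items():
        S[:, i] = val
    counters = _init_counters(cn, S)
    clamp_names = {net.vertices[i].name: v for i, v in clamp_idx.items()}

    def snap(bits_row: np.ndarray) -> ExtendedState:
        return ExtendedState(
            bits=tuple(int(x) for x in bits_row),
            counters={net.vertices[w].name: int(counters[w][0]) for w in cn.watched},
            clamps=dict(clamp_names),
        )

    states = [snap(S[0])]
    for t in range(steps):
        S = _advance(cn, S, counters, clamp_idx)
        states.append(snap(S[0]))
    return Trajectory(tuple(states), net)


def step(state: ExtendedState, net: NetworkSpec) -> ExtendedState:
    """Apply one synchronous update to an extended state."""
    cn = CompiledNet(net)
    S = np.asarray(state.bits, dtype=np.int8)[None, :].copy()
    clamp_idx = {net.index(k): int(v) for k, v in state.clamps.items()}
    for i, val in clamp_idx.items():
        S[:, i] = val
    counters = {net.index(k): np.array([v], dtype=np.int16)
                for k, v in state.counters.items()}
    for w in cn.watched:
        counters.setdefault(w, S[:, w].astype(np.int16).copy())
    nxt = _advance(cn, S, counters, clamp_idx)
    return ExtendedState(
        bits=tuple(int(x) for x in nxt[0]),
        counters={net.vertices[w].name: int(counters[w][0]) for w in cn.watched},
        clamps=dict(state.clamps),
    )
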