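"""Random signed-threshold networks and hand-built fixture networks.

The generator produces arbitrary valid networks (not biologically motivated
topologies) so that the dynamics engine, the enumeration and the
brute-force oracle can be cross-checked property-style without the curated
asset.  Generation is pure given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import EdgeSpec, GateRule, NetworkSpec, VertexSpec

__all__ = ["GeneratorConfig", "random_network", "fixture_networks"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_vertices: int = 8
    n_edges: int = 12
    activation_fraction: float = 0.6
    self_degrading_fraction: float = 0.4
    n_inputs: int = 1
    n_gates: int = 0
    gate_thresholds: tuple[int, ...] = (2, 3)
    seed: int = 0

    def validate(self) -> None:
        n, m = self.n_vertices, self.n_edges
        if self.n_inputs >= n:
            raise ValueError("need at least one non-input vertex")
        # inputs have no incoming edges
        max_edges = n * (n - 1) - self.n_inputs * (n - 1)
        if m > max_edges:
            raise ValueError(f"{m} edges infeasible for n={n} with "
                             f"{self.n_inputs} inputs (max {max_edges})")
        for frac in (self.activation_fraction, self.self_degrading_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


def random_network(cfg: GeneratorConfig) -> NetworkSpec:
    """Generate a random valid network; identical for identical configs."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_vertices
    names = [f"V{i}" for i in range(n)]
    input_ix = set(rng.choice(n, size=cfg.n_inputs, replace=False).tolist())
    free_ix = [i for i in range(n) if i not in input_ix]
    selfdeg_ix = {
        i for i in free_ix
        if rng.random() < cfg.self_degrading_fraction
    }
    # candidate ordered pairs; inputs receive no edges
    pairs = [(s, t) for s in range(n) for t in free_ix if s != t]
    chosen = rng.choice(len(pairs), size=cfg.n_edges, replace=False)
    edges = tuple(
        EdgeSpec(names[pairs[k][0]], names[pairs[k][1]],
                 +1 if rng.random() < cfg.activation_fraction else -1)
        for k in sorted(chosen.tolist())
    )
    gates = []
    gateable = [e for e in edges if e.source not in {names[i] for i in input_ix}]
    for _ in range(cfg.n_gates):
        if not gateable:
            break
        e = gateable.pop(int(rng.integers(len(gateable))))
        thr = int(rng.choice(cfg.gate_thresholds))
        gates.append(GateRule(e.source, thr, (e.target,)))
    vertices = tuple(
        VertexSpec(names[i], i, is_input=i in input_ix,
                   is_self_degrading=i in selfdeg_ix)
        for i in range(n)
    )
    return NetworkSpec(vertices, edges, tuple(gates),
                       name=f"random-{cfg.seed}")


def fixture_networks() -> dict[str, NetworkSpec]:
    """Small hand-built networks with known, hand-enumerable behaviour.

    ``selfdeg1``
        One self-degrading vertex, no edges: everything decays to 0.
    ``mutual_inhibition``
        Two vertices inhibiting each other: 10 and 01 are fixed points
        (the ON vertex holds at a zero tie), 11 drives both OFF, and 00
        holds, giving basins {00: 2, 10: 1, 01: 1}.
    ``gated_chain``
        IN -> A (threshold-2 gate on A -> B): B only fires after A has been
        ON twice in a row, giving a one-step-delayed switch.
    ``apoptosis_motif``
        Four vertices: a clamped stress input, a pro-death effector D
        (activated by stress, inhibited by the protector P), a constitutive
        protector P inhibited by stress, and a readout R copying D.  The
        16-state transition table is small enough to enumerate by hand:
        with stress ON the protector decays, D fires and R follows; with
        stress OFF, P recovers and D and R decay.
    """
    nets = {}

    nets["selfdeg1"] = NetworkSpec(
        (VertexSpec("A", 0, is_self_degrading=True),), (), name="selfdeg1")

    nets["mutual_inhibition"] = NetworkSpec(
        (VertexSpec("A", 0), VertexSpec("B", 1)),
        (EdgeSpec("A", "B", -1), EdgeSpec("B", "A", -1)),
        name="mutual_inhibition")

    nets["gated_chain"] = NetworkSpec(
        (VertexSpec("IN", 0, is_input=True),
         VertexSpec("A", 1, is_self_degrading=True),
         VertexSpec("B", 2, is_self_degrading=True)),
        (EdgeSpec("IN", "A", +1), EdgeSpec("A", "B", +1)),
        (GateRule("A", 2, ("B",)),),
        name="gated_chain")

    nets["apoptosis_motif"] = NetworkSpec(
        (VertexSpec("STRESS", 0, is_input=True),
         VertexSpec("P", 1, is_self_degrading=True, is_constitutive=True),
         VertexSpec("D", 2, is_self_degrading=True),
         VertexSpec("R", 3, is_self_degrading=True)),
        (EdgeSpec("STRESS", "D", +1), EdgeSpec("STRESS", "P", -1),
         EdgeSpec("P", "D", -1), EdgeSpec("D", "R", +1)),
        name="apoptosis_motif")

    return nets
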