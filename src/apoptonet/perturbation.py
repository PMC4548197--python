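"""In-silico knockout / overexpression screens and HSP-extension analyses.

A loss-of-function mutation clamps a vertex OFF for the whole simulation; a
gain-of-function (overexpression) clamps it ON.  The clamped vertex ignores
its regulators but keeps acting on its targets (and on any persistence gate
that watches it).  A screen re-enumerates the full state space per
(vertex, condition) pair and summarises the basin-weighted fates.

The heat-shock-protein analyses merge an inhibitory overlay (HSP27 -| BID,
CYT-C; HSP40 -| BAX; HSP70 -| APAF, BID, BAX; HSP90 -| APAF), clamp the HSP
vertex ON to represent overexpression, and enumerate all four GF x FasL
input conditions.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .attractors import EnumerationResult, enumerate_attractors
from .fates import FATES, FateSummary, fate_probabilities
from .network import HSP_NAMES, NetworkSpec, apply_variant, hsp_overlay

__all__ = ["PerturbationResult", "perturb", "screen", "hsp_analysis",
           "ALL_INPUT_CONDITIONS", "SCREEN_CONDITION"]

#: The four GF x FasL input conditions, in the order they are reported.
ALL_INPUT_CONDITIONS = (
    {"GF": 0, "FASL": 0},
    {"GF": 1, "FASL": 0},
    {"GF": 0, "FASL": 1},
    {"GF": 1, "FASL": 1},
)

#: Input condition under which the vertex-perturbation survival
#: probabilities are reported: growth factor present, death ligand absent.
SCREEN_CONDITION = ({"GF": 1, "FASL": 0},)


@dataclass(frozen=True)
class PerturbationResult:
    """Fate summaries for one vertex clamped ON or OFF."""

    vertex: str
    value: int
    summaries: tuple[FateSummary, ...]
    baselines: tuple[FateSummary, ...]

    def f_survival(self) -> Fraction:
        """Survival probability pooled equally over the condition set."""
        fs = [s.f_survival for s in self.summaries]
        return sum(fs, Fraction(0)) / len(fs)

    def delta_survival(self) -> Fraction:
        base = [b.f_survival for b in self.baselines]
        return self.f_survival() - sum(base, Fraction(0)) / len(base)


def perturb(net: NetworkSpec, vertex: str, value: int,
            condition: Mapping[str, int]) -> dict[str, int]:
    """Combine an input condition with a perturbation clamp.

    Returns the clamp assignment to pass to the enumeration.  Perturbing an
    input vertex to a value that conflicts with the condition is an error.
    """
    if value not in (0, 1):
        raise ValueError("clamp value must be 0 or 1")
    net.index(vertex)  # raises KeyError for unknown vertices
    clamps = dict(condition)
    if vertex in clamps and clamps[vertex] != value:
        raise ValueError(
            f"{vertex} is clamped to {clamps[vertex]} by the input condition")
    clamps[vertex] = value
    return clamps


def screen(net: NetworkSpec, vertices: Sequence[str], value: int,
           conditions: Sequence[Mapping[str, int]] = SCREEN_CONDITION,
           steps: int = 15) -> list[PerturbationResult]:
    """Clamp each vertex to ``value`` and re-enumerate under each condition."""
    baselines = tuple(
        fate_probabilities(enumerate_attractors(net, c, steps))
        for c in conditions
    )
    out = []
    for v in vertices:
        summaries = tuple(
            fate_probabilities(
                enumerate_attractors(net, perturb(net, v, value, c), steps))
            for c in conditions
        )
        out.append(PerturbationResult(v, value, summaries, baselines))
    return out


def screen_frame(results: Iterable[PerturbationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for s, b in zip(r.summaries, r.baselines):
            cond = dict(s.condition)
            rows.append({
                "vertex": r.vertex, "clamp": r.value,
                "GF": cond.get("GF"), "FASL": cond.get("FASL"),
                **{f"f_{f}": float(s.fraction(f)) for f in FATES},
                "delta_survival": float(s.f_survival - b.f_survival),
            })
    return pd.DataFrame(rows)


def hsp_analysis(net: NetworkSpec, hsp: str,
                 conditions: Sequence[Mapping[str, int]] = ALL_INPUT_CONDITIONS,
                 steps: int = 15) -> tuple[FateSummary, ...]:
    """Fate summaries of the HSP-extended network with the HSP clamped ON."""
    name = hsp.upper()
    if name not in HSP_NAMES:
        raise KeyError(f"unknown HSP {hsp!r}; expected one of {HSP_NAMES}")
    merged = apply_variant(net, hsp_overlay(name))
    out = []
    for c in conditions:
        clamps = dict(c)
        clamps[name] = 1
        out.append(fate_probabilities(
            enumerate_attractors(merged, clamps, steps)))
    return tuple(out)
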