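"""Cell-fate classification and basin-weighted fate statistics.

Attractor states map onto three cellular fates.  The classification rule is
pinned by its consistency with all seventeen published attractor labels:

* **apoptosis** — the executioner cascade is fully engaged: caspase-8 AND
  caspase-3 are ON;
* **DNA repair** — caspase-8 is ON (the stress response is engaged) and DNA
  damage is present but caspase-3 has not fired;
* **survival** — everything else, including states where downstream caspase
  activity exists without the caspase-8 initiator.

Fate probabilities are exact rationals on basin counts; rounding happens
only at presentation.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .attractors import Attractor, EnumerationResult
from .network import NetworkSpec

__all__ = ["FATES", "FateSummary", "VertexFrequencyTable", "classify_fate",
           "fate_probabilities", "vertex_on_frequency"]

FATES = ("survival", "apoptosis", "repair")


def classify_fate(attractor: Attractor | str, net: NetworkSpec) -> str:
    """Classify an attractor state into survival / apoptosis / repair."""
    string = attractor if isinstance(attractor, str) else attractor.state_string
    if len(string) != net.n:
        raise ValueError(f"state string length {len(string)} != {net.n} vertices")
    casp8 = string[net.index("CASP8")] == "1"
    casp3 = string[net.index("CASP3")] == "1"
    damage = string[net.index("DNADAM")] == "1"
    if casp8 and casp3:
        return "apoptosis"
    if casp8 and damage:
        return "repair"
    return "survival"


@dataclass(frozen=True)
class FateSummary:
    """Basin-weighted fate probabilities under one clamp condition."""

    condition: tuple[tuple[str, int], ...]
    f_survival: Fraction
    f_apoptosis: Fraction
    f_repair: Fraction
    attractor_fates: tuple[tuple[str, str, int], ...]  # (state, fate, basin)

    def fraction(self, fate: str) -> Fraction:
        return {"survival": self.f_survival, "apoptosis": self.f_apoptosis,
                "repair": self.f_repair}[fate]

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {f: round(float(self.fraction(f)), ndigits) for f in FATES}

    def to_frame(self) -> pd.DataFrame:
        cond = dict(self.condition)
        return pd.DataFrame([
            {**cond, "fate": f, "f_exact": str(self.fraction(f)),
             "f": float(self.fraction(f))}
            for f in FATES
        ])


def fate_probabilities(res: EnumerationResult) -> FateSummary:
    """Fate probabilities from an enumeration's basin partition."""
    total = res.total_states
    weights = {f: Fraction(0) for f in FATES}
    per_attractor = []
    for a in res.attractors:
        fate = classify_fate(a, res.network)
        weights[fate] += Fraction(a.basin_size, total)
        per_attractor.append((a.state_string, fate, a.basin_size))
    assert sum(weights.values()) == 1
    return FateSummary(res.condition, weights["survival"], weights["apoptosis"],
                       weights["repair"], tuple(per_attractor))


@dataclass(frozen=True)
class VertexFrequencyTable:
    """Basin-weighted ON-percentage of each vertex within one fate."""

    condition: tuple[tuple[str, int], ...]
    fate: str
    percentages: tuple[tuple[str, Fraction], ...]

    def percent(self, name: str) -> Fraction:
        return dict(self.percentages)[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"vertex": v, "on_percent": float(p)} for v, p in self.percentages])


def vertex_on_frequency(res: EnumerationResult, fate: str) -> VertexFrequencyTable:
    """ON-state frequency of every vertex over the attractors of one fate.

    The percentage for vertex *v* is 100 x (summed basins of the attractors
    of the given fate whose *v* bit is ON) / (all initial states), so the
    values are bounded by 100 x the fate probability.
    """
    if fate not in FATES:
        raise ValueError(f"unknown fate {fate!r}")
    net = res.network
    total = res.total_states
    acc = [Fraction(0)] * net.n
    for a in res.attractors:
        if classify_fate(a, net) != fate:
            continue
        for i, c in enumerate(a.state_string):
            if c == "1":
                acc[i] += Fraction(100 * a.basin_size, total)
    return VertexFrequencyTable(res.condition, fate,
                                tuple(zip(net.names, acc)))
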