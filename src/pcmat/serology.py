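"""Serum avidity readout: hapten-valency ELISA surrogate.

Plates carry a carrier protein bearing either few (NP7) or many (NP28)
hapten copies.  Binding to the densely haptenated plate is nearly
affinity-independent (avidity rescues weak antibodies), while the sparse
plate discriminates by affinity, so the NP7/NP28 signal ratio rises as the
serum mixture shifts toward high-affinity species.  The functional form
used here -- each species binds with an effective dissociation constant
kd/n and contributes in proportion to the epitope count n -- is a modeling
choice whose single-species limits are analytic: the ratio spans
(7*7)/(28*28) = 0.0625 (kd -> infinity) to 7/28 = 0.25 (kd -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .simulate import SerumSample


@dataclass(frozen=True)
class AvidityModel:
    """Plate valencies and signal scale of the ELISA surrogate."""

    valency_low: int = 7
    valency_high: int = 28
    plate_capacity: float = 1.0

    def __post_init__(self):
        if not (0 < self.valency_low < self.valency_high):
            raise ValueError("need 0 < valency_low < valency_high")


def elisa_signal(serum: SerumSample, valency: int, plate_capacity: float = 1.0) -> float:
    """Total plate signal from a serum mixture at the given hapten valency.

    ``sum_i n * c_i / (c_i + kd_i / n)``: additive over species, monotone
    in every concentration and every affinity.
    """
    if valency <= 0:
        raise ValueError(f"valency must be > 0, got {valency}")
    total = 0.0
    for conc, kd, _clone in serum.species:
        if conc < 0 or kd <= 0:
            raise ValueError("species need concentration >= 0 and kd > 0")
        if conc > 0:
            total += valency * conc / (conc + kd / valency)
    return plate_capacity * total


def _unit_dilution(serum: SerumSample) -> SerumSample:
    """Rescale a mixture to unit total antibody concentration.

    Real avidity ELISAs compare plates at standardized serum dilutions
    (against an IgG standard); measuring at a fixed total concentration is
    what makes the ratio a property of the mixture's affinity composition
    rather than of its amount.
    """
    total = sum(c for c, _, _ in serum.species)
    if total <= 0:
        return serum
    return SerumSample(
        timepoint=serum.timepoint,
        species=[(c / total, kd, clone) for c, kd, clone in serum.species],
    )


def np_ratio(serum: SerumSample, model: AvidityModel = AvidityModel()) -> float:
    """NP7/NP28 signal ratio at standardized dilution; the avidity surrogate.

    The mixture is rescaled to unit total concentration before the two
    plate signals are computed, so the ratio is invariant to uniform
    scaling of all concentrations and bounded in (low^2/high^2, low/high).
    Raises on an empty serum (zero high-valency signal is undefined).
    """
    serum = _unit_dilution(serum)
    hi = elisa_signal(serum, model.valency_high, model.plate_capacity)
    if hi == 0:
        raise ValueError("zero high-valency signal: ratio undefined")
    lo = elisa_signal(serum, model.valency_low, model.plate_capacity)
    return lo / hi


def ratio_series(
    series: Sequence[SerumSample], model: AvidityModel = AvidityModel()
) -> pd.DataFrame:
    """NP7/NP28 ratio at every timepoint with a non-empty serum."""
    rows = []
    for s in series:
        if not s.species or all(c == 0 for c, _, _ in s.species):
            continue
        rows.append({"timepoint": s.timepoint, "np_ratio": np_ratio(s, model)})
    return pd.DataFrame(rows, columns=["timepoint", "np_ratio"])


def affinity_fold_change(
    series: Sequence[SerumSample],
    t_early: int,
    t_late: int,
    model: AvidityModel = AvidityModel(),
) -> float:
    """Ratio of NP7/NP28 at ``t_late`` over ``t_early``."""
    by_t = {s.timepoint: s for s in series}
    for t in (t_early, t_late):
        if t not in by_t:
            raise ValueError(f"timepoint {t} not present in serum series")
    return np_ratio(by_t[t_late], model) / np_ratio(by_t[t_early], model)
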