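"""Division-label (H2B-mCherry dilution) analysis.

After doxycycline shuts off label synthesis, fluorescence halves with each
division, so dim cells are the ones that divided.  This module gates cells
into LO / MID / HI label classes, compares a per-cell flag (e.g. the
high-affinity V gene) between the divided (LO) and undivided (HI) gates
with a paired per-animal test, and estimates the division-affinity
coupling as the least-squares slope of division count on log-affinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .report import TestResult, run_test

LO, MID, HI = "LO", "MID", "HI"


@dataclass(frozen=True)
class GateSpec:
    """How to split a fluorescence distribution into LO/MID/HI.

    ``quantile`` gates take the outer quantiles of the population
    (defaults: bottom and top quartile); ``threshold`` gates use absolute
    fluorescence cut-offs.  With ``lo_thresh == hi_thresh`` the single
    threshold splits LO (below) from HI (at or above), with no MID gate.
    """

    method: str = "quantile"
    lo_q: float = 0.25
    hi_q: float = 0.75
    lo_thresh: float | None = None
    hi_thresh: float | None = None

    def validate(self) -> None:
        if self.method not in ("quantile", "threshold"):
            raise ValueError(f"unknown gate method {self.method!r}")
        if self.method == "quantile":
            if not 0 < self.lo_q < self.hi_q < 1:
                raise ValueError(
                    f"need 0 < lo_q < hi_q < 1, got {self.lo_q}, {self.hi_q}"
                )
        else:
            if self.lo_thresh is None or self.hi_thresh is None:
                raise ValueError("threshold method requires lo_thresh and hi_thresh")
            if self.lo_thresh <= 0 or self.hi_thresh <= 0:
                raise ValueError("thresholds must be positive")
            if self.lo_thresh > self.hi_thresh:
                raise ValueError("lo_thresh must be <= hi_thresh")


@dataclass
class GateResult:
    gates: pd.Series  # LO/MID/HI per cell, aligned to input
    degenerate: bool  # all-equal fluorescence split only by tie-break


def gate_by_label(
    cells: pd.DataFrame,
    spec: GateSpec = GateSpec(),
    mcherry_col: str = "c_mcherry",
    cell_id_col: str = "cell_id",
) -> GateResult:
    """Assign each cell to the LO, MID or HI label gate.

    Quantile gates are rank-based with deterministic tie-breaking by cell
    id: after sorting by (fluorescence, cell_id), the lowest ``lo_q``
    fraction is LO and the highest ``1 - hi_q`` fraction is HI.
    """
    spec.validate()
    n = len(cells)
    if n == 0:
        return GateResult(pd.Series([], dtype=object), degenerate=False)
    if n < 10:
        warnings.warn(f"gating only {n} cells; gates will be noisy", stacklevel=2)
    values = cells[mcherry_col].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("fluorescence must be >= 0")
    degenerate = bool(np.all(values == values[0]))
    gates = np.array([MID] * n, dtype=object)
    if spec.method == "threshold":
        gates[values < spec.lo_thresh] = LO
        if spec.lo_thresh == spec.hi_thresh:
            gates[values >= spec.hi_thresh] = HI
        else:
            gates[values > spec.hi_thresh] = HI
    else:
        ids = cells[cell_id_col].astype(str).to_numpy()
        order = np.lexsort((ids, values))
        n_lo = int(np.floor(spec.lo_q * n))
        n_hi = int(np.floor((1.0 - spec.hi_q) * n))
        gates[order[:n_lo]] = LO
        if n_hi > 0:
            gates[order[n - n_hi:]] = HI
    return GateResult(pd.Series(gates, index=cells.index), degenerate=degenerate)


@dataclass
class DivisionComparison:
    """Paired LO-vs-HI comparison of a per-cell flag across animals."""

    per_animal: pd.DataFrame  # animal, freq_lo, freq_hi, n_lo, n_hi
    test: TestResult | None
    direction: str  # "LO>HI", "HI>LO" or "none"
    degenerate: bool
    excluded_animals: tuple[str, ...]


def compare_by_division(
    cells: pd.DataFrame,
    flag_col: str,
    spec: GateSpec = GateSpec(),
    animal_col: str = "c_animal",
    mcherry_col: str = "c_mcherry",
) -> DivisionComparison:
    """Per-animal frequency of ``flag_col`` in the LO vs HI label gates.

    Gates are drawn within each animal's cell population (each animal is
    its own flow sample).  Animals with an empty gate are excluded with a
    warning.  The paired two-sided t-test runs across animals when at
    least two contribute.
    """
    rows = []
    excluded = []
    degenerate = False
    for animal, grp in cells.groupby(animal_col, sort=True):
        res = gate_by_label(grp, spec, mcherry_col=mcherry_col)
        degenerate = degenerate or res.degenerate
        lo = grp[res.gates == LO]
        hi = grp[res.gates == HI]
        if len(lo) == 0 or len(hi) == 0:
            excluded.append(str(animal))
            warnings.warn(f"animal {animal}: empty gate, excluded", stacklevel=2)
            continue
        rows.append(
            {
                "animal": animal,
                "freq_lo": float(lo[flag_col].mean()),
                "freq_hi": float(hi[flag_col].mean()),
                "n_lo": len(lo),
                "n_hi": len(hi),
            }
        )
    per_animal = pd.DataFrame(rows)
    test = None
    direction = "none"
    if len(per_animal) >= 2:
        test = run_test(
            "t", [per_animal["freq_lo"], per_animal["freq_hi"]], paired=True
        )
        diff = float((per_animal["freq_lo"] - per_animal["freq_hi"]).mean())
        if diff > 0:
            direction = "LO>HI"
        elif diff < 0:
            direction = "HI>LO"
    return DivisionComparison(
        per_animal=per_animal,
        test=test,
        direction=direction,
        degenerate=degenerate,
        excluded_animals=tuple(excluded),
    )


@dataclass
class CouplingEstimate:
    """Least-squares division-affinity coupling with bootstrap CI."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int
    constant_affinity: bool


def estimate_coupling(
    cells: pd.DataFrame,
    divisions_col: str = "divisions_since_label",
    affinity_col: str = "affinity",
    n_boot: int = 1000,
    ci: float = 0.95,
    rng: np.random.Generator | None = None,
) -> CouplingEstimate:
    """Slope of division count on log-affinity, with a bootstrap CI.

    The percentile CI uses ``n_boot`` case resamples from a seeded
    generator.  Constant affinity leaves the slope undefined and is
    flagged rather than raising.
    """
    rng = rng or np.random.default_rng()
    x = np.log(cells[affinity_col].to_numpy(dtype=float))
    y = cells[divisions_col].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("estimate_coupling needs at least 3 cells")
    if np.allclose(x, x[0]):
        return CouplingEstimate(
            slope=float("nan"),
            intercept=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            n=n,
            constant_affinity=True,
        )
    slope, intercept = np.polyfit(x, y, 1)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    mx = bx.mean(axis=1, keepdims=True)
    my = by.mean(axis=1, keepdims=True)
    varx = ((bx - mx) ** 2).mean(axis=1)
    cov = ((bx - mx) * (by - my)).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = cov / varx
    slopes = slopes[np.isfinite(slopes)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(slopes, [alpha, 1.0 - alpha])
    return CouplingEstimate(
        slope=float(slope),
        intercept=float(intercept),
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        constant_affinity=False,
    )
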