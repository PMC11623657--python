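"""Vectorized PC-cohort samplers built from the same help-division primitives.

These samplers draw plasma-cell tables directly from the
capture -> Myc -> budget chain, skipping the GC agent loop.  They exist for
calibration studies that need thousands of replicate experiments (type-I
error of the divided-vs-undivided comparison, recovery of a known
division-affinity coupling slope), where the full simulator would be
needlessly slow and adds nothing: the quantity under test is a property of
the analysis, not of GC dynamics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def sample_pc_cohort(
    n: int,
    slope: float,
    intercept: float = 4.0,
    affinity_sigma: float = 0.6,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample PCs whose mean division count is linear in log-affinity.

    Divisions are Poisson with mean ``max(0, intercept + slope *
    log(affinity))``; affinities are lognormal with the given log-sd.  The
    default intercept (about four divisions, the scale of simulated export
    budgets) keeps truncation at zero negligible for slopes up to ~5, so
    the generative ``slope`` is exactly the least-squares target of
    :func:`pcmat.division.estimate_coupling`.
    """
    rng = rng or np.random.default_rng()
    log_aff = rng.normal(0.0, affinity_sigma, size=n)
    mean = np.maximum(0.0, intercept + slope * log_aff)
    divisions = rng.poisson(mean)
    return pd.DataFrame(
        {
            "affinity": np.exp(log_aff),
            "divisions_since_label": divisions,
        }
    )


def sample_division_experiment(
    n_animals: int = 5,
    n_cells: int = 150,
    target_v_fraction: float = 0.4,
    target_affinity: float = 3.0,
    other_affinity: float = 1.0,
    affinity_sigma: float = 0.35,
    capture_cmax: float = 1.0,
    capture_K: float = 1.0,
    myc_m0: float = 0.3,
    myc_k: float = 2.0,
    division_beta: float = 2.0,
    mcherry_f0: float = 1000.0,
    label_noise_sigma: float = 0.15,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample one multi-animal division-tracking experiment.

    Each cell's division count is Poisson with mean ``beta * (m0 + k *
    capture(affinity))`` -- the model's budget chain.  With ``myc_k=0``
    divisions are independent of affinity and of the V gene, which is the
    null hypothesis of the divided-vs-undivided comparisons.  mCherry is
    ``F0 * 2^-divisions`` with multiplicative lognormal noise.
    """
    rng = rng or np.random.default_rng()
    frames = []
    for a in range(n_animals):
        is_target = rng.random(n_cells) < target_v_fraction
        base = np.where(is_target, target_affinity, other_affinity)
        affinity = base * np.exp(rng.normal(0.0, affinity_sigma, size=n_cells))
        captured = capture_cmax * affinity / (affinity + capture_K)
        myc = myc_m0 + myc_k * captured
        divisions = rng.poisson(division_beta * myc)
        noise = np.exp(rng.normal(0.0, label_noise_sigma, size=n_cells))
        mcherry = mcherry_f0 * np.power(0.5, divisions) * noise
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"a{a}.{i}" for i in range(n_cells)],
                    "c_animal": f"a{a}",
                    "target_v": is_target,
                    "affinity": affinity,
                    "divisions_since_label": divisions,
                    "c_mcherry": mcherry,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
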