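"""Clonal diversity statistics: Chao1 richness, clone sizes, expansion.

Richness is computed on clone abundances by default (one count per clone);
pass node-level abundances for the sequence-genotype variant.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd


def chao1(abundances: Sequence[int]) -> float:
    """Bias-corrected Chao1 species-richness estimator.

    ``S_obs + f1 * (f1 - 1) / (2 * (f2 + 1))`` where f1 and f2 are the
    singleton and doubleton counts; defined for f2 = 0, and equal to the
    observed richness when f1 <= 1.
    """
    counts = np.asarray(list(abundances), dtype=int)
    if counts.size == 0:
        raise ValueError("chao1 requires a non-empty abundance vector")
    if (counts < 1).any():
        raise ValueError("abundances must all be >= 1")
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def clone_sizes(annotated: pd.DataFrame, clone_col: str = "clone_id") -> list[int]:
    """Per-clone cell counts, sorted descending then by clone id (deterministic)."""
    if annotated.empty:
        return []
    sizes = annotated.groupby(clone_col).size()
    order = sorted(sizes.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [int(s) for _, s in order]


def expanded_fraction(sizes: Sequence[int]) -> float:
    """Percentage of cells belonging to clones of size >= 2."""
    sizes = list(sizes)
    if not sizes:
        raise ValueError("expanded_fraction requires a non-empty size list")
    total = sum(sizes)
    expanded = sum(s for s in sizes if s >= 2)
    return 100.0 * expanded / total


def diversity_table(
    annotated: pd.DataFrame,
    by: Sequence[str] = ("c_animal",),
    clone_col: str = "clone_id",
) -> pd.DataFrame:
    """Per-stratum richness summary: n_cells, n_clones, chao1, expanded %."""
    rows = []
    for key, grp in annotated.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        sizes = clone_sizes(grp, clone_col)
        rows.append(
            {
                **dict(zip(by, key)),
                "n_cells": len(grp),
                "n_clones": len(sizes),
                "chao1": chao1(sizes),
                "expanded_pct": expanded_fraction(sizes),
            }
        )
    return pd.DataFrame(rows)
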