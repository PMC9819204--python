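"""Zero-anchored quantile scoring of relative abundances.

Zero-inflated taxa make ordinary quantile scoring degenerate (most samples
tie at 0), so exact zeros are anchored at score 0 and only the positive
values are split into quantile groups.  With ``levels=4`` positives are
tertile-scored 1/2/3; with ``levels=3`` and ``split="median"`` positives
score 1 below their median and 2 at or above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import AbundanceTable

__all__ = ["RankedMatrix", "zero_anchored_rank", "rank_table"]


@dataclass
class RankedMatrix:
    """Integer-scored samples × taxa matrix with entries in {0, ..., levels-1}."""

    scores: pd.DataFrame  # int dtype, index = sample ids, columns = taxon ids
    levels: int
    split: str

    @property
    def sample_ids(self) -> list:
        return list(self.scores.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.scores.columns)

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy()


def zero_anchored_rank(values, levels: int = 4, split: str = "quantile") -> np.ndarray:
    """Score a nonnegative vector: 0 stays 0, positives go to 1..levels-1.

    ``split="quantile"`` places cut points at the k/(levels-1) empirical
    quantiles (linear interpolation) of the *positive* values, k = 1..levels-2;
    values tied with a cut point take the lower group's score.
    ``split="median"`` (levels=3 only) scores positives 1 if strictly below
    their median and 2 if greater than or equal to it.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if split not in ("quantile", "median"):
        raise ValueError(f"unknown split {split!r}")
    if split == "median" and levels != 3:
        raise ValueError("median split is defined for levels=3 only")
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("values must be nonnegative")
    scores = np.zeros(x.shape, dtype=np.int64)
    pos_mask = x > 0
    pos = x[pos_mask]
    if pos.size == 0:
        return scores
    if split == "median":
        med = np.median(pos)
        scores[pos_mask] = np.where(pos < med, 1, 2)
        return scores
    if levels == 2:
        scores[pos_mask] = 1
        return scores
    cuts = np.quantile(pos, np.arange(1, levels - 1) / (levels - 1))
    # ties at a cut point fall to the lower group (strict > moves you up)
    scores[pos_mask] = 1 + (pos[:, None] > cuts[None, :]).sum(axis=1)
    return scores


def rank_table(
    table: AbundanceTable, levels: int = 4, split: str = "quantile"
) -> RankedMatrix:
    """Apply :func:`zero_anchored_rank` to every taxon column of a relative table."""
    if table.mode != "relative":
        raise ValueError("rank_table expects a relative-abundance table")
    vals = table.values
    out = np.empty(vals.shape, dtype=np.int64)
    for j in range(vals.shape[1]):
        out[:, j] = zero_anchored_rank(vals[:, j], levels=levels, split=split)
    scores = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return RankedMatrix(scores=scores, levels=levels, split=split)
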