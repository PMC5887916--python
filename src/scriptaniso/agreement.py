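"""Inter-rater agreement: two-way, absolute-agreement, average-measures ICC.

Used to compare two coders' script-level measurements, and Unicode-derived
against manuscript-derived measurements. The statistic is ICC(A,k) in the
McGraw & Wong nomenclature, computed from the two-way ANOVA mean squares:

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

with rows = items (scripts), columns = raters, n = number of items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class RatingMatrix:
    """An items x raters table of one script-level measure.

    Rows with any missing cell are dropped listwise (and counted) before the
    ANOVA; at least two complete rows and two raters are required.
    """

    values: np.ndarray
    item_ids: list[str]
    rater_ids: list[str]
    n_dropped: int = 0

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[pd.DataFrame],
        column: str,
        key: str = "script",
        rater_ids: Optional[Sequence[str]] = None,
    ) -> "RatingMatrix":
        """Align per-rater measure tables on the key column."""
        if len(frames) < 2:
            raise ValueError("need at least two raters")
        rater_ids = list(rater_ids) if rater_ids else [f"rater{i+1}" for i in range(len(frames))]
        merged = None
        for rid, f in zip(rater_ids, frames):
            part = f[[key, column]].rename(columns={column: rid})
            merged = part if merged is None else merged.merge(part, on=key, how="outer")
        total = len(merged)
        complete = merged.dropna()
        return cls(
            values=complete[rater_ids].to_numpy(dtype=float),
            item_ids=complete[key].astype(str).tolist(),
            rater_ids=rater_ids,
            n_dropped=total - len(complete),
        )


@dataclass(frozen=True)
class IccResult:
    icc: float
    n_used: int
    k_raters: int
    n_dropped: int
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc_a_k(matrix: RatingMatrix) -> IccResult:
    """Two-way absolute-agreement average-measures intraclass correlation.

    Raises on fewer than two complete items, fewer than two raters, or a
    matrix with no variance at all (the ANOVA decomposition is degenerate).
    """
    x = np.asarray(matrix.values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("rating matrix needs at least 2 raters")
    if np.isnan(x).any():
        raise ValueError("rating matrix contains missing cells after row dropping")
    n, k = x.shape
    if n < 2:
        raise ValueError(f"need at least 2 complete items, got {n}")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("degenerate input: zero total variance")

    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (msc - mse) / n)
    return IccResult(
        icc=float(icc),
        n_used=n,
        k_raters=k,
        n_dropped=matrix.n_dropped,
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
    )
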