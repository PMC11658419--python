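"""Condition tables and z-score normalization for cross-condition heatmaps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConditionTable", "z_score_normalize", "build_condition_table"]


def z_score_normalize(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-column (x - mean)/SD with sample SD (ddof 1).

    Raises on a zero-variance column, naming it. Output columns have mean 0
    and SD 1; applying the transform twice is the identity up to rounding.
    """
    out = table.copy()
    cols = columns if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    for c in cols:
        x = table[c].to_numpy(dtype=np.float64)
        if np.any(~np.isfinite(x)):
            raise ValueError(f"column {c!r} contains non-finite values")
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero standard deviation; cannot z-score")
        out[c] = (x - x.mean()) / sd
    return out


@dataclass
class ConditionTable:
    """Replicate-aggregated metrics per experimental condition."""

    means: pd.DataFrame  # index: condition, columns: metrics
    sds: pd.DataFrame
    n_replicates: pd.Series
    reference: str | None = None

    def relative_to_reference(self) -> pd.DataFrame:
        if self.reference is None or self.reference not in self.means.index:
            raise ValueError(
                f"reference condition {self.reference!r} not present in the table"
            )
        return self.means / self.means.loc[self.reference]

    def zscored(self) -> pd.DataFrame:
        """Z-score the condition means per metric (over all conditions)."""
        return z_score_normalize(self.means)


def build_condition_table(
    replicates: pd.DataFrame,
    condition_col: str = "condition",
    reference: str | None = None,
    metrics: list[str] | None = None,
) -> ConditionTable:
    """Aggregate replicate rows into per-condition mean ± SD.

    ``replicates`` holds one row per replicate with a condition column and
    numeric metric columns. If ``reference`` is given it must be present.
    """
    if condition_col not in replicates.columns:
        raise ValueError(f"no condition column {condition_col!r} in replicate table")
    cols = metrics or [
        c for c in replicates.columns
        if c != condition_col and pd.api.types.is_numeric_dtype(replicates[c])
    ]
    if not cols:
        raise ValueError("no numeric metric columns found")
    grouped = replicates.groupby(condition_col, sort=True)[cols]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    n = grouped.size()
    if reference is not None and reference not in means.index:
        raise ValueError(f"reference condition {reference!r} has no replicates")
    if means.isna().any().any():
        raise ValueError("aggregated table contains missing values")
    return ConditionTable(means=means, sds=sds, n_replicates=n, reference=reference)
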