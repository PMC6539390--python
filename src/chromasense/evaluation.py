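"""Batch-wise splitting, regression metrics, and multi-run summaries.

The calibration/validation split is always by whole culture batch (the
first ``n_cal_batches`` batches calibrate, the rest validate): samples
within a batch share growth history, so a within-batch split would leak
batch identity into validation.  Metrics follow chemometrics reporting:
Rc2/RMSECV on the calibration set of the single fitted model, Rp2/RMSEP
on the validation set, with mean/variance/sd over repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mean_squared_error, r2_score

from .synthetic import FEATURE_NAMES

__all__ = ["SplitDataset", "MetricSummary", "split_by_batch", "r2", "rmse",
           "summarize_runs"]


@dataclass
class SplitDataset:
    """Calibration/validation partition of a sample table, by whole batch.

    ``feature_columns`` defaults to the 36 study feature names; any other
    tabular layout can override it.
    """

    calibration: pd.DataFrame
    validation: pd.DataFrame
    n_cal_batches: int
    feature_columns: tuple[str, ...] = FEATURE_NAMES

    def xy(self, subset: str, target: str = "od_measured"):
        """(features, target) arrays for 'calibration' or 'validation'."""
        frame = getattr(self, subset)
        return (frame[list(self.feature_columns)].to_numpy(dtype=float),
                frame[target].to_numpy(dtype=float))


def split_by_batch(frame: pd.DataFrame, n_cal_batches: int = 6) -> SplitDataset:
    """Order-preserving, batch-complete calibration/validation split.

    The first ``n_cal_batches`` batches (in order of first appearance)
    form the calibration set; all remaining batches validate.
    """
    if "batch_id" not in frame.columns:
        raise ValueError("frame must carry a batch_id column")
    batches = frame["batch_id"].drop_duplicates().tolist()
    if n_cal_batches >= len(batches):
        raise ValueError(
            f"n_cal_batches={n_cal_batches} must leave at least one of the "
            f"{len(batches)} batches for validation")
    cal_ids = set(batches[:n_cal_batches])
    in_cal = frame["batch_id"].isin(cal_ids)
    return SplitDataset(calibration=frame[in_cal].reset_index(drop=True),
                        validation=frame[~in_cal].reset_index(drop=True),
                        n_cal_batches=n_cal_batches)


def r2(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSE/SST."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size < 2:
        raise ValueError("y and y_pred must share length >= 2")
    if np.ptp(y) == 0:
        raise ValueError("r2 undefined for constant y")
    return float(r2_score(y, y_pred))


def rmse(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.size == 0 or y.shape != y_pred.shape:
        raise ValueError("y and y_pred must share non-zero length")
    return float(np.sqrt(mean_squared_error(y, y_pred)))


@dataclass(frozen=True)
class MetricSummary:
    """Mean / sample variance / sd of a metric over repeated runs.

    Both variance and sd are carried so a "mean +/- spread" report can
    use either convention.
    """

    mean: float
    variance: float
    sd: float
    n_runs: int


def summarize_runs(values) -> MetricSummary:
    """Summarize a metric over independent runs (sample, n-1, variance)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to summarize")
    var = float(v.var(ddof=1))
    return MetricSummary(mean=float(v.mean()), variance=var,
                         sd=float(np.sqrt(var)), n_runs=int(v.size))
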