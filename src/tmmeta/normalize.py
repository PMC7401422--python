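"""Quantile normalization and automated sample-level quality control.

The pipeline operates on log2-intensity matrices (probes x samples).
Quality control is an automated surrogate for curator review: each sample's
median Pearson correlation against the other samples and its signal
distribution are reported, and weakly-correlated samples are flagged.
Flagged samples are never dropped silently; the caller decides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A log2-intensity expression matrix with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame, rows indexed by probe_id, columns by sample_id.
    metadata
        DataFrame indexed by sample_id with columns ``individual``,
        ``condition`` (``treated`` / ``control``) and ``replicate``.
    study_id
        Optional study label carried through the pipeline.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    study_id: str = ""

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate probe_ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in expression matrix")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def probe_ids(self):
        return self.values.index

    @property
    def sample_ids(self):
        return self.values.columns

    def drop_samples(self, samples) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s not in set(samples)]
        return ExpressionMatrix(
            self.values[keep], self.metadata.loc[keep], study_id=self.study_id
        )


@dataclass
class QCReport:
    """Per-sample QC metrics and outlier flags."""

    metrics: pd.DataFrame  # sample_id index; median_correlation, signal_median, signal_iqr, flagged, reason
    flag_threshold: float
    flagged_samples: set = field(default_factory=set)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the same empirical value distribution.

    Each column's values are replaced by the mean, across samples, of the
    values at the same rank; tied values within a column receive the mean
    of the rank-means they span. After the call every column's sorted
    vector is identical.
    """
    vals = m.values.to_numpy(dtype=float)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 probes and >=2 samples")
    if not np.isfinite(vals).all():
        bad = np.argwhere(~np.isfinite(vals))
        cells = [
            f"({m.values.index[i]}, {m.values.columns[j]})" for i, j in bad[:10]
        ]
        raise ValueError(f"non-finite values at cells: {', '.join(cells)}")

    rank_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = rank_means
        # ties within a column -> mean of the rank-means they span
        s = pd.Series(assigned)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.metadata,
        study_id=m.study_id,
    )


def qc_flag_samples(m: ExpressionMatrix, min_median_correlation: float = 0.8) -> QCReport:
    """Flag samples poorly correlated with the rest of the study.

    A sample is flagged when its median Pearson correlation against every
    other sample falls below ``min_median_correlation``, or when it is
    constant (correlation undefined).
    """
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[1]
    if n < 3:
        raise ValueError("QC needs >=3 samples")
    sds = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals.T)
    med_corr = np.full(n, np.nan)
    reasons = [""] * n
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        if sds[i] == 0:
            flagged[i] = True
            reasons[i] = "zero variance"
            continue
        others = [corr[i, j] for j in range(n) if j != i and sds[j] > 0]
        if others:
            med_corr[i] = float(np.median(others))
            if med_corr[i] < min_median_correlation:
                flagged[i] = True
                reasons[i] = f"median correlation {med_corr[i]:.3f} < {min_median_correlation}"
    q75, q25 = np.percentile(vals, [75, 25], axis=0)
    metrics = pd.DataFrame(
        {
            "median_correlation": med_corr,
            "signal_median": np.median(vals, axis=0),
            "signal_iqr": q75 - q25,
            "flagged": flagged,
            "reason": reasons,
        },
        index=pd.Index(m.values.columns, name="sample_id"),
    )
    return QCReport(
        metrics=metrics,
        flag_threshold=min_median_correlation,
        flagged_samples=set(metrics.index[metrics["flagged"]]),
    )
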