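"""Inter-array-correlation outlier screening.

Technical outlier arrays on methylation chips show up as samples whose
beta profile barely correlates with everyone else's.  The screen computes
the sample-by-sample Pearson correlation matrix across CpGs, summarizes
each array by its mean correlation with all others, and flags arrays whose
robust z-score (median/MAD) falls below a conservative cutoff (default
-5).  An average-linkage dendrogram on the correlation distance 1 - r is
included so the classical visual check on the clustering can be replicated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, OutlierMixin

from .io import BetaMatrix

__all__ = [
    "QCReport",
    "interarray_correlation",
    "flag_outliers",
    "run_qc",
    "InterArrayOutlierDetector",
]

_MAD_SCALE = 1.4826  # makes MAD consistent with the SD under normality
_ABS_FALLBACK = 0.5


@dataclass
class QCReport:
    """Per-sample QC statistics plus the clustering used for visual review.

    ``samples`` columns: ``mean_corr`` (mean inter-array correlation),
    ``robust_z``, ``outlier``.  ``linkage`` is the scipy merge history of
    average-linkage clustering on 1 - r (None when fewer than 2 valid
    arrays).  ``mad_fallback`` records that the MAD was zero and the
    absolute cutoff mean_corr < 0.5 was used instead.
    """

    samples: pd.DataFrame
    z_cut: float
    linkage: np.ndarray | None
    linkage_method: str = "average"
    mad_fallback: bool = False

    @property
    def outlier_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["outlier"]])

    def to_dict(self) -> dict:
        return {
            "z_cut": self.z_cut,
            "mad_fallback": self.mad_fallback,
            "linkage_method": self.linkage_method,
            "outlier_ids": self.outlier_ids,
            "samples": self.samples.reset_index().to_dict(orient="list"),
            "linkage": None if self.linkage is None else self.linkage.tolist(),
        }


def interarray_correlation(beta: BetaMatrix) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of beta profiles across CpGs.

    Missing cells are per-CpG mean-imputed first.  A zero-variance array
    has no defined correlation; its row and column are reported missing
    (and such arrays are auto-flagged downstream).
    """
    if beta.n_samples < 3:
        raise ValueError("inter-array correlation needs at least 3 samples")
    v = beta.imputed()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(v, rowvar=False)
    degenerate = np.flatnonzero(np.ptp(v, axis=0) == 0)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=beta.sample_ids, columns=beta.sample_ids)


def flag_outliers(
    corr: pd.DataFrame,
    z_cut: float = -5.0,
    linkage_method: str = "average",
) -> QCReport:
    """Flag technical outliers from an inter-array correlation matrix.

    Statistic: each array's mean correlation with all other arrays.
    Rule: robust z = (statistic - median) / (1.4826 * MAD) < ``z_cut``
    AND mean correlation < 0.5.  The absolute guard keeps the rule
    deliberately conservative: biological structure (e.g. arrays from
    animals at the extremes of the age range) produces genuine left tails
    in the mean-correlation distribution, and an array that still tracks
    the cohort closely is never removed on the z-score alone.  A zero MAD
    (all arrays essentially identical) falls back to the absolute rule by
    itself.  Arrays with undefined correlations (zero variance) are always
    flagged.
    """
    c = corr.to_numpy(dtype=float, copy=True)
    n = c.shape[0]
    if c.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    off = c.copy()
    np.fill_diagonal(off, np.nan)
    with np.errstate(invalid="ignore"):
        mean_corr = np.nanmean(off, axis=1)
    invalid = np.isnan(mean_corr)

    valid_means = mean_corr[~invalid]
    med = float(np.median(valid_means)) if valid_means.size else np.nan
    mad = float(np.median(np.abs(valid_means - med))) if valid_means.size else np.nan
    robust_z = np.full(n, np.nan)
    mad_fallback = False
    if valid_means.size:
        if mad > 0:
            robust_z[~invalid] = (valid_means - med) / (_MAD_SCALE * mad)
            flags = (robust_z < z_cut) & (mean_corr < _ABS_FALLBACK)
            # NaN comparisons are False; invalid arrays flagged below
            flags = np.where(invalid, True, flags)
        else:
            mad_fallback = True
            flags = np.where(invalid, True, mean_corr < _ABS_FALLBACK)
    else:
        flags = np.ones(n, dtype=bool)

    link = None
    valid_idx = np.flatnonzero(~invalid)
    if valid_idx.size >= 2:
        sub = c[np.ix_(valid_idx, valid_idx)]
        dist = 1.0 - sub
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        link = linkage(squareform(dist, checks=False), method=linkage_method)

    samples = pd.DataFrame(
        {
            "mean_corr": mean_corr,
            "robust_z": robust_z,
            "outlier": flags.astype(bool),
        },
        index=pd.Index(corr.index, name="sample_id"),
    )
    return QCReport(
        samples=samples,
        z_cut=float(z_cut),
        linkage=link,
        linkage_method=linkage_method,
        mad_fallback=mad_fallback,
    )


def run_qc(
    beta: BetaMatrix, z_cut: float = -5.0, linkage_method: str = "average"
) -> QCReport:
    """Convenience: correlation matrix + outlier flags in one call."""
    return flag_outliers(
        interarray_correlation(beta), z_cut=z_cut, linkage_method=linkage_method
    )


class InterArrayOutlierDetector(OutlierMixin, BaseEstimator):
    """Estimator facade over the correlation screen.

    ``fit(X)`` takes samples x CpGs; ``labels_`` holds -1 for flagged
    arrays and 1 otherwise, and ``report_`` the full :class:`QCReport`.
    """

    def __init__(self, z_cut: float = -5.0, linkage_method: str = "average"):
        self.z_cut = z_cut
        self.linkage_method = linkage_method

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ids = [f"s{i}" for i in range(X.shape[0])]
        beta = BetaMatrix(
            [f"cg{j}" for j in range(X.shape[1])], ids, X.T
        )
        self.report_ = run_qc(
            beta, z_cut=self.z_cut, linkage_method=self.linkage_method
        )
        flags = self.report_.samples["outlier"].to_numpy()
        self.labels_ = np.where(flags, -1, 1)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
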