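"""Between-network functional connectivity (netmats) and amplitude-FC links.

The K x K connectivity matrix C is estimated as partial correlations
between the stage-1 network timeseries: C_ij = -P_ij / sqrt(P_ii P_jj)
for the inverse covariance P, i.e. the correlation between networks i and
j after removing the linear influence of all other networks.  Each
network's row is summarised into three scalars -- the mean |r|, the mean
positive r, and the mean negative r over its off-diagonal entries -- and
the summaries are then correlated with per-network amplitude measures,
either within one subject (across the K networks) or across subjects
(per network, with Bonferroni-corrected p-values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import NetworkTimeseriesSet

__all__ = [
    "NetMat",
    "SummaryFC",
    "partial_correlation",
    "full_correlation",
    "summary_fc",
    "within_subject_amp_fc",
    "across_subject_amp_fc",
]

FC_TYPES = ("absolute", "positive", "negative")


@dataclass
class NetMat:
    """K x K (partial) correlation matrix with estimator metadata."""

    C: np.ndarray
    kind: Literal["partial", "full"] = "partial"
    ridge: float = 0.0
    network_labels: list[str] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.C, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("C must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("C must have unit diagonal")
        off = c[~np.eye(c.shape[0], dtype=bool)]
        if np.any(np.abs(off) > 1 + 1e-10):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.C = c
        if self.network_labels is None:
            self.network_labels = [f"net{i + 1}" for i in range(c.shape[0])]


@dataclass
class SummaryFC:
    """Per-network absolute / positive / negative mean connectivity.

    ``positive``/``negative`` entries are NaN when a network's row has no
    entries of that sign.
    """

    absolute: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    network_labels: list[str] | None = None

    def as_frame(self) -> pd.DataFrame:
        labels = self.network_labels or [
            f"net{i + 1}" for i in range(self.absolute.size)
        ]
        return pd.DataFrame(
            {
                "network": labels,
                "absolute": self.absolute,
                "positive": self.positive,
                "negative": self.negative,
            }
        )


def _series_matrix(ts: NetworkTimeseriesSet | np.ndarray) -> tuple[np.ndarray, list | None]:
    if isinstance(ts, NetworkTimeseriesSet):
        return np.asarray(ts.series, dtype=float), ts.network_labels
    return np.asarray(ts, dtype=float), None


def partial_correlation(
    ts: NetworkTimeseriesSet | np.ndarray, ridge: float = 0.0
) -> NetMat:
    """Partial-correlation netmat from K x T network timeseries.

    ``ridge`` adds ``ridge * mean(diag(cov))`` to the covariance diagonal
    before inversion (L2 regularization of the precision estimate); the
    default of 0 is appropriate when T is comfortably larger than K.
    """
    d, labels = _series_matrix(ts)
    k, t = d.shape
    if t <= k and ridge == 0:
        raise ValueError(
            f"T={t} <= K={k}: covariance is singular at ridge 0; pass ridge > 0"
        )
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    cov = np.cov(d, ddof=1)
    cov = np.atleast_2d(cov)
    if ridge > 0:
        cov = cov + ridge * np.mean(np.diag(cov)) * np.eye(k)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance of the network timeseries is not positive definite; "
            "consider a small ridge (e.g. ridge=0.1)"
        ) from err
    from scipy.linalg import cho_solve

    p = cho_solve((chol, True), np.eye(k))
    denom = np.sqrt(np.outer(np.diag(p), np.diag(p)))
    c = -p / denom
    np.fill_diagonal(c, 1.0)
    c = (c + c.T) / 2.0  # enforce exact symmetry
    return NetMat(C=c, kind="partial", ridge=ridge, network_labels=labels)


def full_correlation(ts: NetworkTimeseriesSet | np.ndarray) -> NetMat:
    """Plain Pearson-correlation netmat (the unregularized full-correlation
    alternative to the partial-correlation default)."""
    d, labels = _series_matrix(ts)
    c = np.corrcoef(d)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return NetMat(C=c, kind="full", network_labels=labels)


def summary_fc(nm: NetMat) -> SummaryFC:
    """Absolute / positive / negative mean FC per network row, excluding the
    diagonal.  An empty sign class yields NaN for that network."""
    c = nm.C
    k = c.shape[0]
    if k < 2:
        raise ValueError("summary FC needs K >= 2 (no off-diagonal entries)")
    absolute = np.empty(k)
    positive = np.full(k, np.nan)
    negative = np.full(k, np.nan)
    for i in range(k):
        row = np.delete(c[i], i)
        absolute[i] = np.mean(np.abs(row))
        pos = row[row > 0]
        neg = row[row < 0]
        if pos.size:
            positive[i] = pos.mean()
        if neg.size:
            negative[i] = neg.mean()
    return SummaryFC(absolute, positive, negative, network_labels=nm.network_labels)


def _pairwise_r(x: np.ndarray, y: np.ndarray, min_pairs: int = 3) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_pairs:
        return np.nan
    xo, yo = x[ok], y[ok]
    if xo.std() == 0 or yo.std() == 0:
        return np.nan
    return float(np.corrcoef(xo, yo)[0, 1])


def within_subject_amp_fc(measure_row: np.ndarray, sfc: SummaryFC) -> dict:
    """Correlation, across this subject's K networks, between a per-network
    measure (e.g. network amplitude) and each FC summary type.

    NaN FC entries (empty sign classes) are pairwise-dropped; a result is
    NaN when fewer than 3 complete pairs remain or a side is constant.
    """
    measure_row = np.asarray(measure_row, dtype=float)
    if measure_row.size < 3:
        raise ValueError("within-subject correlation needs K >= 3 networks")
    return {
        "absolute": _pairwise_r(measure_row, sfc.absolute),
        "positive": _pairwise_r(measure_row, sfc.positive),
        "negative": _pairwise_r(measure_row, sfc.negative),
    }


def across_subject_amp_fc(
    measure: pd.DataFrame, sfc_per_subject: Sequence[SummaryFC]
) -> pd.DataFrame:
    """Across-subject correlation between a per-network measure and each FC
    summary type, per network.

    Returns a tidy table (network, fc_type, r, p, p_corrected) with the
    Bonferroni family taken as all K networks x 3 FC types of this analysis.
    """
    values = measure.to_numpy(dtype=float)
    s, k = values.shape
    if s < 10:
        raise ValueError("across-subject correlation needs S >= 10 subjects")
    if len(sfc_per_subject) != s:
        raise ValueError("need one SummaryFC per subject")
    stacked = {
        t: np.vstack([getattr(f, t) for f in sfc_per_subject]) for t in FC_TYPES
    }
    n_tests = k * len(FC_TYPES)
    records = []
    for j, net in enumerate(measure.columns):
        for fc_type in FC_TYPES:
            x, y = values[:, j], stacked[fc_type][:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                records.append(
                    {"network": net, "fc_type": fc_type, "r": np.nan,
                     "p": np.nan, "p_corrected": np.nan, "n": int(ok.sum())}
                )
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            records.append(
                {
                    "network": net,
                    "fc_type": fc_type,
                    "r": float(r),
                    "p": float(p),
                    "p_corrected": float(min(1.0, p * n_tests)),
                    "n": int(ok.sum()),
                }
            )
    return pd.DataFrame.from_records(records)
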