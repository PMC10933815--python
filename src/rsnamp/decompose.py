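"""Stage-1 spatial regression and the three per-network amplitude measures.

Given a set of group spatial maps ``G`` (one signed Z-statistic map per
resting-state network) and a single subject's voxel-by-time BOLD matrix
``X``, stage 1 of dual regression solves the per-timepoint least-squares
problem ``X = G D + E`` for the network timeseries ``D``.  Three scalar
summaries per network are derived from it:

* **network amplitude** ``a_k`` -- the standard deviation of ``d_k``;
* **temporal synchrony** ``â_k`` -- the same statistic computed after
  z-scoring every voxel's timeseries, so it reflects only how coherently
  the map's voxels fluctuate, not how large their fluctuations are;
* **BOLD amplitude** ``ȧ_k`` -- a summary of per-voxel timeseries standard
  deviations over the voxels strongly weighted in the map (binary-mask
  mean by default, with two weighted variants).

The product of interest is that network amplitude factorises, across
subjects, into the synchrony and voxel-amplitude components; the helpers
here keep the three estimators strictly consistent (same SD convention,
same regression) so the factorisation is testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "GroupMaps",
    "BoldRun",
    "NetworkTimeseriesSet",
    "NetworkMask",
    "spatial_regress",
    "network_amplitude",
    "temporal_normalize",
    "temporal_synchrony",
    "threshold_mask",
    "z_from_two_sided_p",
    "bold_amplitude",
    "sweep_thresholds",
    "sigma_identity_check",
    "measure_table",
    "DEFAULT_Z_THRESHOLD",
]

#: two-sided normal quantile for P(|Z| > z) = 1e-3, the conventional
#: map-thresholding level for defining a network's strongly-weighted voxels.
DEFAULT_Z_THRESHOLD = 3.29

_MAX_CONDITION = 1e12


@dataclass
class GroupMaps:
    """Signed Z-statistic network weight maps, one column per network."""

    weights: np.ndarray  # (n_voxels, K)
    network_labels: list[str] | None = None
    shape: tuple[int, int, int] | None = None  # optional 3-D box for NIfTI export
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D (n_voxels, K) array")
        n, k = self.weights.shape
        if k >= n:
            raise ValueError(f"need more voxels than networks (N={n}, K={k})")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights contain non-finite values")
        if np.any(np.all(self.weights == 0, axis=0)):
            raise ValueError("group maps contain an all-zero column")
        if self.network_labels is None:
            self.network_labels = [f"net{i + 1}" for i in range(k)]
        elif len(self.network_labels) != k:
            raise ValueError("network_labels length does not match K")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def n_networks(self) -> int:
        return self.weights.shape[1]

    def condition_number(self) -> float:
        """Condition number of G^T G (reported on singularity errors)."""
        return float(np.linalg.cond(self.weights.T @ self.weights))


@dataclass
class BoldRun:
    """One subject's voxel x time BOLD matrix."""

    data: np.ndarray  # (n_voxels, T)
    subject_id: str | int = 0
    shape: tuple[int, int, int] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_voxels, T) array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contain non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class NetworkTimeseriesSet:
    """K network timeseries from one stage-1 regression."""

    series: np.ndarray  # (K, T)
    normalized_input: bool = False
    residual_variance: np.ndarray | None = None  # per-voxel variance of E
    network_labels: list[str] | None = None


@dataclass
class NetworkMask:
    """Binary voxel masks from thresholding |weights| of each map."""

    masks: np.ndarray  # (n_voxels, K) of {0, 1}
    z_threshold: float
    network_labels: list[str] | None = None


def spatial_regress(
    run: BoldRun, maps: GroupMaps, keep_residual_variance: bool = False
) -> NetworkTimeseriesSet:
    """Stage-1 dual regression: D = (G^T G)^-1 G^T X.

    The exact multiple-regression least-squares solution of every timepoint's
    voxel vector on the group maps, solved via a stable factorization.
    """
    g = maps.weights
    x = run.data
    if x.shape[0] != g.shape[0]:
        raise ValueError(
            f"run has {x.shape[0]} voxels but maps have {g.shape[0]}"
        )
    cond = maps.condition_number()
    if not np.isfinite(cond) or cond > _MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"G^T G is singular or ill-conditioned (condition number {cond:.3g})"
        )
    d, _, rank, _ = linalg.lstsq(g, x, lapack_driver="gelsd")
    if rank < g.shape[1]:
        raise np.linalg.LinAlgError(
            f"group maps are rank deficient (rank {rank} < K={g.shape[1]})"
        )
    resid_var = None
    if keep_residual_variance:
        resid = x - g @ d
        resid_var = resid.var(axis=1, ddof=1)
    return NetworkTimeseriesSet(
        series=d,
        normalized_input=False,
        residual_variance=resid_var,
        network_labels=list(maps.network_labels),
    )


def network_amplitude(ts: NetworkTimeseriesSet | np.ndarray) -> np.ndarray:
    """Per-network amplitude a_k = sd(d_k), sample SD (T-1 denominator)."""
    series = ts.series if isinstance(ts, NetworkTimeseriesSet) else np.asarray(ts)
    if series.ndim != 2:
        raise ValueError("expected a (K, T) timeseries matrix")
    return series.std(axis=1, ddof=1)


def temporal_normalize(run: BoldRun) -> BoldRun:
    """Z-score every voxel's timeseries: x̂_i = (x_i - mean) / sd.

    Errors on zero-variance voxels (their z-score is undefined); the offending
    voxel indices are listed rather than silently dropped.
    """
    x = run.data
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    # constant rows: SD indistinguishable from rounding error at the row's scale
    tiny = 1e-12 * np.maximum(np.abs(mu[:, 0]), 1.0)
    bad = np.flatnonzero(sd[:, 0] <= tiny)
    if bad.size:
        shown = ", ".join(map(str, bad[:10]))
        more = "" if bad.size <= 10 else f" (+{bad.size - 10} more)"
        raise ValueError(
            f"cannot temporally normalize: zero-variance voxels [{shown}]{more}"
        )
    return BoldRun(
        data=(x - mu) / sd,
        subject_id=run.subject_id,
        shape=run.shape,
        affine=run.affine,
    )


def temporal_synchrony(run: BoldRun, maps: GroupMaps) -> np.ndarray:
    """Per-network temporal synchrony â_k = sd of stage-1 timeseries of the
    z-scored run.

    Invariant to per-voxel positive affine rescaling of the input: all voxel
    amplitudes are set to one before the regression, so only the temporal
    covariation among the map's voxels (and the map weights) remains.
    """
    d_hat = spatial_regress(temporal_normalize(run), maps)
    d_hat.normalized_input = True
    return network_amplitude(d_hat)


def z_from_two_sided_p(p: float) -> float:
    """The z with P(|Z| > z) = p under the standard normal (e.g. p=1e-3 -> 3.29)."""
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return float(stats.norm.isf(p / 2.0))


def threshold_mask(maps: GroupMaps, z: float = DEFAULT_Z_THRESHOLD) -> NetworkMask:
    """Binary masks m_k(i) = 1 iff |g_k(i)| > z (strict inequality)."""
    if z < 0:
        raise ValueError("threshold must be non-negative")
    masks = (np.abs(maps.weights) > z).astype(int)
    counts = masks.sum(axis=0)
    if np.any(counts < 2):
        bad = [maps.network_labels[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(
            f"threshold {z} leaves <2 voxels for network(s) {bad}; "
            "per-network measures are undefined on such masks"
        )
    return NetworkMask(masks=masks, z_threshold=z,
                       network_labels=list(maps.network_labels))


def bold_amplitude(
    run: BoldRun,
    maps: GroupMaps,
    method: Literal["binary_mean", "weighted_sum", "root_sum_var"] = "binary_mean",
    z: float = DEFAULT_Z_THRESHOLD,
) -> np.ndarray:
    """Per-network BOLD amplitude ȧ_k from the per-voxel timeseries SDs v.

    binary_mean   mean of v over the |g_k| > z mask (the default definition)
    weighted_sum  g_k^T v / N
    root_sum_var  sqrt((g_k ∘ g_k)^T (v ∘ v))

    All variants scale linearly under global rescaling of the data.  The
    weighted variants use the full signed map, so ``weighted_sum`` can be
    negative when a map has strong negative weights.
    """
    v = run.data.std(axis=1, ddof=1)
    g = maps.weights
    if v.shape[0] != g.shape[0]:
        raise ValueError("run and maps have different voxel counts")
    if method == "binary_mean":
        m = threshold_mask(maps, z).masks
        return (m * v[:, None]).sum(axis=0) / m.sum(axis=0)
    if method == "weighted_sum":
        return g.T @ v / g.shape[0]
    if method == "root_sum_var":
        return np.sqrt((g**2).T @ v**2)
    raise ValueError(f"unknown BOLD-amplitude method {method!r}")


def _restricted_synchrony(
    xhat: np.ndarray,
    maps: GroupMaps,
    mask: np.ndarray,
    mode: Literal["multi", "single"],
) -> np.ndarray:
    """Thresholded-voxel stage-1 timeseries, one network at a time.

    For network k the regression is restricted to the voxels in mask_k.  In
    ``multi`` mode all K map columns are kept as regressors on those rows,
    (G_m^T G_m)^-1 G_m^T X̂_m, and row k is taken -- with a zero threshold this
    reproduces the full regression exactly.  ``single`` mode regresses on
    column k alone.
    """
    k_total = maps.n_networks
    out = np.empty((k_total, xhat.shape[1]))
    for k in range(k_total):
        rows = mask[:, k].astype(bool)
        g_m = maps.weights[rows]
        x_m = xhat[rows]
        if mode == "multi":
            gtg = g_m.T @ g_m
            if np.linalg.cond(gtg) > _MAX_CONDITION:
                raise np.linalg.LinAlgError(
                    f"restricted design singular for network "
                    f"{maps.network_labels[k]}"
                )
            d_m = linalg.lstsq(g_m, x_m, lapack_driver="gelsd")[0]
            out[k] = d_m[k]
        else:
            gk = g_m[:, k]
            denom = gk @ gk
            if denom == 0:
                raise np.linalg.LinAlgError(
                    f"restricted design singular for network "
                    f"{maps.network_labels[k]}"
                )
            out[k] = gk @ x_m / denom
    return out


def sweep_thresholds(
    runs: Sequence[BoldRun],
    maps: GroupMaps,
    z_list: Sequence[float],
    mode: Literal["multi", "single"] = "multi",
) -> pd.DataFrame:
    """Map-threshold sweep of the synchrony computation.

    For each threshold z, the synchrony regression is recomputed using only
    voxels with |g_k| > z, and three summaries are reported:

    ``r_timeseries``  mean (over subjects and networks) Pearson r between the
                      full and thresholded stage-1 timeseries of z-scored data;
    ``r_synchrony``   mean over networks of the across-subject r between full
                      and thresholded temporal synchrony;
    ``r_amplitude``   mean over networks of the across-subject r between the
                      full network amplitude and thresholded synchrony.

    Together these localize how much of the synchrony (and of the amplitude's
    synchrony component) is carried by the strongly-weighted voxels alone.
    """
    z_list = list(z_list)
    if sorted(z_list) != z_list:
        raise ValueError("z_list must be sorted ascending")
    n_subj = len(runs)
    k_total = maps.n_networks

    amp_full = np.empty((n_subj, k_total))
    syn_full = np.empty((n_subj, k_total))
    d_hats = []
    for s, run in enumerate(runs):
        amp_full[s] = network_amplitude(spatial_regress(run, maps))
        d_hat = spatial_regress(temporal_normalize(run), maps).series
        d_hats.append(d_hat)
        syn_full[s] = d_hat.std(axis=1, ddof=1)

    records = []
    for z in z_list:
        mask = threshold_mask(maps, z).masks
        syn_thr = np.empty((n_subj, k_total))
        r_ts = np.empty((n_subj, k_total))
        for s, run in enumerate(runs):
            xhat = temporal_normalize(run).data
            d_thr = _restricted_synchrony(xhat, maps, mask, mode)
            syn_thr[s] = d_thr.std(axis=1, ddof=1)
            for k in range(k_total):
                r_ts[s, k] = np.corrcoef(d_hats[s][k], d_thr[k])[0, 1]
        r_syn = [
            np.corrcoef(syn_full[:, k], syn_thr[:, k])[0, 1] for k in range(k_total)
        ]
        r_amp = [
            np.corrcoef(amp_full[:, k], syn_thr[:, k])[0, 1] for k in range(k_total)
        ]
        records.append(
            {
                "z": z,
                "r_timeseries": float(r_ts.mean()),
                "r_synchrony": float(np.mean(r_syn)),
                "r_amplitude": float(np.mean(r_amp)),
            }
        )
    return pd.DataFrame.from_records(records)


def sigma_identity_check(
    run: BoldRun, maps: GroupMaps, rtol: float = 1e-8
) -> dict:
    """Consistency diagnostic: when every voxel has the same SD sigma and a
    zero mean, network amplitude must equal sigma times temporal synchrony.

    Returns a record with the common sigma, the two measure vectors, and the
    maximum relative deviation |a_k - sigma * â_k| / (sigma * â_k).
    """
    sds = run.data.std(axis=1, ddof=1)
    means = run.data.mean(axis=1)
    sigma = float(sds[0])
    if sigma == 0 or not (
        np.allclose(sds, sigma, rtol=1e-9) and np.allclose(means, 0, atol=1e-9 * sigma)
    ):
        raise ValueError(
            "sigma identity requires equal-SD, zero-mean voxel timeseries"
        )
    a = network_amplitude(spatial_regress(run, maps))
    a_hat = temporal_synchrony(run, maps)
    rel = np.max(np.abs(a - sigma * a_hat) / (sigma * a_hat))
    return {
        "sigma": sigma,
        "amplitude": a,
        "synchrony": a_hat,
        "max_relative_deviation": float(rel),
        "holds": bool(rel <= rtol),
    }


def measure_table(
    values: np.ndarray,
    measure: Literal["network_amplitude", "temporal_synchrony", "bold_amplitude"],
    network_labels: Sequence[str] | None = None,
    **metadata,
) -> pd.DataFrame:
    """Wrap an S x K measure matrix as a labelled DataFrame with provenance.

    The measure name and any method metadata (BOLD-amplitude variant,
    threshold, ...) are stored in ``DataFrame.attrs``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected an (S, K) matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("measure values contain non-finite entries")
    if measure != "bold_amplitude" or metadata.get("method") != "weighted_sum":
        if np.any(values < 0):
            raise ValueError(f"{measure} values must be non-negative")
    cols = (
        list(network_labels)
        if network_labels is not None
        else [f"net{i + 1}" for i in range(values.shape[1])]
    )
    df = pd.DataFrame(values, columns=cols)
    df.attrs["measure"] = measure
    df.attrs.update(metadata)
    return df
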