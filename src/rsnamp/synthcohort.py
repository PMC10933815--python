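"""Synthetic fMRI cohort generator with planted ground truth.

Emulates the kind of multi-subject resting-state dataset on which the
amplitude decomposition operates: group network maps with partial overlap
and signed weights over a flat voxel grid, per-subject BOLD runs built from
latent network signals with controllable within-network synchrony and
between-network correlation, per-voxel fluctuation scales, and phenotype /
confound tables with planted linear effects and missingness.

Generative model for a voxel i whose primary network is k, subject s:

    x_i(t) = sigma_{s,k} * ( sqrt(rho_{s,k}) * sign(g_ki) * s_k(t)
                             + sqrt(1 - rho_{s,k}) * eps_i(t)
                             + noise_sd * eta_i(t) )

where s_k are zero-mean unit-SD latent network signals (band-limited
Gaussian noise, mixed through the Cholesky factor of the target
between-network correlation), eps_i is independent band-limited noise per
voxel, eta_i is white noise, rho_{s,k} in (0, 1] is the planted
within-network synchrony and sigma_{s,k} the planted voxel-SD scale.  The
unstructured noise sits inside the sigma factor so that the voxel-SD scale
and the synchrony act on the data exactly independently: rescaling every
sigma by c multiplies all downstream amplitude measures by exactly c and
leaves temporal synchrony untouched.

Network synchrony values are drawn with a shared cluster-level factor over
a planted 2-block partition of the networks (so amplitude covariation is
block structured), while the voxel-SD scales share a single global factor
(so BOLD-amplitude covariation is not block structured).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .decompose import BoldRun, GroupMaps

__all__ = [
    "SimConfig",
    "PhenotypeSpec",
    "ConfoundSpec",
    "GroundTruth",
    "Cohort",
    "make_group_maps",
    "make_subject",
    "make_phenotypes",
    "simulate_cohort",
    "phase_toy",
]

# rng stream tags: one sub-stream per generator stage, all keyed off cfg.seed
_STREAM_MAPS = 0
_STREAM_TRUTH = 1
_STREAM_PHENO = 2
_STREAM_SUBJECT = 10  # + subject index


@dataclass(frozen=True)
class PhenotypeSpec:
    """One phenotype column: linear effects on cluster-mean measures."""

    name: str
    category: str = "other"
    effect_synchrony: float = 0.0  # coefficient on cluster-mean planted rho
    effect_voxel_sd: float = 0.0  # coefficient on cluster-mean planted sigma scale
    missing_rate: float = 0.0
    cluster: int = 0  # which planted cluster's mean the effects act on
    noise_sd: float = 1.0


@dataclass(frozen=True)
class ConfoundSpec:
    """One confound: standard-normal across subjects, with linear leakage
    into planted synchrony and into every phenotype column."""

    name: str
    effect_imaging: float = 0.0
    effect_phenotype: float = 0.0


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults follow the acquisition emulated throughout: T=490 timepoints at
    TR=0.735 s with latent signals low-passed at 0.1 Hz, K networks over a
    flat voxel grid, synchrony (the shared-signal fraction rho) spanning most
    of its range, and moderate unstructured noise.
    """

    n_voxels: int = 400
    n_networks: int = 6
    n_timepoints: int = 490
    n_subjects: int = 200
    overlap_fraction: float = 0.2
    neg_weight_fraction: float = 0.15
    synchrony_range: tuple[float, float] = (0.2, 0.9)
    voxel_sd_range: tuple[float, float] = (0.8, 1.2)
    between_net_corr: float | np.ndarray = 0.3
    noise_sd: float = 0.5
    cluster_coupling: float = 0.7  # weight of the shared cluster factor in rho
    # exponent gamma coupling each network's between-network correlation to its
    # synchrony (latent corr_jk = rho_j^(g/2) rho_k^(g/2) R_jk); 0 decouples them
    fc_synchrony_coupling: float = 1.0
    tr: float = 0.735  # seconds
    lowpass_hz: float = 0.1
    phenotype_spec: tuple[PhenotypeSpec, ...] = ()
    confound_spec: tuple[ConfoundSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_voxels, self.n_networks, self.n_timepoints, self.n_subjects) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_networks >= self.n_voxels:
            raise ValueError("need n_networks < n_voxels")
        if self.n_networks >= self.n_timepoints:
            raise ValueError("need n_networks < n_timepoints")
        for name in ("synchrony_range", "voxel_sd_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered low <= high")
        lo, hi = self.synchrony_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("synchrony_range must lie in (0, 1]")
        if self.voxel_sd_range[0] < 0:
            raise ValueError("voxel_sd_range must be non-negative")
        for name in ("overlap_fraction", "neg_weight_fraction", "cluster_coupling"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fc_synchrony_coupling < 0:
            raise ValueError("fc_synchrony_coupling must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for ps in self.phenotype_spec:
            if not 0 <= ps.missing_rate < 1:
                raise ValueError(
                    f"phenotype {ps.name!r}: missing_rate must be in [0, 1); "
                    "an all-missing column carries no information"
                )
        self._between_corr_matrix()  # validate early

    def _between_corr_matrix(self) -> np.ndarray:
        k = self.n_networks
        r = self.between_net_corr
        if np.isscalar(r):
            mat = np.full((k, k), float(r))
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(r, dtype=float)
            if mat.shape != (k, k):
                raise ValueError("between_net_corr matrix must be K x K")
            if not np.allclose(mat, mat.T):
                raise ValueError("between_net_corr must be symmetric")
        if np.min(np.linalg.eigvalsh(mat)) < -1e-10:
            raise ValueError("between_net_corr must be positive semidefinite")
        return mat

    @property
    def cluster_assignment(self) -> np.ndarray:
        """Planted 2-block partition: first half of the networks vs the rest."""
        k = self.n_networks
        return (np.arange(k) >= (k + 1) // 2).astype(int)


@dataclass
class GroundTruth:
    """Planted parameters behind a simulated cohort."""

    true_synchrony: np.ndarray  # (S, K), rho in (0, 1]
    true_voxel_sd_scale: np.ndarray  # (S, K)
    true_between_net_corr: np.ndarray  # (K, K)
    cluster_assignment: np.ndarray  # (K,) of {0, 1}
    phenotype_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s, k = self.true_synchrony.shape
        if self.true_voxel_sd_scale.shape != (s, k):
            raise ValueError("true_voxel_sd_scale shape mismatch")
        if self.true_between_net_corr.shape != (k, k):
            raise ValueError("true_between_net_corr shape mismatch")
        if self.cluster_assignment.shape != (k,):
            raise ValueError("cluster_assignment shape mismatch")
        if np.any(self.true_synchrony <= 0) or np.any(self.true_synchrony > 1):
            raise ValueError("true synchrony must lie in (0, 1]")


@dataclass
class Cohort:
    """A fully simulated cohort: inputs for every downstream stage."""

    config: SimConfig
    maps: GroupMaps
    runs: list[BoldRun]
    truth: GroundTruth
    phenotypes: pd.DataFrame | None = None
    confounds: pd.DataFrame | None = None


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def make_group_maps(cfg: SimConfig) -> GroupMaps:
    """Generate signed Z-stat network maps over a flat voxel grid.

    Each network's support is a contiguous block of voxels; a fraction of
    each support is shared with the next network (partial overlap), and a
    fraction of within-network voxels carries negative weights
    (anticorrelated sub-regions).  Suprathreshold magnitudes are drawn
    uniform on [4, 8] so every network has |Z| > 3.29 voxels by
    construction; the background is weak Gaussian noise.
    """
    rng = _rng(cfg, _STREAM_MAPS)
    n, k = cfg.n_voxels, cfg.n_networks
    block = n // k
    if block < 2:
        raise ValueError(
            f"infeasible geometry: {k} networks of >=2 voxels each "
            f"do not fit {n} voxels"
        )
    weights = rng.normal(0.0, 0.1, size=(n, k))  # near-zero background
    supports = []
    for j in range(k):
        core = np.arange(j * block, (j + 1) * block)
        support = core
        if k > 1 and cfg.overlap_fraction > 0:
            n_shared = int(np.ceil(cfg.overlap_fraction * block))
            nxt = (j + 1) % k
            shared = np.arange(nxt * block, nxt * block + n_shared)
            support = np.concatenate([core, shared])
        supports.append(support)
    for j, support in enumerate(supports):
        mag = rng.uniform(4.0, 8.0, size=support.size)
        sign = np.ones(support.size)
        n_neg = int(round(cfg.neg_weight_fraction * support.size))
        if n_neg:
            neg_idx = rng.choice(support.size, size=n_neg, replace=False)
            sign[neg_idx] = -1.0
        weights[support, j] = sign * mag
    return GroupMaps(weights=weights)


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple[int, int], cfg: SimConfig
) -> np.ndarray:
    """White Gaussian rows low-pass filtered and re-standardized (unit sample SD)."""
    raw = rng.standard_normal(shape)
    nyquist = 0.5 / cfg.tr
    wn = cfg.lowpass_hz / nyquist
    if 0 < wn < 1:
        b, a = signal.butter(4, wn, btype="low")
        raw = signal.filtfilt(b, a, raw, axis=-1)
    raw -= raw.mean(axis=-1, keepdims=True)
    raw /= raw.std(axis=-1, ddof=1, keepdims=True)
    return raw


def _primary_network(cfg: SimConfig) -> np.ndarray:
    """Primary network index per voxel (-1 for background voxels)."""
    n, k = cfg.n_voxels, cfg.n_networks
    block = n // k
    owner = np.full(n, -1, dtype=int)
    owner[: block * k] = np.repeat(np.arange(k), block)
    return owner


def _draw_truth(cfg: SimConfig) -> GroundTruth:
    """Planted per-subject synchrony and voxel-SD scales.

    rho mixes a per-cluster shared factor with network-specific variation
    (block-structured covariation); sigma mixes one global factor with
    network-specific variation (covariation without block structure).
    """
    rng = _rng(cfg, _STREAM_TRUTH)
    s, k = cfg.n_subjects, cfg.n_networks
    clusters = cfg.cluster_assignment
    alpha = cfg.cluster_coupling

    lo, hi = cfg.synchrony_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    cluster_factor = rng.uniform(-1.0, 1.0, size=(s, 2))
    net_factor = rng.uniform(-1.0, 1.0, size=(s, k))
    rho = mid + half * (
        alpha * cluster_factor[:, clusters] + (1.0 - alpha) * net_factor
    )
    rho = np.clip(rho, min(lo, 1e-6), 1.0)

    vlo, vhi = cfg.voxel_sd_range
    vmid, vhalf = (vlo + vhi) / 2.0, (vhi - vlo) / 2.0
    global_factor = rng.uniform(-1.0, 1.0, size=(s, 1))
    vnet_factor = rng.uniform(-1.0, 1.0, size=(s, k))
    sigma = vmid + vhalf * (alpha * global_factor + (1.0 - alpha) * vnet_factor)

    return GroundTruth(
        true_synchrony=rho,
        true_voxel_sd_scale=sigma,
        true_between_net_corr=cfg._between_corr_matrix(),
        cluster_assignment=clusters,
    )


def _truth_slice(cfg: SimConfig, subject_index: int) -> tuple[np.ndarray, np.ndarray]:
    truth = _draw_truth(cfg)
    return (
        truth.true_synchrony[subject_index],
        truth.true_voxel_sd_scale[subject_index],
    )


def make_subject(
    cfg: SimConfig,
    maps: GroupMaps,
    subject_index: int,
    rho: np.ndarray | None = None,
    sigma_scale: np.ndarray | None = None,
) -> tuple[BoldRun, dict]:
    """Simulate one subject's BOLD run.

    ``rho`` and ``sigma_scale`` (length-K vectors) default to the cohort-level
    planted draw for this subject, so a standalone call reproduces exactly
    the run generated inside :func:`simulate_cohort`.  Returns the run and
    the per-subject ground-truth slice.
    """
    if maps.n_voxels != cfg.n_voxels or maps.n_networks != cfg.n_networks:
        raise ValueError("maps are inconsistent with the config")
    if cfg.noise_sd == 0 and cfg.synchrony_range[1] == 0:
        raise ValueError(
            "degenerate config: zero noise and zero synchrony leave "
            "zero-variance voxels, whose temporal normalization is undefined"
        )
    if rho is None or sigma_scale is None:
        drho, dsigma = _truth_slice(cfg, subject_index)
        rho = drho if rho is None else np.asarray(rho, dtype=float)
        sigma_scale = dsigma if sigma_scale is None else np.asarray(sigma_scale, float)
    rho = np.asarray(rho, dtype=float)
    sigma_scale = np.asarray(sigma_scale, dtype=float)

    rng = _rng(cfg, _STREAM_SUBJECT + subject_index)
    n, k, t = cfg.n_voxels, cfg.n_networks, cfg.n_timepoints

    latent = _bandlimited_noise(rng, (k, t), cfg)
    extra = _bandlimited_noise(rng, (k, t), cfg)
    chol = np.linalg.cholesky(
        cfg._between_corr_matrix() + 1e-12 * np.eye(k)
    )
    # synchrony-coupled connectivity: network k joins the shared factors with
    # weight w_k = rho_k^(g/2), keeping unit variance; the latent correlation
    # between j and k becomes w_j w_k R_jk, so more-synchronous networks show
    # stronger between-network coupling (g=0 decouples FC from synchrony)
    w = rho ** (cfg.fc_synchrony_coupling / 2.0)
    s_net = w[:, None] * (chol @ latent) + np.sqrt(1.0 - w**2)[:, None] * extra
    # exact unit sample SD per row: realized-SD fluctuations of the shared
    # signals would otherwise leak into every voxel of a network at once,
    # correlating amplitude and BOLD amplitude spuriously at finite T
    # (row rescaling leaves all correlation structure untouched)
    s_net = s_net - s_net.mean(axis=1, keepdims=True)
    s_net = s_net / s_net.std(axis=1, ddof=1, keepdims=True)

    eps = _bandlimited_noise(rng, (n, t), cfg)
    eta = rng.standard_normal((n, t))
    # background voxels: one voxel-SD scale for the subject, no network signal
    sigma_bg = rng.uniform(*cfg.voxel_sd_range)

    owner = _primary_network(cfg)
    x = np.empty((n, t))
    for i in range(n):
        j = owner[i]
        if j < 0:
            x[i] = sigma_bg * (eps[i] + cfg.noise_sd * eta[i])
            continue
        sgn = np.sign(maps.weights[i, j]) or 1.0
        x[i] = sigma_scale[j] * (
            np.sqrt(rho[j]) * sgn * s_net[j]
            + np.sqrt(1.0 - rho[j]) * eps[i]
            + cfg.noise_sd * eta[i]
        )
    if np.any(x.std(axis=1) == 0):
        raise ValueError("degenerate config produced a zero-variance voxel")
    run = BoldRun(data=x, subject_id=subject_index)
    return run, {"rho": rho, "sigma_scale": sigma_scale}


def make_phenotypes(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype and confound tables with planted linear effects.

    Each phenotype column is a linear combination of the z-scored
    cluster-mean planted synchrony and voxel-SD scale, plus confound
    leakage and unit-variance Gaussian noise; entries are then removed
    completely at random at the column's missing rate.  The confound matrix
    is standard normal (full column rank with probability one).
    """
    s = truth.true_synchrony.shape[0]
    rng = _rng(cfg, _STREAM_PHENO)

    conf_names = [c.name for c in cfg.confound_spec]
    conf = rng.standard_normal((s, len(cfg.confound_spec)))
    confounds = pd.DataFrame(conf, columns=conf_names)

    clusters = truth.cluster_assignment
    cols = {}
    categories = {}
    effects = {}
    for ps in cfg.phenotype_spec:
        members = clusters == ps.cluster
        if not members.any():
            raise ValueError(f"phenotype {ps.name!r} targets an empty cluster")
        syn = truth.true_synchrony[:, members].mean(axis=1)
        sd = truth.true_voxel_sd_scale[:, members].mean(axis=1)
        col = (
            ps.effect_synchrony * _zscore(syn)
            + ps.effect_voxel_sd * _zscore(sd)
            + ps.noise_sd * rng.standard_normal(s)
        )
        for q, cs in enumerate(cfg.confound_spec):
            col = col + cs.effect_phenotype * conf[:, q]
        if ps.missing_rate > 0:
            miss = rng.random(s) < ps.missing_rate
            col = np.where(miss, np.nan, col)
        cols[ps.name] = col
        categories[ps.name] = ps.category
        effects[ps.name] = {
            "effect_synchrony": ps.effect_synchrony,
            "effect_voxel_sd": ps.effect_voxel_sd,
            "cluster": ps.cluster,
        }
    phenotypes = pd.DataFrame(cols)
    phenotypes.attrs["categories"] = categories
    truth.phenotype_effects = effects
    return phenotypes, confounds


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate maps, all subject runs, ground truth, phenotypes, confounds.

    Confound leakage into imaging (``effect_imaging``) perturbs the planted
    synchrony before the runs are generated, then everything downstream sees
    only the data.
    """
    maps = make_group_maps(cfg)
    truth = _draw_truth(cfg)
    if cfg.confound_spec:
        rng = _rng(cfg, _STREAM_PHENO)
        conf = rng.standard_normal((cfg.n_subjects, len(cfg.confound_spec)))
        lo, hi = cfg.synchrony_range
        half = (hi - lo) / 2.0
        for q, cs in enumerate(cfg.confound_spec):
            truth.true_synchrony = np.clip(
                truth.true_synchrony + cs.effect_imaging * half * conf[:, [q]],
                1e-6,
                1.0,
            )
    runs = []
    for i in range(cfg.n_subjects):
        run, _ = make_subject(
            cfg,
            maps,
            i,
            rho=truth.true_synchrony[i],
            sigma_scale=truth.true_voxel_sd_scale[i],
        )
        runs.append(run)
    phenotypes = confounds = None
    if cfg.phenotype_spec or cfg.confound_spec:
        phenotypes, confounds = make_phenotypes(cfg, truth)
    return Cohort(
        config=cfg,
        maps=maps,
        runs=runs,
        truth=truth,
        phenotypes=phenotypes,
        confounds=confounds,
    )


def phase_toy(
    theta: float, n_timepoints: int = 1000, n_periods: int = 10
) -> tuple[BoldRun, GroupMaps]:
    """Two-voxel sinusoidal toy: x1 = sin(t), x2 = sin(t + theta).

    With equal positive unit weights the stage-1 timeseries is
    (sin t + sin(t + theta))/2 = cos(theta/2) sin(t + theta/2), so the
    network amplitude is proportional to |cos(theta/2)| over whole periods:
    it decays as the two voxels dephase and vanishes in antiphase.
    """
    t = np.linspace(0.0, 2.0 * np.pi * n_periods, n_timepoints, endpoint=False)
    data = np.vstack([np.sin(t), np.sin(t + theta)])
    maps = GroupMaps(weights=np.ones((2, 1)))
    return BoldRun(data=data, subject_id=f"phase_{theta:.3f}"), maps


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd
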