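"""Association statistics: deconfounding, imputation, mass correlation,
dependent-correlation comparison, measure-triplet correlations and the
age/sex regression models.

This layer relates the imaging measures (network amplitude, temporal
synchrony, BOLD amplitude, or their cluster means) to phenotype tables in
the presence of nuisance structure:

* regression-based deconfounding of both sides before correlation;
* soft-shrinkage SVD imputation of missing phenotype entries (used only
  for the regression models; correlations use pairwise-complete data);
* mass univariate Pearson correlation with a Bonferroni threshold and a
  more stringent fixed cut (P = 1e-20, roughly |r| > 0.05 at n ~ 38k);
* a two-sided test for equality of two overlapping dependent correlations
  (Dunn & Clark's z with Hittner's backtransformed-average modification);
* full and partial correlations among the three amplitude measures; and
* per-network multiple linear regressions on a small predictor set with
  age, sex, age^2 and age-by-sex interaction terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrComparison",
    "deconfound",
    "impute_missing",
    "pearson_with_p",
    "neg_log10_p",
    "r_at_p",
    "bonferroni_threshold",
    "mass_correlate",
    "compare_dependent_correlations",
    "triplet_correlations",
    "fit_regression",
    "regression_panel",
    "select_variables",
]

STRINGENT_P = 1e-20

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# deconfounding and imputation


def _check_full_rank(conf: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(conf)
    if rank < conf.shape[1]:
        # name the columns implicated via the R factor's near-zero pivots
        r = np.linalg.qr(conf, mode="r")
        dep = [names[j] for j in range(conf.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(
            f"confound matrix is rank deficient (rank {rank} < {conf.shape[1]}); "
            f"collinear columns include {dep or 'unidentified'}"
        )


def deconfound(y: np.ndarray | pd.DataFrame, conf: np.ndarray | pd.DataFrame):
    """Residualize each column of ``y`` on the confounds plus an intercept.

    Missing entries in ``y`` are handled per column: the regression uses the
    complete rows only and NaNs are preserved in the output.  Confounds may
    not contain missing values.  Residual columns are orthogonal to every
    confound column (and demeaned) on their complete rows.
    """
    is_frame = isinstance(y, pd.DataFrame)
    values = y.to_numpy(dtype=float) if is_frame else np.asarray(y, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    conf_names = (
        list(conf.columns) if isinstance(conf, pd.DataFrame)
        else [f"conf{j}" for j in range(np.atleast_2d(np.asarray(conf)).shape[-1])]
    )
    conf_arr = (
        conf.to_numpy(dtype=float) if isinstance(conf, pd.DataFrame)
        else np.asarray(conf, dtype=float)
    )
    if conf_arr.ndim == 1:
        conf_arr = conf_arr[:, None]
    if np.isnan(conf_arr).any():
        raise ValueError("confounds contain missing values; prepare them first")
    design = np.column_stack([np.ones(conf_arr.shape[0]), conf_arr])
    _check_full_rank(design, ["intercept"] + conf_names)

    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        ok = np.isfinite(col)
        beta, *_ = np.linalg.lstsq(design[ok], col[ok], rcond=None)
        out[ok, j] = col[ok] - design[ok] @ beta
    if squeeze:
        out = out[:, 0]
    if is_frame:
        res = pd.DataFrame(out, index=y.index, columns=y.columns)
        res.attrs.update(y.attrs)
        return res
    return out


def impute_missing(
    pt: pd.DataFrame,
    shrinkage: float = 0.1,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Iterative soft-shrinkage SVD completion of missing phenotype entries.

    Columns are standardized internally (observed mean/SD), missing cells are
    mean-filled, and the matrix is repeatedly replaced by its SVD
    reconstruction with singular values soft-thresholded at
    ``shrinkage * s1`` (s1 = leading singular value of the initial filled
    matrix) -- only on the missing cells -- until the relative change of the
    imputed values drops below ``tol``.  Observed entries are returned
    bit-exactly unchanged.
    """
    if shrinkage < 0:
        raise ValueError("shrinkage must be non-negative")
    values = pt.to_numpy(dtype=float)
    mask = np.isnan(values)
    if not mask.any():
        return pt.copy()
    if np.any(mask.all(axis=0)):
        bad = [pt.columns[j] for j in np.flatnonzero(mask.all(axis=0))]
        raise ValueError(f"column(s) {bad} are entirely missing")
    mu = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (values - mu) / sd
    z_filled = np.where(mask, 0.0, z)  # mean fill in standardized units
    s1 = np.linalg.svd(z_filled, compute_uv=False)[0]
    lam_target = shrinkage * s1
    # warm-started annealing path: iterating directly at a tiny threshold
    # barely moves the imputed cells per step, so approach the target
    # threshold geometrically from above, converging at each level
    lam_path = [lam_target]
    lam = 0.3 * s1
    while lam > lam_target:
        lam_path.append(lam)
        lam *= 0.5
    current = z_filled
    for lam in sorted(lam_path, reverse=True):
        for _ in range(max_iter):
            u, s, vt = np.linalg.svd(current, full_matrices=False)
            recon = (u * np.maximum(s - lam, 0.0)) @ vt
            new = np.where(mask, recon, z)
            delta = np.linalg.norm(new[mask] - current[mask])
            scale = max(np.linalg.norm(new[mask]), 1e-12)
            current = new
            if delta / scale < tol:
                break
    imputed = values.copy()
    imputed[mask] = (current * sd + mu)[mask]
    out = pd.DataFrame(imputed, index=pt.index, columns=pt.columns)
    out.attrs.update(pt.attrs)
    return out


# ---------------------------------------------------------------------------
# correlation machinery


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t distribution on n-2 df,
    after pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    xo, yo = x[ok], y[ok]
    if xo.std() == 0 or yo.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(np.corrcoef(xo, yo)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def neg_log10_p(r: float, n: int) -> float:
    """-log10 of the two-sided Pearson p, computed in log space so extreme
    associations (p far below float underflow) remain finite and exact."""
    if abs(r) >= 1.0:
        return np.inf
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    logp = stats.t.logsf(t, n - 2) + math.log(2.0)
    return -logp / _LN10


def r_at_p(p: float, n: int) -> float:
    """The |r| whose two-sided Pearson p equals ``p`` at sample size n
    (e.g. ~0.05 at p = 1e-20, n = 37,842)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    t = stats.t.isf(p / 2.0, n - 2)
    return float(t / math.sqrt(n - 2 + t * t))


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Per-test significance level alpha / m."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m_tests


def mass_correlate(
    measures: pd.DataFrame,
    pt: pd.DataFrame,
    stringent_p: float = STRINGENT_P,
    alpha: float = 0.05,
    age: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlate each measure column with every phenotype column.

    Returns a tidy table with, per (measure, variable): pairwise-complete r,
    p, -log10 p, and significance flags at the Bonferroni level
    (alpha / n_variables) and at the stringent fixed threshold.  When ``age``
    is given, age is regressed out of both the measure and the variable
    (complete rows) before correlating.  With exactly two measure columns a
    companion column ``diff_neg_log10_p`` carries the signed difference of
    -log10 p between the first and second measure, the profile used to
    contrast which variables bind more strongly to which summary.  Variables
    with fewer than 4 complete pairs are dropped.
    """
    n_vars = pt.shape[1]
    bonf = bonferroni_threshold(alpha, n_vars)
    records = []
    for m_name in measures.columns:
        m_col = measures[m_name].to_numpy(dtype=float)
        for v_name in pt.columns:
            v_col = pt[v_name].to_numpy(dtype=float)
            ok = np.isfinite(m_col) & np.isfinite(v_col)
            if age is not None:
                ok &= np.isfinite(np.asarray(age, dtype=float))
            if ok.sum() < 4:
                continue
            x, y = m_col[ok], v_col[ok]
            if age is not None:
                a = np.asarray(age, dtype=float)[ok]
                x = deconfound(x, a)
                y = deconfound(y, a)
            if x.std() == 0 or y.std() == 0:
                continue
            r, p = pearson_with_p(x, y)
            nlp = neg_log10_p(r, int(ok.sum()))
            records.append(
                {
                    "measure": m_name,
                    "variable": v_name,
                    "n": int(ok.sum()),
                    "r": r,
                    "p": p,
                    "neg_log10_p": nlp,
                    "sig_bonferroni": p <= bonf,
                    "sig_stringent": p <= stringent_p,
                }
            )
    table = pd.DataFrame.from_records(records)
    if not table.empty and measures.shape[1] == 2:
        m1, m2 = measures.columns
        wide = table.pivot(index="variable", columns="measure", values="neg_log10_p")
        diff = (wide[m1] - wide[m2]).rename("diff_neg_log10_p")
        table = table.merge(diff, left_on="variable", right_index=True, how="left")
    table.attrs["bonferroni_p"] = bonf
    table.attrs["stringent_p"] = stringent_p
    return table


# ---------------------------------------------------------------------------
# dependent-correlation comparison


@dataclass
class CorrComparison:
    """Comparison of two overlapping dependent correlations r(x1,y), r(x2,y)."""

    r1: float
    r2: float
    r12: float
    n: int
    p1: float
    p2: float
    p_diff: float
    statistic: float
    method: str = "hittner2003"


def compare_dependent_correlations(
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    method: Literal["hittner2003", "dunn1969"] = "hittner2003",
) -> CorrComparison:
    """Two-sided test of H0: cor(x1, y) = cor(x2, y) on one sample.

    Because both correlations share y and x1, x2 are themselves correlated,
    the Fisher-z difference must account for cov(r1, r2).  Dunn & Clark's z
    does so through a term c(r12, r..); the default variant replaces the two
    correlations in c by the back-transformed average of their Fisher z's
    (Hittner et al.'s modification, the recommended default for overlapping
    correlations).  ``dunn1969`` uses the plain mean of r1 and r2 instead.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(y)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"need >= 10 complete triples, got {n}")
    r1, p1 = pearson_with_p(x1[ok], y[ok])
    r2, p2 = pearson_with_p(x2[ok], y[ok])
    r12, _ = pearson_with_p(x1[ok], x2[ok])
    for name, r in (("r1", r1), ("r2", r2)):
        if abs(r) == 1.0:
            raise ValueError(f"|{name}| = 1: Fisher z is undefined")
    z1, z2 = math.atanh(r1), math.atanh(r2)
    if method == "hittner2003":
        rm = math.tanh((z1 + z2) / 2.0)
    elif method == "dunn1969":
        rm = (r1 + r2) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    rm2 = rm * rm
    cov = (r12 * (1.0 - 2.0 * rm2) - 0.5 * rm2 * (1.0 - 2.0 * rm2 - r12 * r12)) / (
        (1.0 - rm2) ** 2
    )
    if z1 == z2:
        # identical correlations (e.g. x2 an affine copy of x1): no difference
        z_stat, p_diff = 0.0, 1.0
    elif cov >= 1.0:
        raise ValueError(
            "degenerate comparison: the two measures are perfectly coupled "
            "(covariance term >= 1) yet their correlations differ"
        )
    else:
        z_stat = (z1 - z2) * math.sqrt((n - 3) / (2.0 - 2.0 * cov))
        p_diff = 2.0 * stats.norm.sf(abs(z_stat))
    return CorrComparison(
        r1=r1, r2=r2, r12=r12, n=n, p1=p1, p2=p2,
        p_diff=float(p_diff), statistic=float(z_stat), method=method,
    )


# ---------------------------------------------------------------------------
# triplet correlations


def _partial_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    denom = math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    return (r_xy - r_xz * r_yz) / denom


def triplet_correlations(
    amplitude: pd.DataFrame,
    synchrony: pd.DataFrame,
    bold: pd.DataFrame,
) -> pd.DataFrame:
    """Across-subject full and partial correlations among the three measures,
    one row per network.

    Columns: r(a, â), r(a, ȧ), r(â, ȧ); the partials r(a, â | ȧ) and
    r(a, ȧ | â); and the variance-explained r² of synchrony and BOLD
    amplitude for the network amplitude.
    """
    if not (amplitude.shape == synchrony.shape == bold.shape):
        raise ValueError("the three measure tables must be aligned S x K")
    records = []
    for j, net in enumerate(amplitude.columns):
        a = amplitude.iloc[:, j].to_numpy(dtype=float)
        s = synchrony.iloc[:, j].to_numpy(dtype=float)
        b = bold.iloc[:, j].to_numpy(dtype=float)
        if min(a.std(), s.std(), b.std()) == 0:
            raise ValueError(f"constant measure column for network {net}")
        r_as = float(np.corrcoef(a, s)[0, 1])
        r_ab = float(np.corrcoef(a, b)[0, 1])
        r_sb = float(np.corrcoef(s, b)[0, 1])
        records.append(
            {
                "network": net,
                "r_amp_syn": r_as,
                "r_amp_bold": r_ab,
                "r_syn_bold": r_sb,
                "pr_amp_syn": _partial_r(r_as, r_ab, r_sb),
                "pr_amp_bold": _partial_r(r_ab, r_as, r_sb),
                "r2_syn": r_as**2,
                "r2_bold": r_ab**2,
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# regression models


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"cannot normalize constant column {name!r}")
    return (x - x.mean()) / sd


def fit_regression(
    y: np.ndarray,
    predictors: Mapping[str, np.ndarray],
    age: np.ndarray,
    sex: np.ndarray,
) -> pd.DataFrame:
    """One multiple linear regression of a per-network measure.

    The design is [predictors..., age, sex, age x sex, age^2, age^2 x sex]
    plus an intercept.  The dependent variable, the predictors and age are
    z-scored; sex stays 0/1 coded (female/male), and the interaction and
    quadratic columns are built from the z-scored age and raw sex without
    re-normalization.  Returns a per-coefficient table (coef, se, t, p).
    """
    y = _zscore(np.asarray(y, dtype=float), "y")
    sex = np.asarray(sex, dtype=float)
    if not set(np.unique(sex)) <= {0.0, 1.0}:
        raise ValueError("sex must be coded 0/1")
    age_z = _zscore(np.asarray(age, dtype=float), "age")
    cols: dict[str, np.ndarray] = {}
    for name, x in predictors.items():
        cols[name] = _zscore(np.asarray(x, dtype=float), name)
    cols["age"] = age_z
    cols["sex"] = sex
    cols["age_x_sex"] = age_z * sex
    cols["age2"] = age_z**2
    cols["age2_x_sex"] = age_z**2 * sex
    design = pd.DataFrame(cols)
    design.insert(0, "intercept", 1.0)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"collinear regression design (rank {rank} < {design.shape[1]})"
        )
    fit = sm.OLS(y, design.to_numpy()).fit()
    return pd.DataFrame(
        {
            "predictor": design.columns,
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)


def regression_panel(
    measures: Mapping[str, pd.DataFrame],
    predictors: Mapping[str, np.ndarray],
    age: np.ndarray,
    sex: np.ndarray,
) -> pd.DataFrame:
    """Fit one regression per (measure type, network) and Bonferroni-correct.

    ``measures`` maps a measure name (e.g. "network_amplitude") to its S x K
    table; every network column of every table becomes a dependent variable.
    Corrected p-values use the family of all networks within one
    (measure, predictor) pair, so each predictor's profile across networks is
    corrected for the number of networks.
    """
    frames = []
    for m_name, table in measures.items():
        k = table.shape[1]
        for net in table.columns:
            res = fit_regression(
                table[net].to_numpy(dtype=float), predictors, age, sex
            )
            res.insert(0, "network", net)
            res.insert(0, "measure", m_name)
            res["p_corrected"] = np.minimum(1.0, res["p"] * k)
            frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# variable selection


ILLNESS_CATEGORIES = frozenset(
    {"cancer_illness", "noncancer_illness", "treatment", "operation", "diagnosis"}
)


def select_variables(
    pt: pd.DataFrame,
    categories: Mapping[str, str] | None = None,
    prevalence_min: float = 0.01,
    nonmissing_min: float = 0.5,
) -> list[str]:
    """Screen phenotype columns for association testing.

    Illness-type variables (binary condition indicators) are kept when the
    condition's prevalence exceeds ``prevalence_min`` of the cohort; all
    other variables are kept when more than ``nonmissing_min`` of their
    entries are observed.
    """
    categories = categories or pt.attrs.get("categories", {})
    s = pt.shape[0]
    keep = []
    for name in pt.columns:
        col = pt[name].to_numpy(dtype=float)
        if categories.get(name) in ILLNESS_CATEGORIES:
            n_cases = np.nansum(col > 0)
            if n_cases > prevalence_min * s:
                keep.append(name)
        else:
            if np.isfinite(col).sum() > nonmissing_min * s:
                keep.append(name)
    return keep
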