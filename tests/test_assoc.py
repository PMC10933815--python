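"""Deconfounding, imputation, mass correlation, dependent-correlation
comparison, triplet correlations, and the regression models."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rsnamp.assoc import (
    bonferroni_threshold,
    compare_dependent_correlations,
    deconfound,
    fit_regression,
    impute_missing,
    mass_correlate,
    neg_log10_p,
    pearson_with_p,
    r_at_p,
    regression_panel,
    select_variables,
    triplet_correlations,
)

RNG = np.random.default_rng(12)


class TestDeconfound:
    def test_residual_orthogonal_to_confound(self):
        conf = RNG.standard_normal((500, 1))
        y = 2.0 * conf[:, 0] + RNG.standard_normal(500)
        resid = deconfound(y, conf)
        assert abs(np.corrcoef(resid, conf[:, 0])[0, 1]) < 1e-10
        assert abs(resid.mean()) < 1e-10

    def test_intercept_only_demeans(self):
        y = RNG.standard_normal(100) + 7
        resid = deconfound(y, np.zeros((100, 0)))
        np.testing.assert_allclose(resid, y - y.mean(), atol=1e-10)

    def test_independent_outcome_nearly_unchanged(self):
        s = 2000
        conf = RNG.standard_normal((s, 3))
        y = RNG.standard_normal(s)
        resid = deconfound(y, conf)
        assert np.corrcoef(y, resid)[0, 1] > 0.99

    def test_idempotent(self):
        conf = RNG.standard_normal((300, 4))
        y = RNG.standard_normal((300, 2)) + conf @ RNG.standard_normal((4, 2))
        once = deconfound(y, conf)
        twice = deconfound(once, conf)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_missing_entries_preserved_and_complete_rows_orthogonal(self):
        conf = RNG.standard_normal((400, 2))
        y = conf @ np.array([1.0, -2.0]) + RNG.standard_normal(400)
        y[::7] = np.nan
        resid = deconfound(y, conf)
        assert np.isnan(resid[::7]).all()
        ok = np.isfinite(resid)
        for q in range(2):
            assert abs(np.corrcoef(resid[ok], conf[ok, q])[0, 1]) < 1e-10

    def test_rank_deficient_confounds_named(self):
        conf = pd.DataFrame({"a": RNG.standard_normal(50)})
        conf["b"] = 2 * conf["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            deconfound(RNG.standard_normal(50), conf)


class TestImputeMissing:
    def test_complete_table_returned_unchanged(self):
        pt = pd.DataFrame(RNG.standard_normal((20, 4)))
        out = impute_missing(pt)
        pd.testing.assert_frame_equal(out, pt)

    def test_rank_one_matrix_recovered(self):
        """A noiseless rank-1 matrix with 5% of entries removed is completed
        almost exactly as the shrinkage vanishes."""
        rng = np.random.default_rng(5)
        u = rng.uniform(1, 2, size=40)
        v = rng.uniform(-1, 1, size=8)
        full = np.outer(u, v)
        mask = rng.random(full.shape) < 0.05
        holed = full.copy()
        holed[mask] = np.nan
        out = impute_missing(pd.DataFrame(holed), shrinkage=1e-9,
                             max_iter=2000, tol=1e-12)
        np.testing.assert_allclose(out.to_numpy()[mask], full[mask], atol=1e-6)

    def test_observed_entries_bit_exact(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((30, 5))
        holed = vals.copy()
        holed[rng.random(vals.shape) < 0.2] = np.nan
        out = impute_missing(pd.DataFrame(holed), shrinkage=0.1)
        obs = np.isfinite(holed)
        assert np.array_equal(out.to_numpy()[obs], holed[obs])
        assert np.isfinite(out.to_numpy()).all()

    def test_constant_column_imputes_the_constant(self):
        pt = pd.DataFrame({
            "c": [3.0, 3.0, np.nan, 3.0],
            "x": [1.0, -1.0, 0.5, 2.0],
        })
        out = impute_missing(pt)
        assert out.loc[2, "c"] == pytest.approx(3.0, abs=1e-12)

    def test_all_missing_column_rejected(self):
        pt = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(pt)


class TestCorrelationPrimitives:
    def test_perfect_correlations(self):
        x = RNG.standard_normal(50)
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan, 12.0])
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(1.0)

    def test_stringent_threshold_matches_reported_effect_size(self):
        """At biobank scale (n = 37,842), p = 1e-20 corresponds to |r| ~ 0.05."""
        assert round(r_at_p(1e-20, 37842), 2) == 0.05

    def test_neg_log10_p_survives_underflow(self):
        nlp = neg_log10_p(0.3, 37842)
        assert nlp > 300  # far beyond float underflow of the plain p-value
        # and agrees with scipy in the representable regime
        r, n = 0.05, 1000
        _, p = pearson_with_p(*_corr_pair(r, n))
        # direct check of the formula at moderate strength instead:
        t = 0.2 * math.sqrt((500 - 2) / (1 - 0.04))
        p_direct = 2 * stats.t.sf(t, 498)
        assert neg_log10_p(0.2, 500) == pytest.approx(-math.log10(p_direct),
                                                      rel=1e-10)

    def test_bonferroni_arithmetic(self):
        assert bonferroni_threshold(0.05, 4897) == pytest.approx(1.02e-5,
                                                                 rel=5e-3)
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert -math.log10(10**-7.5 / 21) == pytest.approx(8.82, abs=5e-3)


def _corr_pair(r, n, rng=None):
    rng = rng or np.random.default_rng(abs(int(r * 1000)) + n)
    x = rng.standard_normal(n)
    y = r * x + np.sqrt(1 - r * r) * rng.standard_normal(n)
    return x, y


class TestMassCorrelate:
    def _tables(self, s=2000, seed=0):
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal(s)
        measures = pd.DataFrame({
            "sensory": latent + 0.3 * rng.standard_normal(s),
            "cognitive": rng.standard_normal(s),
        })
        pt = pd.DataFrame({
            "planted": 0.5 * latent + rng.standard_normal(s),
            **{f"null{i}": rng.standard_normal(s) for i in range(30)},
        })
        return measures, pt

    def test_planted_effect_flagged_nulls_calibrated(self):
        measures, pt = self._tables()
        table = mass_correlate(measures, pt)
        planted = table[(table.measure == "sensory")
                        & (table.variable == "planted")].iloc[0]
        assert planted.sig_bonferroni and planted.r > 0.3
        nulls = table[table.variable.str.startswith("null")]
        # uncorrected false-positive rate compatible with alpha = 0.05
        rate = (nulls.p <= 0.05).mean()
        n = len(nulls)
        assert abs(rate - 0.05) < 1.96 * math.sqrt(0.05 * 0.95 / n) + 1e-9

    def test_identical_measures_have_zero_p_difference(self):
        measures, pt = self._tables()
        twin = pd.DataFrame({"a": measures["sensory"],
                             "b": measures["sensory"]})
        table = mass_correlate(twin, pt)
        np.testing.assert_allclose(table["diff_neg_log10_p"], 0.0, atol=1e-10)

    def test_age_option_equals_explicit_residualization(self):
        measures, pt = self._tables(s=500)
        age = np.random.default_rng(9).standard_normal(500)
        with_age = mass_correlate(measures, pt, age=age)
        resid_m = pd.DataFrame(
            {c: deconfound(measures[c].to_numpy(), age)
             for c in measures.columns}
        )
        resid_p = pd.DataFrame(
            {c: deconfound(pt[c].to_numpy(), age) for c in pt.columns}
        )
        explicit = mass_correlate(resid_m, resid_p)
        merged = with_age.merge(explicit, on=["measure", "variable"],
                                suffixes=("_opt", "_exp"))
        np.testing.assert_allclose(merged["r_opt"], merged["r_exp"],
                                   atol=1e-12)

    def test_short_variables_dropped(self):
        measures = pd.DataFrame({"m": RNG.standard_normal(20)})
        pt = pd.DataFrame({"mostly_nan": [1.0, 2.0, 3.0] + [np.nan] * 17})
        table = mass_correlate(measures, pt)
        assert table.empty


class TestCompareDependentCorrelations:
    def _triple(self, r1, r2, r12, n, rng):
        cov = np.array([[1.0, r12, r1], [r12, 1.0, r2], [r1, r2, 1.0]])
        x1, x2, y = rng.multivariate_normal(np.zeros(3), cov, size=n).T
        return x1, x2, y

    def test_identical_measures_give_p_one(self):
        x = RNG.standard_normal(200)
        y = 0.4 * x + RNG.standard_normal(200)
        res = compare_dependent_correlations(x, x, y)
        assert res.r1 == res.r2
        assert res.p_diff == pytest.approx(1.0)

    def test_symmetric_in_the_two_measures(self):
        rng = np.random.default_rng(3)
        x1, x2, y = self._triple(0.5, 0.2, 0.4, 300, rng)
        a = compare_dependent_correlations(x1, x2, y)
        b = compare_dependent_correlations(x2, x1, y)
        assert a.p_diff == pytest.approx(b.p_diff, rel=1e-12)
        assert (a.r1, a.r2) == (b.r2, b.r1)

    def test_degenerate_correlation_rejected(self):
        x = RNG.standard_normal(50)
        x2 = RNG.standard_normal(50)
        with pytest.raises(ValueError, match="Fisher z|degenerate"):
            compare_dependent_correlations(x, x2, y=x)  # r1 = 1

    def test_affine_copy_measures_give_p_one(self):
        x = RNG.standard_normal(80)
        y = 0.5 * x + RNG.standard_normal(80)
        res = compare_dependent_correlations(x, 2 * x + 1, y)
        assert res.p_diff == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 sits inside its binomial 95%
        interval over 2000 replicates (r1 = r2 = 0.3, r12 = 0.6, n = 500)."""
        rng = np.random.default_rng(2023)
        n_reps, n = 2000, 500
        rejections = 0
        for _ in range(n_reps):
            x1, x2, y = self._triple(0.3, 0.3, 0.6, n, rng)
            if compare_dependent_correlations(x1, x2, y).p_diff < 0.05:
                rejections += 1
        rate = rejections / n_reps
        half = 1.96 * math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < half

    def test_strong_alternative_detected_and_matches_permutation_oracle(self):
        """Under r1=0.5 vs r2=0.1 the test rejects overwhelmingly, and its
        decisions agree with a swap-permutation oracle."""
        rng = np.random.default_rng(77)

        def permutation_p(x1, x2, y, n_perm=200):
            z1 = (x1 - x1.mean()) / x1.std(ddof=1)
            z2 = (x2 - x2.mean()) / x2.std(ddof=1)
            obs = abs(np.corrcoef(z1, y)[0, 1] - np.corrcoef(z2, y)[0, 1])
            hits = 0
            for _ in range(n_perm):
                swap = rng.random(len(y)) < 0.5
                p1 = np.where(swap, z2, z1)
                p2 = np.where(swap, z1, z2)
                stat = abs(np.corrcoef(p1, y)[0, 1] - np.corrcoef(p2, y)[0, 1])
                hits += stat >= obs
            return (hits + 1) / (n_perm + 1)

        small_p = 0
        agreements = 0
        n_reps = 40
        for _ in range(n_reps):
            x1, x2, y = self._triple(0.5, 0.1, 0.3, 500, rng)
            res = compare_dependent_correlations(x1, x2, y)
            small_p += res.p_diff < 1e-6
            agreements += (res.p_diff < 0.05) == (
                permutation_p(x1, x2, y) < 0.05
            )
        assert small_p > n_reps / 2
        assert agreements >= 0.9 * n_reps


class TestTripletCorrelations:
    def _measures(self, cfg_kw, seed):
        from rsnamp.synthcohort import SimConfig, simulate_cohort
        from rsnamp.pipeline import compute_measures

        cfg = SimConfig(n_voxels=120, n_networks=3, n_timepoints=250,
                        n_subjects=60, seed=seed, **cfg_kw)
        return compute_measures(simulate_cohort(cfg))

    def test_only_synchrony_varying(self):
        """With voxel SDs pinned, amplitude is pure synchrony: r(a, â) ~ 1
        and r(a, ȧ) ~ 0."""
        m = self._measures({"voxel_sd_range": (1.0, 1.0)}, seed=8)
        trip = triplet_correlations(m["network_amplitude"],
                                    m["temporal_synchrony"],
                                    m["bold_amplitude"])
        assert (trip["r_amp_syn"] > 0.95).all()
        assert (trip["r_amp_bold"].abs() < 0.4).all()

    def test_only_voxel_sd_varying(self):
        m = self._measures(
            {"synchrony_range": (0.6, 0.6), "voxel_sd_range": (0.5, 1.5)},
            seed=9,
        )
        trip = triplet_correlations(m["network_amplitude"],
                                    m["temporal_synchrony"],
                                    m["bold_amplitude"])
        assert (trip["r_amp_bold"] > 0.8).all()

    def test_partials_match_residualization_oracle(self):
        rng = np.random.default_rng(10)
        s = 200
        base = rng.standard_normal(s)
        a = pd.DataFrame({"n1": base + 0.5 * rng.standard_normal(s)})
        b = pd.DataFrame({"n1": base + 0.8 * rng.standard_normal(s)})
        c = pd.DataFrame({"n1": 0.3 * base + rng.standard_normal(s)})
        trip = triplet_correlations(a, b, c).iloc[0]
        x, y, z = (d["n1"].to_numpy() for d in (a, b, c))
        design = np.column_stack([np.ones(s), z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(trip["pr_amp_syn"],
                                   np.corrcoef(rx, ry)[0, 1], atol=1e-10)


class TestRegression:
    def _cohort(self, s=2000, seed=1):
        rng = np.random.default_rng(seed)
        age = rng.uniform(45, 80, s)
        sex = (rng.random(s) < 0.5).astype(float)
        preds = {name: rng.standard_normal(s)
                 for name in ("sbp", "body_fat", "haemoglobin", "sleep")}
        return rng, age, sex, preds

    def test_planted_coefficients_recovered(self):
        rng, age, sex, preds = self._cohort()
        age_z = (age - age.mean()) / age.std(ddof=1)
        beta = {"sbp": -0.2, "body_fat": 0.1, "haemoglobin": 0.15,
                "sleep": -0.05}
        y = sum(b * preds[k] for k, b in beta.items())
        y = y - 0.3 * age_z + 0.2 * sex + 0.5 * rng.standard_normal(len(age))
        res = fit_regression(y, preds, age, sex).set_index("predictor")
        sd_y = np.std(y, ddof=1)
        for name, b in beta.items():
            row = res.loc[name]
            assert abs(row.coef - b / sd_y) < 2 * row.se

    def test_null_outcome_calibrated(self):
        """With a pure-noise outcome, each predictor's p-value rejects at
        ~alpha across replicates."""
        rng, age, sex, preds = self._cohort(s=300, seed=2)
        n_reps = 500
        hits = 0
        n_preds = 0
        for _ in range(n_reps):
            y = rng.standard_normal(300)
            res = fit_regression(y, preds, age, sex)
            body = res[res.predictor != "intercept"]
            hits += (body.p <= 0.05).sum()
            n_preds += len(body)
        rate = hits / n_preds
        half = 1.96 * math.sqrt(0.05 * 0.95 / n_preds)
        assert abs(rate - 0.05) < half + 0.005

    def test_sex_coding_flip_negates_sex_terms(self):
        rng, age, sex, preds = self._cohort(s=400, seed=3)
        y = rng.standard_normal(400) + 0.3 * sex
        a = fit_regression(y, preds, age, sex).set_index("predictor")
        b = fit_regression(y, preds, age, 1 - sex).set_index("predictor")
        for term in ("sex", "age_x_sex", "age2_x_sex"):
            assert a.loc[term].coef == pytest.approx(-b.loc[term].coef,
                                                     abs=1e-8)

    def test_units_of_raw_predictors_irrelevant(self):
        rng, age, sex, preds = self._cohort(s=300, seed=4)
        y = rng.standard_normal(300) + 0.2 * preds["sbp"]
        a = fit_regression(y, preds, age, sex)
        scaled = {k: (v * 13.7 + 5 if k == "sbp" else v)
                  for k, v in preds.items()}
        b = fit_regression(y, scaled, age, sex)
        np.testing.assert_allclose(a["t"], b["t"], atol=1e-10)

    def test_panel_bonferroni_family_is_per_measure_predictor(self):
        rng, age, sex, preds = self._cohort(s=120, seed=5)
        tables = {
            "amp": pd.DataFrame(rng.standard_normal((120, 3)),
                                columns=["n1", "n2", "n3"])
        }
        panel = regression_panel(tables, preds, age, sex)
        assert np.all(panel.p_corrected >= panel.p - 1e-15)
        expected = np.minimum(1.0, panel.p * 3)
        np.testing.assert_allclose(panel.p_corrected, expected, atol=1e-12)

    def test_collinear_design_rejected(self):
        rng, age, sex, preds = self._cohort(s=100, seed=6)
        preds["dup"] = preds["sbp"].copy()
        with pytest.raises(ValueError, match="collinear"):
            fit_regression(rng.standard_normal(100), preds, age, sex)


class TestSelectVariables:
    def test_prevalence_and_missingness_rules(self):
        s = 200
        pt = pd.DataFrame({
            "rare_illness": np.r_[np.ones(1), np.zeros(s - 1)],
            "common_illness": np.r_[np.ones(10), np.zeros(s - 10)],
            "gappy": np.r_[np.full(150, np.nan), np.ones(50)],
            "dense": np.ones(s) + np.arange(s),
        })
        cats = {"rare_illness": "diagnosis", "common_illness": "diagnosis"}
        keep = select_variables(pt, cats)
        assert "common_illness" in keep and "dense" in keep
        assert "rare_illness" not in keep and "gappy" not in keep
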