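"""Statistical layer: adjusted comparison, FDR, partial correlation, drivers."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import bruteforce as bf
from wmnet import (adjusted_group_compare, compare_all, correlate_clinical,
                   fdr_bh, ks_normality, partial_correlation)


class TestKsNormality:
    def test_calibrated_under_normal_null(self):
        rng = np.random.default_rng(1)
        passes = sum(ks_normality(rng.normal(size=200))[1] > 0.05
                     for _ in range(50))
        assert passes >= 45

    def test_power_against_uniform(self):
        rng = np.random.default_rng(2)
        rejections = sum(ks_normality(rng.random(200))[1] < 0.05
                         for _ in range(50))
        assert rejections >= 45

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality(np.full(20, 3.0))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            ks_normality(np.array([1.0, 2.0, 3.0]))


class TestAdjustedGroupCompare:
    def test_reduces_to_pooled_t_with_constant_covariates(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        g = np.repeat([0, 1], 15)
        t, p, means = adjusted_group_compare(y, g, np.full(30, 40.0),
                                             np.zeros(30))
        t_ref, p_ref = sps.ttest_ind(y[g == 1], y[g == 0])
        assert t == pytest.approx(float(t_ref), abs=1e-10)
        assert p == pytest.approx(float(p_ref), abs=1e-10)
        assert means["group0"] == pytest.approx(y[g == 0].mean())
        assert means["group1"] == pytest.approx(y[g == 1].mean())

    def test_perfect_separation(self):
        g = np.repeat([0.0, 1.0], 10)
        rng = np.random.default_rng(4)
        t, p, _ = adjusted_group_compare(g.copy(), g, rng.normal(30, 5, 20),
                                         (rng.random(20) > 0.5).astype(float))
        assert p < 1e-12 and t > 0

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 40
        g = rng.integers(0, 2, n).astype(float)
        age = rng.normal(30, 8, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.5 * g + 0.02 * age - 0.1 * sex + rng.normal(size=n)
        x = sm.add_constant(np.column_stack([g, age, sex]))
        fit = sm.OLS(y, x).fit()
        t, p, _ = adjusted_group_compare(y, g, age, sex)
        assert t == pytest.approx(fit.tvalues[1], abs=1e-9)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-9)
        assert fit.df_resid == n - 4

    def test_type_i_error_calibrated(self):
        """Null rejection rate at alpha=.05 within binomial error, 1000 sims."""
        rng = np.random.default_rng(6)
        n, rejections = 47, 0
        g = np.repeat([1.0, 0.0], [18, 29])
        n_sim = 1000
        for _ in range(n_sim):
            age = rng.normal(29, 7, n)
            sex = (rng.random(n) > 0.5).astype(float)
            y = rng.normal(size=n) + 0.05 * age
            _, p, _ = adjusted_group_compare(y, g, age, sex)
            rejections += p < 0.05
        rate = rejections / n_sim
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_confounded_design_rejected(self):
        y = np.arange(10.0)
        g = np.repeat([0.0, 1.0], 5)
        with pytest.raises(ValueError, match="rank"):
            adjusted_group_compare(y, g, age=g * 2.0 + 1.0, gender=g)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="both groups"):
            adjusted_group_compare(np.arange(6.0), np.zeros(6),
                                   np.arange(6.0), np.zeros(6))


class TestFdrBh:
    def test_hand_computed_step_up(self):
        q, reject = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert reject.all()

    def test_single_p_unchanged(self):
        q, _ = fdr_bh([0.031])
        assert q[0] == pytest.approx(0.031)

    def test_all_ones_no_rejections(self):
        q, reject = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any() and np.allclose(q, 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_definition_and_preserves_order(self, pvals):
        """Adjusted p equals the step-up definition and is order-preserving."""
        q, _ = fdr_bh(pvals)
        assert np.allclose(q, bf.step_up_fdr(pvals), atol=1e-12)
        assert (q <= 1.0).all() and (q >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-15).all()


class TestPartialCorrelation:
    def test_constant_covariate_reduces_to_pearson(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 50))
        r, df, p = partial_correlation(x, y, np.ones((50, 1)))
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(float(r_ref), abs=1e-10)
        assert df == 50 - 3

    def test_identical_variables_give_unity(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        r, _, p = partial_correlation(x, x, z)
        assert r == pytest.approx(1.0)
        assert p < 1e-100

    def test_first_order_closed_form_at_large_n(self):
        """r_xy.z -> (r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2))."""
        rng = np.random.default_rng(10)
        n = 100_000
        cov = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.4], [0.5, 0.4, 1.0]])
        x, y, z = rng.multivariate_normal(np.zeros(3), cov, size=n).T
        r, df, _ = partial_correlation(x, y, z)
        want = (0.6 - 0.5 * 0.4) / np.sqrt((1 - 0.25) * (1 - 0.16))
        assert want == pytest.approx(0.504, abs=5e-4)
        assert r == pytest.approx(want, abs=0.01)
        assert df == n - 3

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        n = 60
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("xyzw"))
        df["y"] += 0.5 * df["x"] + 0.3 * df["z"]
        out = pingouin.partial_corr(df, x="x", y="y", covar=["z", "w"])
        r, dof, p = partial_correlation(df["x"], df["y"], df[["z", "w"]])
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-9)

    @given(st.floats(min_value=0.1, max_value=50),
           st.floats(min_value=-20, max_value=20),
           st.floats(min_value=0.1, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, scale, shift, cov_scale):
        rng = np.random.default_rng(12)
        x, y, z = rng.normal(size=(3, 40))
        r1, _, p1 = partial_correlation(x, y, z)
        r2, _, p2 = partial_correlation(scale * x + shift, y,
                                        cov_scale * z - shift)
        assert r2 == pytest.approx(r1, abs=1e-8)
        assert p2 == pytest.approx(p1, abs=1e-8)

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            partial_correlation(np.arange(4.0), np.arange(4.0) ** 2,
                                np.ones((4, 3)))

    def test_zero_residual_variance_rejected(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="residual variance"):
            partial_correlation(2 * z + 1, np.random.default_rng(0).normal(size=10), z)


def _cohort_tables(seed, **param_overrides):
    from wmnet import CohortParams, load_aal90, simulate_networks
    from wmnet.cohort import subjects_to_frame
    from wmnet.io import RunConfig
    from wmnet.pipeline import subject_metric_tables

    params = CohortParams().with_(**param_overrides)
    recs, nets, _ = simulate_networks(params, seed=seed)
    gt, nt = subject_metric_tables(nets, RunConfig(compute_sigma=False))
    return subjects_to_frame(recs), gt, nt, load_aal90()


class TestCompareAll:
    def test_planted_effects_recovered(self):
        """Patients show lower Eg / higher Lp; affected regions detected."""
        subs, gt, nt, atlas = _cohort_tables(seed=3)
        res = pd.DataFrame([r.__dict__ for r in compare_all(gt, nt, subs, atlas)])
        glob = res[(res.region == "GLOBAL") & (res.network_kind == "FA_wei")]
        eg = glob[glob.target == "Eg"].iloc[0]
        lp = glob[glob.target == "Lp"].iloc[0]
        assert eg.significant and eg.adjusted_mean_patient < eg.adjusted_mean_control
        assert lp.significant and lp.adjusted_mean_patient > lp.adjusted_mean_control
        nodal_sig = res[(res.target == "Enodal") & (res.network_kind == "FA_wei")
                        & res.significant]
        from wmnet import CohortParams
        affected = {atlas.abbreviations[i - 1]
                    for i in CohortParams().affected_regions}
        assert len(affected & set(nodal_sig.region)) > len(affected) / 2

    def test_determinism(self):
        subs, gt, nt, atlas = _cohort_tables(seed=5)
        a = pd.DataFrame([r.__dict__ for r in compare_all(gt, nt, subs, atlas)])
        b = pd.DataFrame([r.__dict__ for r in compare_all(gt, nt, subs, atlas)])
        assert a.equals(b)

    def test_family_structure_and_q_vs_p(self):
        subs, gt, nt, atlas = _cohort_tables(seed=5)
        res = compare_all(gt, nt, subs, atlas)
        for r in res:
            assert r.q >= r.p - 1e-15
            assert r.significant == (r.q <= 0.05)
        families = {r.family_id for r in res}
        assert families == {"global:FA_wei", "global:FA_bin",
                            "nodal:FA_wei", "nodal:FA_bin"}
        assert sum(r.family_id == "nodal:FA_wei" for r in res) == 90


class TestCorrelateClinical:
    def test_duration_coupling_sign_recovered(self):
        subs, gt, nt, atlas = _cohort_tables(seed=3)
        res = pd.DataFrame([r.__dict__
                            for r in correlate_clinical(nt, subs, atlas)])
        from wmnet import CohortParams
        affected = [atlas.abbreviations[i - 1]
                    for i in CohortParams().affected_regions]
        dur = res[(res.clinical_variable == "duration")
                  & res.region.isin(affected)]
        assert (dur.r < 0).mean() > 0.8
        assert dur.r.median() < -0.3

    def test_duration_analysis_controls_onset(self):
        subs, gt, nt, atlas = _cohort_tables(seed=5)
        res = correlate_clinical(nt, subs, atlas)
        for r in res:
            if r.clinical_variable == "duration":
                assert r.covariates == ("age", "gender", "onset")
                assert r.df == 18 - 2 - 3
            else:
                assert r.covariates == ("age", "gender")
                assert r.df == 18 - 2 - 2

    def test_insufficient_patients_rejected(self):
        from wmnet.cohort import GroupParams

        subs, gt, nt, atlas = _cohort_tables(
            seed=5, patients=GroupParams(4, 2, 30.4, 8.16, 90.0, 11.57,
                                         95.06, 10.90))
        with pytest.raises(ValueError, match="degrees of freedom"):
            correlate_clinical(nt, subs, atlas)
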