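"""GLM, permutation inference, z-scores and effect sizes against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi

from shapemorph import (
    DesignError,
    ShapeGLM,
    build_design,
    cohens_d,
    cohens_d_from_samples,
    fit_vertex_glm,
    permutation_fwer,
    volume_group_comparison,
    volume_zscore,
)
from shapemorph.mesh import MarkerField
from shapemorph.calibration import single_structure_config
from shapemorph.synthetic import simulate_cohort


class TestBuildDesign:
    def test_full_design_shape_and_intercept(self):
        rng = np.random.default_rng(0)
        n = 198
        cohort = pd.DataFrame(
            {
                "group": [1] * 92 + [0] * 106,
                "age": rng.normal(23, 5, n),
                "sex": rng.integers(0, 2, n),
                "icv_mm3": rng.normal(1.4e6, 1e5, n),
            }
        )
        X, names = build_design(cohort, ("age", "sex", "icv"))
        assert X.shape == (198, 5)
        np.testing.assert_array_equal(X[:, 0], 1.0)
        assert names == ["intercept", "group", "age", "sex", "icv"]
        # covariates mean-centred, group left binary
        np.testing.assert_allclose(X[:, 2:].mean(axis=0), 0.0, atol=1e-9)
        assert set(np.unique(X[:, 1])) == {0.0, 1.0}

    def test_empty_covariates_two_columns(self, small_cohort_table):
        X, names = build_design(small_cohort_table, ())
        assert X.shape == (12, 2) and names == ["intercept", "group"]

    def test_duplicated_covariate_raises_naming_column(self, small_cohort_table):
        with pytest.raises(DesignError, match="age"):
            build_design(small_cohort_table, ("age", "age"))


class TestVertexGLM:
    def test_two_group_identity(self):
        """With no covariates, beta1 is the patient-minus-control mean."""
        y = np.array([[1.0, 2.0, 3.0, 4.0, 10.0, 12.0, 14.0, 16.0]])
        cohort = pd.DataFrame({"group": [0] * 4 + [1] * 4})
        X, _ = build_design(cohort, ())
        fit = fit_vertex_glm(y, X)
        assert fit.beta[1, 0] == pytest.approx(13.0 - 2.5, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        n, n_vert = 12, 9
        cohort = pd.DataFrame(
            {
                "group": rng.permutation([1] * 6 + [0] * 6),
                "age": rng.normal(23, 5, n),
                "edu": rng.normal(12, 3, n),
            }
        )
        X, _ = build_design(cohort, ("age", "edu"))
        Y = rng.standard_normal((n_vert, n))
        fit = fit_vertex_glm(Y, X)
        for k in range(n_vert):
            beta_or = np.linalg.solve(X.T @ X, X.T @ Y[k])
            np.testing.assert_allclose(fit.beta[:, k], beta_or, rtol=1e-10)

    def test_matches_statsmodels_t(self):
        rng = np.random.default_rng(8)
        n = 20
        cohort = pd.DataFrame(
            {
                "group": rng.permutation([1] * 10 + [0] * 10),
                "age": rng.normal(23, 5, n),
            }
        )
        X, _ = build_design(cohort, ("age",))
        Y = rng.standard_normal((3, n))
        fit = fit_vertex_glm(Y, X)
        for k in range(3):
            res = smapi.OLS(Y[k], X).fit()
            assert fit.tstat[k] == pytest.approx(res.tvalues[1], rel=1e-10)

    def test_constant_marker_gives_zero_beta_and_t(self, small_cohort_table):
        X, _ = build_design(small_cohort_table, ("age",))
        y = np.full((1, 12), 5.0)
        fit = fit_vertex_glm(y, X)
        assert fit.beta[1, 0] == pytest.approx(0.0, abs=1e-10)
        assert fit.tstat[0] == 0.0


class TestPermutationFwer:
    def test_null_data_gives_p_one_everywhere(self, small_cohort_table):
        X, _ = build_design(small_cohort_table, ())
        y = np.full((5, 12), 2.0)
        res = permutation_fwer(y, X, n_permutations=99, seed=0)
        np.testing.assert_array_equal(res.p_fwer, 1.0)
        np.testing.assert_array_equal(res.p_uncorrected, 1.0)

    def test_strong_effect_attains_minimum_p(self):
        cohort = pd.DataFrame({"group": [1] * 10 + [0] * 10})
        X, _ = build_design(cohort, ())
        rng = np.random.default_rng(1)
        y = rng.standard_normal((4, 20)) * 0.01
        y[2] += 100.0 * X[:, 1]  # one vertex with an overwhelming effect
        res = permutation_fwer(y, X, n_permutations=999, seed=3)
        assert res.p_fwer[2] == pytest.approx(1 / 1000)
        assert res.significant[2]

    def test_matches_exhaustive_enumeration_three_per_group(self):
        """Monte Carlo max-|t| p at one vertex agrees with enumeration over
        all C(6,3)=20 relabelings within 3 Monte Carlo SEs."""
        y = np.array([[0.8, 1.1, 0.9, 2.0, 2.4, 2.1]])
        cohort = pd.DataFrame({"group": [0, 0, 0, 1, 1, 1]})
        X, _ = build_design(cohort, ())
        n_perm = 20000
        res = permutation_fwer(
            y, X, n_permutations=n_perm, seed=9, scheme="label-permutation"
        )

        def tstat(labels):
            Xl = np.column_stack([np.ones(6), labels])
            fit = fit_vertex_glm(y, Xl)
            return abs(fit.tstat[0])

        obs = tstat(np.array([0, 0, 0, 1, 1, 1.0]))
        stats = []
        for ones in itertools.combinations(range(6), 3):
            labels = np.zeros(6)
            labels[list(ones)] = 1.0
            stats.append(tstat(labels))
        p_exact = np.mean([s >= obs - 1e-12 for s in stats])
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(res.p_fwer[0] - p_exact) <= 3 * se + 1 / n_perm

    def test_p_fwer_monotone_in_observed_t(self):
        rng = np.random.default_rng(4)
        cohort = pd.DataFrame({"group": rng.permutation([1] * 8 + [0] * 8)})
        X, _ = build_design(cohort, ())
        y = rng.standard_normal((30, 16))
        res = permutation_fwer(y, X, n_permutations=199, seed=5)
        order = np.argsort(np.abs(res.tstat))
        assert (np.diff(res.p_fwer[order]) <= 1e-12).all()
        assert (res.p_fwer >= res.p_uncorrected - 1e-12).all()

    def test_subject_reordering_leaves_observed_statistics_unchanged(self):
        rng = np.random.default_rng(6)
        n = 16
        cohort = pd.DataFrame(
            {"group": rng.permutation([1] * 8 + [0] * 8), "age": rng.normal(23, 4, n)}
        )
        y = rng.standard_normal((10, n))
        X, _ = build_design(cohort, ("age",))
        res = permutation_fwer(y, X, n_permutations=49, seed=0)

        perm = rng.permutation(n)
        cohort2 = cohort.iloc[perm].reset_index(drop=True)
        X2, _ = build_design(cohort2, ("age",))
        res2 = permutation_fwer(y[:, perm], X2, n_permutations=49, seed=0)
        np.testing.assert_allclose(res2.beta1, res.beta1, rtol=1e-10)
        np.testing.assert_allclose(res2.tstat, res.tstat, rtol=1e-10)
        np.testing.assert_allclose(res2.d, res.d, rtol=1e-10)

    def test_invalid_scheme_rejected(self, small_cohort_table):
        X, _ = build_design(small_cohort_table, ())
        with pytest.raises(ValueError, match="scheme"):
            permutation_fwer(np.zeros((2, 12)), X, 10, scheme="bootstrap")


class TestVolumeStats:
    def test_zscore_basics(self):
        group = np.array([0, 0, 0, 1])
        vols = np.array([3.0, 4.0, 5.0, 4.0])
        z = volume_zscore(vols, group)
        assert z[3] == pytest.approx(0.0)
        hc = z[group == 0]
        assert hc.mean() == pytest.approx(0.0, abs=1e-12)
        assert hc.std(ddof=1) == pytest.approx(1.0)

    def test_zscore_from_reference_summary(self):
        """Direct formula on published summary values: a patient at the FES
        mean volume sits -0.4306 control SDs below the control mean."""
        z = (1594.89 - 1712.03) / 272.03
        assert z == pytest.approx(-0.4306, abs=5e-5)

    def test_zero_control_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            volume_zscore(np.array([1.0, 1.0, 2.0]), np.array([0, 0, 1]))

    def test_cohens_d_identities(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(1, 2, 15), rng.normal(0, 1, 12)
        # independent direct implementation from raw vectors
        sp = np.sqrt(((14) * x1.var(ddof=1) + (11) * x2.var(ddof=1)) / 25)
        expected = (x1.mean() - x2.mean()) / sp
        assert cohens_d_from_samples(x1, x2) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_volume_comparison_beta_equals_z_mean_difference(self):
        cfg = single_structure_config(10, subdivision_level=2)
        sim = simulate_cohort(cfg, seed=11)
        res = volume_group_comparison(
            sim.cohort, "left_amygdala", covariates=(), n_permutations=99, seed=0
        )
        grp = sim.cohort["group"].to_numpy()
        z = volume_zscore(sim.cohort["left_amygdala_volume_mm3"].to_numpy(), grp)
        assert res.beta_group == pytest.approx(z[grp == 1].mean() - z[grp == 0].mean(), rel=1e-10)

    def test_planted_volume_reduction_attains_minimum_p(self):
        from shapemorph import EffectSpec

        effect = EffectSpec(
            target_subregions={"basolateral", "basomedial", "centromedial", "lateral"},
            atrophy_amplitude=0.2,
            noise_sd=0.02,
        )
        cfg = single_structure_config(10, effect=effect, subdivision_level=2)
        sim = simulate_cohort(cfg, seed=2)
        res = volume_group_comparison(
            sim.cohort, "left_amygdala", n_permutations=199, seed=1
        )
        assert res.pvalue == pytest.approx(1 / 200)
        assert res.beta_group < 0

    def test_null_volume_p_uniform_over_replicates(self):
        """Under the global null the permutation p is (approximately) uniform."""
        from scipy import stats as spstats

        cfg = single_structure_config(8, subdivision_level=1)
        pvals = []
        root = np.random.SeedSequence(99)
        for rep in root.spawn(200):
            c_ss, p_ss = rep.spawn(2)
            sim = simulate_cohort(cfg, seed=c_ss)
            res = volume_group_comparison(
                sim.cohort, "left_amygdala", n_permutations=99, seed=p_ss
            )
            pvals.append(res.pvalue)
        ks = spstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestShapeGLMModel:
    def test_model_results_roundtrip_and_summary(self):
        cfg = single_structure_config(8, subdivision_level=1)
        sim = simulate_cohort(cfg, seed=21)
        markers = sim.marker_field("left_amygdala")
        model = ShapeGLM(markers, sim.cohort)
        res = model.fit(n_permutations=99, seed=0)
        assert res.p_fwer.shape == (markers.n_vertices,)
        assert 0 < res.structure_pvalue <= 1
        text = res.summary()
        assert "permutations: 99" in text and "freedman-lane" in text
        df = res.to_frame()
        assert list(df.columns) == ["vertex", "beta1", "t", "p_unc", "p_fwer", "d", "significant"]

    def test_misaligned_markers_rejected(self, small_cohort_table):
        markers = MarkerField(np.zeros((5, 7)), tuple(f"s{i}" for i in range(7)), log_scale=True)
        with pytest.raises(ValueError, match="align"):
            ShapeGLM(markers, small_cohort_table)
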