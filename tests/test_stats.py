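"""GLM contrasts, permutation null, pooled FDR, domain aggregation,
symptom correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msfnc.stats import (
    bprs_to_panss,
    domain_aggregate,
    framewise_displacement,
    glm_contrast,
    pooled_fdr,
    sex_permutation_null,
    symptom_correlation,
)


def make_pheno(rng, n=80, sites=("A", "B"), balanced=True):
    half = n // 2
    dx = np.array(["CT"] * half + ["SZ"] * (n - half))
    sex = np.tile(["male", "female"], n // 2)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "diagnosis": dx,
            "sex": sex,
            "age": rng.normal(38, 10, n),
            "site": rng.choice(sites, n),
            "mean_fd": rng.uniform(0.05, 0.3, n),
        }
    )


class TestFramewiseDisplacement:
    def test_constant_motion_zero(self):
        fd, mean = framewise_displacement(np.ones((50, 6)))
        assert mean == 0.0
        np.testing.assert_array_equal(fd, 0.0)

    def test_unit_step_single_axis(self):
        m = np.zeros((10, 6))
        m[5:, 0] = 1.0
        fd, _ = framewise_displacement(m)
        assert fd[5] == 1.0
        assert fd.sum() == 1.0

    def test_matches_elementwise_diff_oracle(self, rng):
        m = np.cumsum(rng.normal(0, 0.1, (100, 6)), axis=0)
        fd, mean = framewise_displacement(m)
        oracle = np.abs(np.diff(m, axis=0)).sum(axis=1)
        np.testing.assert_allclose(fd[1:], oracle)
        assert mean == pytest.approx(fd.mean())

    def test_rotation_conversion_scales_rotations_only(self, rng):
        m = rng.normal(0, 0.01, (20, 6))
        fd_raw, _ = framewise_displacement(m)
        fd_conv, _ = framewise_displacement(m, rotation_radius_mm=50.0)
        trans = np.abs(np.diff(m[:, :3], axis=0)).sum(axis=1)
        rot = np.abs(np.diff(m[:, 3:], axis=0)).sum(axis=1)
        np.testing.assert_allclose(fd_conv[1:], trans + 50.0 * rot)


class TestGlmContrast:
    def test_pure_shift_matches_pooled_t_oracle(self, rng):
        pheno = make_pheno(rng, n=60, sites=("A",))
        pheno["age"] = 40.0
        pheno["mean_fd"] = 0.1
        y = rng.standard_normal((60, 1))
        y[pheno["diagnosis"] == "SZ", 0] += 0.8
        males = pheno["sex"] == "male"
        t, _ = glm_contrast(y, pheno, "male")
        sub = pheno[males]
        oracle = sps.ttest_ind(
            y[males.to_numpy()][(sub["diagnosis"] == "SZ").to_numpy(), 0],
            y[males.to_numpy()][(sub["diagnosis"] == "CT").to_numpy(), 0],
        )
        assert t[0] == pytest.approx(oracle.statistic, abs=1e-8)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        pheno = make_pheno(rng, n=70)
        y = (
            0.5 * (pheno["diagnosis"] == "SZ")
            + 0.02 * pheno["age"]
            + rng.standard_normal(70)
        ).to_numpy()[:, None]
        t, p = glm_contrast(y, pheno, "female")
        sub = pheno[pheno["sex"] == "female"].reset_index(drop=True)
        X = pd.DataFrame(
            {
                "dx": (sub["diagnosis"] == "SZ").astype(float),
                "age": sub["age"],
                "site_B": (sub["site"] == "B").astype(float),
                "fd": sub["mean_fd"],
            }
        )
        X = sm.add_constant(X)
        fit = sm.OLS(y[(pheno["sex"] == "female").to_numpy(), 0], X).fit()
        assert t[0] == pytest.approx(fit.tvalues["dx"], abs=1e-8)
        assert p[0] == pytest.approx(fit.pvalues["dx"], abs=1e-10)

    def test_null_t_distribution_calibrated(self, rng):
        pheno = make_pheno(rng, n=80)
        y = rng.standard_normal((80, 2000))
        t, _ = glm_contrast(y, pheno, "male")
        n_m = int((pheno["sex"] == "male").sum())
        dof = n_m - 5  # intercept, dx, age, site_B, fd
        ks = sps.kstest(t, sps.t(df=dof).cdf)
        assert ks.pvalue > 0.01

    def test_constant_feature_rejected(self, rng):
        pheno = make_pheno(rng, n=40)
        y = np.ones((40, 1))
        with pytest.raises(ValueError, match="residual variance"):
            glm_contrast(y, pheno, "male")


class TestSexPermutation:
    def test_null_pvalues_uniform(self, rng):
        """Under exchangeable sex labels the permutation p-values are
        uniform (KS test on 300 null features)."""
        pheno = make_pheno(rng, n=60, sites=("A",))
        y = rng.standard_normal((60, 300))
        p, _ = sex_permutation_null(y, pheno, n_perm=199, seed=0)
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_interaction_at_floor(self, rng):
        pheno = make_pheno(rng, n=80, sites=("A",))
        y = rng.standard_normal((80, 1))
        boost = (
            (pheno["diagnosis"] == "SZ") & (pheno["sex"] == "male")
        ).to_numpy()
        y[boost, 0] += 3.0
        y[((pheno["diagnosis"] == "SZ") & (pheno["sex"] == "female")).to_numpy(), 0] -= 3.0
        p, obs = sex_permutation_null(y, pheno, n_perm=999, seed=1)
        assert p[0] == pytest.approx(1.0 / 1000.0)
        assert obs[0] > 0

    def test_zero_permutations_rejected(self, rng):
        pheno = make_pheno(rng, n=20)
        with pytest.raises(ValueError, match="n_perm"):
            sex_permutation_null(rng.standard_normal((20, 1)), pheno, n_perm=0)

    def test_group_sizes_preserved_in_every_draw(self, rng):
        # the engine asserts this internally per draw; run it to exercise
        pheno = make_pheno(rng, n=40, sites=("A",))
        sex_permutation_null(rng.standard_normal((40, 3)), pheno, n_perm=25, seed=2)


class TestPower:
    def test_injected_effect_detected_after_fdr(self):
        """Cohen's d = 0.8 at n = 60/60 survives pooled BH correction in
        at least 80% of simulation seeds."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 240  # 60 CT + 60 SZ within each sex cohort
            pheno = pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(n)],
                    "diagnosis": ["CT"] * 120 + ["SZ"] * 120,
                    "sex": np.tile(["male", "female"], 120),
                    "age": rng.normal(38, 10, n),
                    "site": rng.choice(["A", "B"], n),
                    "mean_fd": rng.uniform(0.05, 0.3, n),
                }
            )
            y = rng.standard_normal((n, 200))
            y[pheno["diagnosis"] == "SZ", 0] += 0.8
            # diagnosis effect tested on the full sample (both cohorts share it)
            _, p_m = glm_contrast(y, pheno, "male")
            _, p_f = glm_contrast(y, pheno, "female")
            rej = pooled_fdr(np.concatenate([p_m, p_f]), q=0.05)
            if rej[0] or rej[200]:
                hits += 1
        assert hits / n_seeds >= 0.8


class TestPooledFdr:
    def test_step_up_rule_by_hand(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_array_equal(
            pooled_fdr(p, q=0.05), [True, True, True, False]
        )

    def test_all_ones_no_rejections(self):
        assert pooled_fdr(np.ones(10)).sum() == 0

    def test_rejections_monotone_in_q(self, rng):
        p = rng.uniform(0, 1, 200) ** 2
        counts = [pooled_fdr(p, q=q).sum() for q in np.arange(0.01, 0.21, 0.01)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_empty_input_empty_output(self):
        assert pooled_fdr(np.array([])).size == 0


class TestDomainAggregate:
    @staticmethod
    def icn_frame(domains, orders):
        return pd.DataFrame({"domain": domains, "order": orders})

    def test_constant_matrix_all_blocks_constant(self):
        icns = self.icn_frame(["A", "A", "B", "B"], [25, 25, 25, 25])
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 1.0)
        dm = domain_aggregate(m, icns)
        np.testing.assert_allclose(dm.values[~np.isnan(dm.values)], 0.3)

    def test_two_by_two_toy_matches_hand_means(self):
        # hand-enumerated pairs for 2 domains x 2 orders, one ICN each
        icns = self.icn_frame(["A", "A", "B", "B"], [1, 2, 1, 2])
        m = np.array(
            [
                [1.0, 0.1, 0.2, 0.3],
                [0.1, 1.0, 0.4, 0.5],
                [0.2, 0.4, 1.0, 0.6],
                [0.3, 0.5, 0.6, 1.0],
            ]
        )
        dm = domain_aggregate(m, icns)
        labels = dm.labels
        assert labels == ["A1", "A2", "B1", "B2"]
        v = dm.values
        assert np.isnan(v[0, 0])  # singleton block: no within pair
        assert v[0, 1] == pytest.approx(0.1)  # A1-A2
        assert v[0, 2] == pytest.approx(0.2)  # A1-B1
        assert v[1, 3] == pytest.approx(0.5)  # A2-B2

    def test_seven_domains_four_orders_yield_28(self, rng):
        domains = np.repeat(list("ABCDEFG"), 8)
        orders = np.tile(np.repeat([25, 50, 75, 100], 2), 7)
        p = len(domains)
        m = np.corrcoef(rng.standard_normal((p, 200)))
        dm = domain_aggregate(m, self.icn_frame(domains, orders))
        assert dm.values.shape == (28, 28)
        np.testing.assert_allclose(dm.values, dm.values.T, equal_nan=True)

    def test_commutes_with_within_block_permutation(self, rng):
        domains = ["A"] * 3 + ["B"] * 3
        orders = [25] * 6
        p = 6
        m = np.corrcoef(rng.standard_normal((p, 100)))
        icns = self.icn_frame(domains, orders)
        base = domain_aggregate(m, icns).values
        perm = np.array([2, 0, 1, 3, 5, 4])  # permute within blocks
        m2 = m[np.ix_(perm, perm)]
        again = domain_aggregate(m2, icns).values
        np.testing.assert_allclose(base, again, equal_nan=True, atol=1e-12)


class TestSymptomCorrelation:
    def test_identity_feature_perfect_correlation(self, rng):
        s = rng.normal(50, 10, 40)
        r, p, n = symptom_correlation(s, s)
        assert r == pytest.approx(1.0)
        assert n == 40

    def test_null_feature_small_correlation(self, rng):
        hits = 0
        for _ in range(200):
            f = rng.standard_normal(200)
            s = rng.standard_normal(200)
            r, _, _ = symptom_correlation(f, s)
            hits += abs(r) < 0.2
        assert hits / 200 >= 0.95

    def test_confounded_partial_correlation_recovered(self):
        # oracle: planted partial correlation 0.3 behind an age confound
        rng = np.random.default_rng(5)
        n = 500
        age = rng.normal(40, 12, n)
        z = rng.standard_normal(n)
        f = 0.3 * z + np.sqrt(1 - 0.09) * rng.standard_normal(n) + 0.1 * age
        s = z + 0.2 * age
        r, _, _ = symptom_correlation(f, s, covariates=age[:, None])
        # partial r of f with s given age: corr(0.3 z + e, z) = 0.3
        assert r == pytest.approx(0.3, abs=0.05)

    def test_missing_scores_dropped_pairwise(self, rng):
        f = rng.standard_normal(30)
        s = rng.standard_normal(30)
        s[:5] = np.nan
        _, _, n = symptom_correlation(f, s)
        assert n == 25

    def test_too_few_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="need >="):
            symptom_correlation(rng.standard_normal(8), rng.standard_normal(8))


class TestBprsToPanss:
    def test_identity_table(self):
        table = np.column_stack([np.arange(20, 80), np.arange(20, 80)])
        assert bprs_to_panss(42.0, table) == pytest.approx(42.0)

    def test_linear_interpolation_between_rows(self):
        table = np.array([[20.0, 30.0], [40.0, 60.0]])
        assert bprs_to_panss(30.0, table) == pytest.approx(45.0)

    def test_matches_piecewise_linear_oracle(self, rng):
        b = np.sort(rng.choice(np.arange(18, 120), 15, replace=False)).astype(float)
        p = np.sort(rng.uniform(30, 200, 15))
        table = np.column_stack([b, p])
        probes = rng.uniform(b[0], b[-1], 100)
        np.testing.assert_allclose(
            bprs_to_panss(probes, table), np.interp(probes, b, p)
        )

    def test_non_monotone_table_rejected(self):
        table = np.array([[20.0, 30.0], [40.0, 25.0], [60.0, 80.0]])
        with pytest.raises(ValueError, match="monotone"):
            bprs_to_panss(30.0, table)

    def test_out_of_range_clamped_with_warning(self):
        table = np.array([[20.0, 30.0], [40.0, 60.0]])
        with pytest.warns(UserWarning, match="clamped"):
            assert bprs_to_panss(10.0, table) == pytest.approx(30.0)
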