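"""Ground-truth generator: hierarchy geometry, state sampling, rendering."""

import numpy as np
import pytest

from msfnc._utils import corr_matrix
from msfnc.simulate import (
    CohortSpec,
    EffectPair,
    StateSpec,
    hierarchical_covariance,
    make_hierarchical_sources,
    perturbed_covariance,
    render_cohort,
    simulate_state_timecourses,
    union_map,
)
from conftest import ATLAS_KW, GRID


class TestHierarchicalSources:
    def test_counts_and_hierarchy_bookkeeping(self, atlas):
        coarse, fine = atlas.maps
        assert coarse.shape[1] == 4
        assert fine.shape[1] == 8
        assert np.array_equal(atlas.hierarchy, np.arange(8) // 2)

    def test_maps_unit_norm_nonnegative_peak(self, atlas):
        for scale in atlas.maps:
            norms = np.linalg.norm(scale, axis=0)
            np.testing.assert_allclose(norms, 1.0, atol=1e-9)
            assert np.all(scale.max(axis=0) > 0)

    def test_within_scale_maps_distinct(self, atlas):
        for scale in atlas.maps:
            c = np.abs(corr_matrix(scale.T, scale.T))
            np.fill_diagonal(c, 0.0)
            assert c.max() < 0.5

    def test_coarse_is_not_a_simple_split(self, atlas):
        # oracle: direct correlation of the generated vectors
        for k in range(4):
            r = np.corrcoef(union_map(atlas, k), atlas.maps[0][:, k])[0, 1]
            assert 0.5 < r < 0.98

    def test_child_mass_mostly_inside_parent(self, atlas):
        coarse, fine = atlas.maps
        for j in range(fine.shape[1]):
            parent = coarse[:, atlas.hierarchy[j]]
            child = fine[:, j]
            inside = child[parent > 0.1 * parent.max()].sum() / child.sum()
            outside_hm = child[parent <= 0.5 * parent.max()].sum() / child.sum()
            assert inside >= 0.80
            assert outside_hm >= 0.10

    def test_split_factor_one_reproduces_coarse_scale(self):
        atlas = make_hierarchical_sources(GRID, 4, 1, seed=2, **ATLAS_KW)
        coarse, fine = atlas.maps
        assert fine.shape[1] == coarse.shape[1]
        for k in range(4):
            assert np.corrcoef(coarse[:, k], fine[:, k])[0, 1] > 0.99

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            make_hierarchical_sources((6, 6, 4), 4, 2, seed=0, **ATLAS_KW)

    def test_deterministic_under_seed(self):
        a = make_hierarchical_sources(GRID, 4, 2, seed=9, **ATLAS_KW)
        b = make_hierarchical_sources(GRID, 4, 2, seed=9, **ATLAS_KW)
        for ma, mb in zip(a.maps, b.maps):
            np.testing.assert_array_equal(ma, mb)


class TestStateSpec:
    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            StateSpec([bad])

    def test_transition_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            StateSpec(
                [np.eye(2), np.eye(2)],
                transition=np.array([[0.5, 0.4], [0.1, 0.9]]),
            )

    def test_default_transition_geometric_dwell(self):
        spec = StateSpec([np.eye(3)] * 2, dwell_mean=10.0)
        np.testing.assert_allclose(np.diag(spec.transition), 0.9)
        np.testing.assert_allclose(spec.transition.sum(axis=1), 1.0)

    def test_perturbed_covariance_is_valid_state(self, rng):
        base = hierarchical_covariance(np.arange(8) // 2, rho=0.4)
        pert = perturbed_covariance(base, 0.35, rng)
        StateSpec([base, pert])  # validates PSD + unit diagonal
        off = np.abs(pert - base)[~np.eye(8, dtype=bool)]
        assert off.max() > 0.2  # states are actually distinct


class TestStateTimecourses:
    def test_single_state_identity_covariance(self):
        spec = StateSpec([np.eye(4)])
        tc, labels = simulate_state_timecourses(spec, T=4000, seed=0)
        c = np.corrcoef(tc.T)
        np.fill_diagonal(c, 0.0)
        assert np.abs(c).max() < 0.05
        assert set(labels) == {0}

    def test_two_state_correlations_recovered_on_true_segments(self):
        # oracle: correlation computed separately on ground-truth segments
        c1 = np.eye(2)
        c1[0, 1] = c1[1, 0] = 0.8
        c2 = np.eye(2)
        c2[0, 1] = c2[1, 0] = -0.8
        spec = StateSpec([c1, c2], dwell_mean=50.0)
        tc, labels = simulate_state_timecourses(spec, T=8000, seed=1)
        for s, rho in [(0, 0.8), (1, -0.8)]:
            seg = tc[labels == s]
            assert abs(np.corrcoef(seg.T)[0, 1] - rho) < 0.05

    def test_identity_transition_keeps_one_state(self):
        spec = StateSpec([np.eye(3), np.eye(3)], transition=np.eye(2))
        _, labels = simulate_state_timecourses(spec, T=500, seed=2)
        assert len(set(labels)) == 1

    def test_empirical_covariance_converges(self, atlas):
        cov = hierarchical_covariance(atlas.hierarchy, rho=0.5)
        spec = StateSpec([cov])
        tc, _ = simulate_state_timecourses(spec, T=4000, seed=0)
        emp = (tc.T @ tc) / len(tc)
        assert np.abs(emp - cov).max() < 0.05


class TestRenderCohort:
    def test_noiseless_render_is_exact_mixing(self, atlas, states_single):
        cohort = CohortSpec(n_per_cell=1, seed=5, noise_sd=0.0, motion_amp=0.0)
        datasets, truth = render_cohort(atlas, states_single, cohort, T=50)
        for ds, rec in zip(datasets, truth["subjects"]):
            expect = atlas.fine_maps.T @ rec["timecourses"].T
            np.testing.assert_allclose(ds.data, expect, atol=1e-12)

    def test_noiseless_data_rank_bounded_by_sources(self, atlas, states_single):
        cohort = CohortSpec(n_per_cell=1, seed=5, noise_sd=0.0, motion_amp=0.0)
        datasets, _ = render_cohort(atlas, states_single, cohort, T=50)
        s = np.linalg.svd(datasets[0].data, compute_uv=False)
        assert np.sum(s > s[0] * 1e-10) <= atlas.n_fine

    def test_deterministic_under_seed(self, atlas, states_single):
        cohort = CohortSpec(n_per_cell=1, seed=7, noise_sd=0.1, motion_amp=0.02)
        d1, _ = render_cohort(atlas, states_single, cohort, T=40)
        d2, _ = render_cohort(atlas, states_single, cohort, T=40)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.data, b.data)
            np.testing.assert_array_equal(a.motion, b.motion)

    def test_subject_noise_independent(self, atlas, states_single):
        cohort = CohortSpec(n_per_cell=1, seed=7, noise_sd=0.1, motion_amp=0.0)
        datasets, truth = render_cohort(atlas, states_single, cohort, T=60)
        resid = [
            ds.data - atlas.fine_maps.T @ rec["timecourses"].T
            for ds, rec in zip(datasets, truth["subjects"])
        ]
        r = np.corrcoef(resid[0].ravel(), resid[1].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_cells_receive_effect_offsets(self, atlas):
        cov = hierarchical_covariance(atlas.hierarchy, rho=0.0)
        states = StateSpec([cov])
        effect = EffectPair(i=0, j=4, offsets={"SZ:male": 0.6})
        cohort = CohortSpec(
            n_per_cell=1, seed=11, noise_sd=0.0, motion_amp=0.0,
            effect_pairs=[effect],
        )
        _, truth = render_cohort(atlas, states, cohort, T=3000)
        by_cell = {s["cell"]: s["timecourses"] for s in truth["subjects"]}
        r_affected = np.corrcoef(by_cell["SZ:male"][:, 0], by_cell["SZ:male"][:, 4])[0, 1]
        r_control = np.corrcoef(by_cell["CT:male"][:, 0], by_cell["CT:male"][:, 4])[0, 1]
        assert r_affected > 0.4
        assert abs(r_control) < 0.15

    def test_offset_breaking_psd_raises(self, atlas):
        cov = hierarchical_covariance(atlas.hierarchy, rho=0.0)
        states = StateSpec([cov])
        effect = EffectPair(i=0, j=1, offsets={"SZ:male": 1.5})
        cohort = CohortSpec(n_per_cell=1, seed=1, effect_pairs=[effect])
        with pytest.raises(ValueError, match="PSD"):
            render_cohort(atlas, states, cohort, T=20)

    def test_null_cohort_t_statistics_calibrated(self, atlas):
        """With no planted effects, group labels are exchangeable: a
        two-sample t on FNC features exceeds the 97.5% reference point at
        roughly the nominal 5% two-sided rate."""
        from scipy import stats as sps

        cov = hierarchical_covariance(atlas.hierarchy, rho=0.0)
        states = StateSpec([cov])
        cohort = CohortSpec(n_per_cell=10, seed=13, noise_sd=0.0, motion_amp=0.0)
        _, truth = render_cohort(atlas, states, cohort, T=200)
        iu = np.triu_indices(8, k=1)
        feats, dx = [], []
        for rec in truth["subjects"]:
            feats.append(np.corrcoef(rec["timecourses"].T)[iu])
            dx.append(rec["cell"].startswith("SZ"))
        feats = np.asarray(feats)
        dx = np.asarray(dx)
        t, _ = sps.ttest_ind(feats[dx], feats[~dx], axis=0)
        crit = sps.t.ppf(0.975, df=len(dx) - 2)
        rate = np.mean(np.abs(t) > crit)
        assert rate < 0.25  # 28 pairs: ~1.4 expected, tolerate sampling noise
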