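import numpy as np
import pytest
from scipy.stats import ortho_group

from ctasca import (
    TimeBasis,
    bootstrap_pipeline,
    bootstrap_subjects,
    percentile_ci,
    procrustes_align,
)


class TestBootstrapSubjects:
    def test_replicates_keep_subject_count(self, small_sim):
        reps = bootstrap_subjects(small_sim["data"], 5, seed=1)
        assert len(reps) == 5
        for rep in reps:
            assert rep.dims == small_sim["data"].dims

    def test_whole_series_carried(self, small_sim):
        data = small_sim["data"]
        rep = bootstrap_subjects(data, 1, seed=2)[0]
        # each replicate subject's block equals some original subject's block
        orig = {
            s: data.df[data.df.subject == s][data.response_cols].to_numpy()
            for s in data.subjects
        }
        for s in rep.subjects:
            block = rep.df[rep.df.subject == s][rep.response_cols].to_numpy()
            source = s.split(":", 1)[1]
            np.testing.assert_array_equal(block, orig[source])

    def test_duplicates_get_fresh_ids(self, small_sim):
        rep = bootstrap_subjects(small_sim["data"], 1, seed=3)[0]
        assert len(rep.subjects) == small_sim["data"].dims.I

    def test_seed_reproducibility(self, small_sim):
        a = bootstrap_subjects(small_sim["data"], 3, seed=7)
        b = bootstrap_subjects(small_sim["data"], 3, seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.Y, rb.Y)

    def test_single_subject_degenerate(self):
        import pandas as pd
        from ctasca import LongDataset

        df = pd.DataFrame(
            {
                "subject": ["s1"] * 4,
                "treatment": ["A", "A", "B", "B"],
                "time": [0.0, 1.0, 0.0, 1.0],
                "y": [1.0, 2.0, 3.0, 4.0],
            }
        )
        data = LongDataset(df, ["y"])
        rep = bootstrap_subjects(data, 2, seed=0)[0]
        assert rep.dims.I == 1
        np.testing.assert_array_equal(np.sort(rep.Y, axis=0), np.sort(data.Y, axis=0))

    def test_nboot_zero_errors(self, small_sim):
        with pytest.raises(ValueError):
            bootstrap_subjects(small_sim["data"], 0, seed=0)


class TestProcrustes:
    def test_identity_when_equal(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        _, _, R = procrustes_align(P, P)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_planted_rotation_recovered(self):
        rng = np.random.default_rng(1)
        P_ref = rng.normal(size=(12, 3))
        Q = ortho_group.rvs(3, random_state=5)
        P_boot = P_ref @ Q
        P_rot, _, R = procrustes_align(P_boot, P_ref)
        np.testing.assert_allclose(P_rot, P_ref, atol=1e-10)
        np.testing.assert_allclose(R, Q.T, atol=1e-10)

    def test_scores_rotated_with_same_matrix(self):
        rng = np.random.default_rng(2)
        P_ref = rng.normal(size=(8, 2))
        Q = ortho_group.rvs(2, random_state=3)
        T = rng.normal(size=(20, 2))
        _, T_rot, R = procrustes_align(P_ref @ Q, P_ref, T)
        np.testing.assert_allclose(T_rot, T @ R, atol=1e-12)

    def test_beats_random_rotations(self):
        rng = np.random.default_rng(3)
        P_ref = rng.normal(size=(15, 3))
        P_boot = P_ref + 0.3 * rng.normal(size=(15, 3))
        P_rot, _, _ = procrustes_align(P_boot, P_ref)
        best = np.linalg.norm(P_rot - P_ref)
        for k in range(1000):
            Q = ortho_group.rvs(3, random_state=k)
            assert best <= np.linalg.norm(P_boot @ Q - P_ref) + 1e-12

    def test_rotation_preserves_frobenius_norm(self):
        rng = np.random.default_rng(4)
        P_ref = rng.normal(size=(9, 3))
        P_boot = rng.normal(size=(9, 3))
        P_rot, _, R = procrustes_align(P_boot, P_ref)
        assert np.linalg.norm(P_rot) == pytest.approx(np.linalg.norm(P_boot))
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            procrustes_align(np.zeros((3, 2)), np.zeros((4, 2)))


class TestPercentileCi:
    def test_known_percentiles(self):
        stack = np.arange(1.0, 101.0)[:, None]
        lo, hi = percentile_ci(stack, 0.95)
        assert lo[0] == pytest.approx(np.percentile(stack, 2.5, method="lower"))
        assert hi[0] == pytest.approx(np.percentile(stack, 97.5, method="higher"))

    def test_two_values_collapse_to_min_max(self):
        stack = np.array([[1.0, 5.0], [3.0, -2.0]])
        lo, hi = percentile_ci(stack, 0.95)
        np.testing.assert_array_equal(lo, [1.0, -2.0])
        np.testing.assert_array_equal(hi, [3.0, 5.0])

    def test_constant_replicates(self):
        stack = np.full((10, 3), 2.5)
        lo, hi = percentile_ci(stack, 0.95)
        np.testing.assert_array_equal(lo, 2.5)
        np.testing.assert_array_equal(hi, 2.5)

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_trials = 200
        for _ in range(n_trials):
            sample = rng.normal(size=40)
            reps = np.array(
                [rng.choice(sample, size=40).mean() for _ in range(200)]
            )[:, None]
            lo, hi = percentile_ci(reps, 0.95)
            hits += lo[0] <= 0.0 <= hi[0]
        assert hits / n_trials >= 0.85  # nominal 95% within Monte-Carlo error

    def test_single_replicate_errors(self):
        with pytest.raises(ValueError):
            percentile_ci(np.zeros((1, 2)), 0.95)


class TestBootstrapPipeline:
    def test_two_replicates_bounds_are_min_max(self, small_sim):
        res = bootstrap_pipeline(
            small_sim["data"], TimeBasis("polynomial", 2), effect="MTf",
            A=1, n_boot=2, seed=9,
        )
        # with exactly two replicates the percentile bounds collapse to the
        # elementwise min/max
        assert (res.loading_table.lower <= res.loading_table.upper).all()
        lo, hi = res.loading_table.lower, res.loading_table.upper
        assert res.replicate_failures == 0
        stackable = hi - lo
        assert (stackable >= 0).all()

    def test_noise_free_intervals_are_tight(self):
        import numpy as np
        from ctasca import SimulationSpec, simulate_dataset

        spec = SimulationSpec(
            beta_tilde=np.array(
                [[5.0, 0.5, -0.04, 0.2, -0.02], [4.0, -0.3, 0.02, -0.1, 0.01]]
            ),
            D_tilde=np.zeros((5, 5)),
            sigma_eps=0.0,
            t=np.arange(5.0),
            n_subjects=6,
            seed=1,
        )
        data, _ = simulate_dataset(spec)
        res = bootstrap_pipeline(
            data, TimeBasis("polynomial", 2), effect="MTf", A=1, n_boot=5, seed=2
        )
        lt = res.loading_table
        assert np.allclose(lt.upper - lt.lower, 0.0, atol=1e-8)
        assert ((lt.value >= lt.lower - 1e-8) & (lt.value <= lt.upper + 1e-8)).all()

    def test_random_effect_matrix_rejected(self, small_sim):
        with pytest.raises(ValueError, match="fixed-effect"):
            bootstrap_pipeline(
                small_sim["data"], TimeBasis("polynomial", 2), effect="MTr",
                A=1, n_boot=2, seed=0,
            )

    def test_alignment_preserves_explained_variance(self, small_sim):
        # rotation invariance of the Frobenius norm: the aligned replicate
        # reconstructs the same matrix, so explained variance is unchanged
        rng = np.random.default_rng(0)
        M = rng.normal(size=(10, 4))
        from ctasca import center_columns, pca_svd

        Mc, _ = center_columns(M)
        res = pca_svd(Mc, 3)
        Q = ortho_group.rvs(3, random_state=1)
        recon_rot = (res.scores @ Q) @ (res.loadings @ Q).T
        np.testing.assert_allclose(recon_rot, res.reconstruct(), atol=1e-10)
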