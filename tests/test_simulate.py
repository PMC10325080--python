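import numpy as np
import pytest

from ctasca import (
    SimulationSpec,
    analyse_effect,
    encode_ground_truth,
    reference_scenario,
    simulate_dataset,
)


def _plain_spec(**kw):
    kw.setdefault("beta_tilde", np.array([[5.0, 0.3, -0.02, 0.1, -0.01]]))
    kw.setdefault("D_tilde", np.zeros((5, 5)))
    kw.setdefault("sigma_eps", 0.0)
    kw.setdefault("t", np.arange(4.0))
    kw.setdefault("n_subjects", 3)
    return SimulationSpec(**kw)


class TestSimulationSpec:
    def test_non_psd_D_rejected(self):
        D = np.eye(5)
        D[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive semidefinite"):
            _plain_spec(D_tilde=D)

    def test_asymmetric_D_rejected(self):
        D = np.eye(5)
        D[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            _plain_spec(D_tilde=D)

    def test_wrong_beta_width_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            _plain_spec(beta_tilde=np.ones((2, 4)))

    def test_decreasing_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            _plain_spec(t=np.array([0.0, 2.0, 1.0]))


class TestSimulateDataset:
    def test_degenerate_curves_equal_population_curve(self):
        spec = _plain_spec()
        data, gamma = simulate_dataset(spec)
        np.testing.assert_array_equal(gamma, 0.0)
        _, design = spec.design_for()
        np.testing.assert_allclose(
            data.Y[:, 0], design.X @ spec.beta_tilde[0], atol=1e-12
        )

    def test_reference_dims(self):
        data, _ = simulate_dataset(reference_scenario(seed=0))
        assert data.Y.shape == (880, 25)
        d = data.dims
        assert (d.I, d.H, d.K, d.J) == (40, 2, 11, 25)

    def test_seed_determinism(self):
        spec = reference_scenario(seed=13)
        a, ga = simulate_dataset(spec)
        b, gb = simulate_dataset(spec)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(ga, gb)

    def test_gamma_shared_across_treatments(self):
        sd = 0.5 * np.ones(5)
        spec = _plain_spec(
            D_tilde=np.diag(sd**2), sigma_eps=0.0, n_subjects=4, seed=3
        )
        data, gamma = simulate_dataset(spec)
        _, design = spec.design_for()
        # reconstruct per-row random part from the returned draws: it must
        # explain the data exactly, implying one draw per subject
        rand = np.einsum("np,npj->nj", design.X, gamma[design.subject_index])
        np.testing.assert_allclose(
            data.Y, design.X @ spec.beta_tilde.T + rand, atol=1e-10
        )

    def test_gamma_covariance_approaches_D(self):
        sd = np.array([0.5, 0.2, 0.05, 0.1, 0.02])
        corr = 0.3 * np.ones((5, 5)) + 0.7 * np.eye(5)
        D = corr * np.outer(sd, sd)
        spec = _plain_spec(
            beta_tilde=np.zeros((1, 5)), D_tilde=D, n_subjects=2000, t=np.arange(2.0), seed=9
        )
        _, gamma = simulate_dataset(spec)
        emp = np.cov(gamma[:, :, 0].T)
        assert np.abs(emp - D).max() < 0.12 * sd.max() ** 2 + 0.02


class TestEncodeGroundTruth:
    def test_sum_equals_noise_free_signal(self):
        spec = reference_scenario(seed=2)
        data, gamma = simulate_dataset(spec)
        truth = encode_ground_truth(spec, gamma)
        noise_free = SimulationSpec(
            beta_tilde=spec.beta_tilde, D_tilde=spec.D_tilde, sigma_eps=0.0,
            t=spec.t, n_subjects=spec.n_subjects, seed=spec.seed,
        )
        # same seed => identical gamma draws (gamma drawn before noise)
        data0, gamma0 = simulate_dataset(noise_free)
        np.testing.assert_array_equal(gamma, gamma0)
        np.testing.assert_allclose(truth.model_sum(), data0.Y, atol=1e-10)

    def test_zero_time_rows_give_zero_MTf(self):
        spec = _plain_spec(beta_tilde=np.array([[5.0, 0.0, 0.0, 0.2, -0.01]]))
        data, gamma = simulate_dataset(spec)
        truth = encode_ground_truth(spec, gamma)
        np.testing.assert_array_equal(truth.MTf, 0.0)

    def test_MTf_row_at_t3(self):
        spec = _plain_spec(
            beta_tilde=np.array(
                [[5.0, 0.3, -0.02, 0.1, -0.01], [1.0, -0.4, 0.05, 0.0, 0.0]]
            ),
            n_subjects=2,
        )
        data, gamma = simulate_dataset(spec)
        truth = encode_ground_truth(spec, gamma)
        rows = np.flatnonzero(data.df.time.to_numpy() == 3.0)
        expected = 3.0 * spec.beta_tilde[:, 1] + 9.0 * spec.beta_tilde[:, 2]
        for r in rows:
            np.testing.assert_allclose(truth.MTf[r], expected, atol=1e-12)

    def test_mismatched_gamma_shape_errors(self):
        spec = _plain_spec()
        with pytest.raises(ValueError, match="shape"):
            encode_ground_truth(spec, np.zeros((2, 5, 1)))


class TestReferenceScenario:
    def test_encoded_effects_are_rank_two(self):
        spec = reference_scenario(seed=1)
        data, gamma = simulate_dataset(spec)
        truth = encode_ground_truth(spec, gamma)
        for name in ("MTf", "MTGf"):
            M = truth[name]
            Mc = M - M.mean(axis=0)
            s = np.linalg.svd(Mc, compute_uv=False)
            assert s[2] < 1e-8 * s[0]  # third component carries ~0 variance

    def test_encoded_patterns_one_increasing_one_parabolic(self):
        spec = reference_scenario(seed=1)
        data, gamma = simulate_dataset(spec)
        truth = encode_ground_truth(spec, gamma)
        res = analyse_effect(
            truth.MTf, "trajectory", 2, spec.dims, row_labels=data.row_labels
        )
        sf = res.scores_frame()
        one_treatment = sf[sf.treatment == "A"].groupby("time").mean(numeric_only=True)
        t = one_treatment.index.to_numpy()
        # one component is essentially linear, the other parabolic
        pc1 = one_treatment["PC1"].to_numpy()
        pc2 = one_treatment["PC2"].to_numpy()
        hump = t * (t.max() - t)
        r = {
            "lin": (abs(np.corrcoef(pc1, t)[0, 1]), abs(np.corrcoef(pc2, t)[0, 1])),
            "hump": (abs(np.corrcoef(pc1, hump)[0, 1]), abs(np.corrcoef(pc2, hump)[0, 1])),
        }
        assert max(r["lin"]) > 0.97 and max(r["hump"]) > 0.97
        assert np.argmax(r["lin"]) != np.argmax(r["hump"])

    def test_interaction_patterns_diverge_between_treatments(self):
        spec = reference_scenario(seed=1)
        data, gamma = simulate_dataset(spec)
        truth = encode_ground_truth(spec, gamma)
        res = analyse_effect(
            truth.MTGf, "trajectory", 2, spec.dims, row_labels=data.row_labels
        )
        sf = res.scores_frame()
        mean_by = sf.groupby(["treatment", "time"]).mean(numeric_only=True)
        a = mean_by.loc["A"]["PC1"].to_numpy()
        b = mean_by.loc["B"]["PC1"].to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-8)  # mirror-image divergence
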