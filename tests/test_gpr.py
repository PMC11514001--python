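"""Kernel algebra, blocked reductions, marginal likelihood, training and
prediction of the per-atom GP regressors."""

import numpy as np
import pytest

from dimergpr.alf import PHI_FEATURE_INDICES
from dimergpr.gpr import (
    AtomicGPRModel,
    KernelHyperparameters,
    Standardization,
    TrainingConfig,
    blocked_kernel_matvec,
    kernel_matrix,
    kernel_value,
    load_model,
    log_marginal_likelihood,
    predict_energies,
    predict_energy,
    predict_gradient,
    save_model,
    train_atomic_model,
)
from dimergpr.alf import ALFSpec

ND = 12


def _random_features(rng, n):
    X = rng.uniform(-2.0, 2.0, (n, ND))
    for d in PHI_FEATURE_INDICES:
        X[:, d] = rng.uniform(-np.pi, np.pi, n)
    return X


def _random_hp(rng):
    return KernelHyperparameters(
        lengthscales=rng.uniform(0.5, 3.0, ND),
        signal_variance=float(rng.uniform(0.5, 5.0)),
        noise_variance=float(rng.uniform(0.0, 0.1)),
        prior_mean=float(rng.normal()),
    )


class TestKernel:
    def test_self_kernel_equals_signal_variance(self, rng):
        hp = _random_hp(rng)
        f = _random_features(rng, 1)[0]
        assert kernel_value(f, f, hp) == pytest.approx(hp.signal_variance, rel=1e-14)

    def test_periodic_in_phi_dimensions(self, rng):
        hp = _random_hp(rng)
        f1, f2 = _random_features(rng, 2)
        shifted = f2.copy()
        for d in PHI_FEATURE_INDICES:
            shifted[d] += 2 * np.pi
        assert kernel_value(f1, shifted, hp) == pytest.approx(
            kernel_value(f1, f2, hp), rel=1e-12)

    def test_matches_term_by_term_formula(self, rng):
        # independent oracle: direct evaluation of the published closed form
        hp = _random_hp(rng)
        for _ in range(20):
            f1, f2 = _random_features(rng, 2)
            expo = 0.0
            for d in range(ND):
                if d in PHI_FEATURE_INDICES:
                    expo += 2.0 * np.sin(0.5 * (f1[d] - f2[d])) ** 2 / hp.lengthscales[d] ** 2
                else:
                    expo += (f1[d] - f2[d]) ** 2 / (2.0 * hp.lengthscales[d] ** 2)
            expected = hp.signal_variance * np.exp(-expo)
            assert kernel_value(f1, f2, hp) == pytest.approx(expected, rel=1e-12)

    def test_symmetric(self, rng):
        hp = _random_hp(rng)
        f1, f2 = _random_features(rng, 2)
        assert kernel_value(f1, f2, hp) == pytest.approx(
            kernel_value(f2, f1, hp), rel=1e-14)

    def test_kernel_matrix_positive_semidefinite(self, rng):
        hp = _random_hp(rng)
        X = _random_features(rng, 100)
        K = kernel_matrix(X, X, hp)
        eig = np.linalg.eigvalsh(K)
        assert eig.min() >= -1e-8 * hp.signal_variance


class TestBlockedMatvec:
    @pytest.mark.parametrize("block_size", [1, 7, 200])
    def test_equals_dense_product(self, rng, block_size):
        hp = _random_hp(rng)
        X = _random_features(rng, 200)
        v = rng.normal(size=200)
        dense = kernel_matrix(X, X, hp) @ v
        blocked = blocked_kernel_matvec(X, v, hp, block_size)
        denom = np.abs(dense).max()
        assert np.abs(blocked - dense).max() / denom < 1e-10

    def test_zero_vector_maps_to_zero(self, rng):
        hp = _random_hp(rng)
        X = _random_features(rng, 50)
        assert np.all(blocked_kernel_matvec(X, np.zeros(50), hp, 8) == 0.0)


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self, rng):
        hp = _random_hp(rng)
        jitter = 1e-8
        got = log_marginal_likelihood(_random_features(rng, 1),
                                      np.array([hp.prior_mean]), hp, jitter)
        var = hp.signal_variance + hp.noise_variance + jitter * hp.signal_variance
        expected = -0.5 * np.log(var) - 0.5 * np.log(2 * np.pi)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_invariant_under_reordering(self, rng):
        hp = _random_hp(rng)
        X = _random_features(rng, 40)
        y = rng.normal(size=40)
        perm = rng.permutation(40)
        a = log_marginal_likelihood(X, y, hp)
        b = log_marginal_likelihood(X[perm], y[perm], hp)
        assert a == pytest.approx(b, rel=1e-10)

    def test_matches_naive_dense_implementation(self, rng):
        # independent oracle: slogdet + explicit inverse
        hp = _random_hp(rng)
        jitter = 1e-8
        X = _random_features(rng, 50)
        y = rng.normal(size=50)
        K = kernel_matrix(X, X, hp) + \
            (hp.noise_variance + jitter * hp.signal_variance) * np.eye(50)
        yc = y - hp.prior_mean
        _, logdet = np.linalg.slogdet(K)
        expected = -0.5 * yc @ np.linalg.solve(K, yc) - 0.5 * logdet \
            - 25 * np.log(2 * np.pi)
        got = log_marginal_likelihood(X, y, hp, jitter)
        assert got == pytest.approx(expected, abs=1e-8)


class TestTraining:
    def test_constant_labels_recover_constant(self, rng):
        X = _random_features(rng, 30)
        y = np.full(30, 7.25)
        model = train_atomic_model(X, y, TrainingConfig(seed=0, n_restarts=2,
                                                        max_iter=50))
        assert model.hyperparameters.prior_mean == pytest.approx(7.25)
        probe = _random_features(rng, 5)
        assert np.abs(predict_energies(model, probe) - 7.25).max() < 1e-6

    def test_noiseless_linear_function_interpolated(self, rng):
        X = _random_features(rng, 30)
        y = 3.0 * X[:, 0] - 1.0
        # near-noiseless regime: tiny jitter and noise floor so the
        # posterior interpolates
        model = train_atomic_model(X, y, TrainingConfig(seed=1, jitter=1e-10,
                                                        noise_floor=1e-10))
        pred = predict_energies(model, X)
        assert np.abs(pred - y).max() < 1e-4

    def test_same_seed_reproduces_hyperparameters(self, rng):
        X = _random_features(rng, 40)
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        cfg = TrainingConfig(seed=11, n_restarts=3, max_iter=80)
        m1 = train_atomic_model(X, y, cfg)
        m2 = train_atomic_model(X, y, cfg)
        np.testing.assert_array_equal(m1.hyperparameters.lengthscales,
                                      m2.hyperparameters.lengthscales)
        assert m1.hyperparameters.signal_variance == m2.hyperparameters.signal_variance

    def test_optimum_beats_every_restart_initial_point(self, rng):
        X = _random_features(rng, 50)
        y = np.sin(X[:, 0]) + rng.normal(0, 0.05, 50)
        model = train_atomic_model(X, y, TrainingConfig(seed=2, n_restarts=4))
        assert model.info["lml"] >= max(model.info["initial_lmls"]) - 1e-9

    def test_lengthscale_recovery_from_known_gp(self):
        # data drawn from a GP whose ARD lengthscales are known: three
        # dimensions carry signal, the rest are effectively flat
        rng = np.random.default_rng(0)
        n = 300
        X = _random_features(rng, n)
        true_l = np.full(ND, 50.0)
        true_l[[0, 1, 2]] = [2.0, 2.5, 1.8]
        hp = KernelHyperparameters(true_l, 4.0, 0.0, 0.0)
        K = kernel_matrix(X, X, hp) + 1e-8 * np.eye(n)
        y = np.linalg.cholesky(K) @ rng.standard_normal(n)
        model = train_atomic_model(X, y, TrainingConfig(seed=0, n_restarts=3,
                                                        max_iter=200))
        recovered = model.hyperparameters.lengthscales * model.standardization.scale
        log_ratio = np.log(recovered[[0, 1, 2]] / true_l[[0, 1, 2]])
        assert np.abs(log_ratio).max() < 0.3


class TestPrediction:
    def _toy_model(self, rng, n=3):
        X = _random_features(rng, n)
        hp = KernelHyperparameters(np.full(ND, 1.5), 2.0, 0.0, prior_mean=1.0)
        alpha = rng.normal(size=n)
        std = Standardization(np.zeros(ND), np.ones(ND))
        return AtomicGPRModel(0, ALFSpec(0, 1, 2), X, alpha, hp, std, block_size=2)

    def test_three_point_hand_expansion(self, rng):
        model = self._toy_model(rng)
        f = _random_features(rng, 1)[0]
        expected = model.hyperparameters.prior_mean + sum(
            model.dual_coefficients[i]
            * kernel_value(f, model.training_features[i], model.hyperparameters)
            for i in range(3)
        )
        assert predict_energy(model, f) == pytest.approx(expected, rel=1e-12)

    def test_interpolates_training_labels_at_low_noise(self, rng):
        X = _random_features(rng, 25)
        y = np.cos(X[:, 2]) + X[:, 0] ** 2
        model = train_atomic_model(X, y, TrainingConfig(seed=3, jitter=1e-10,
                                                        noise_floor=1e-10))
        pred = predict_energies(model, X)
        assert np.abs(pred - y).max() < 1e-3

    def test_far_point_reverts_to_prior_mean(self, rng):
        model = self._toy_model(rng)
        f = _random_features(rng, 1)[0]
        f[0] += 100.0  # >= 50 lengthscales away in one aperiodic dimension
        assert predict_energy(model, f) == pytest.approx(
            model.hyperparameters.prior_mean, abs=1e-8)

    def test_feature_length_mismatch_raises(self, rng):
        model = self._toy_model(rng)
        with pytest.raises(ValueError, match="length"):
            predict_energy(model, np.zeros(7))
        with pytest.raises(ValueError, match="length"):
            predict_gradient(model, np.zeros(7))


class TestPredictGradient:
    def test_matches_central_finite_differences(self, rng):
        X = _random_features(rng, 40)
        y = np.sin(X[:, 0]) * np.cos(X[:, 5]) + X[:, 3]
        model = train_atomic_model(X, y, TrainingConfig(seed=4))
        h = 1e-4  # 4th-order stencil: truncation ~h^4, roundoff ~eps/h
        for f in _random_features(rng, 5):
            grad = predict_gradient(model, f)
            fd = np.zeros(ND)
            for d in range(ND):
                es = []
                for mlt in (2, 1, -1, -2):
                    fp = f.copy()
                    fp[d] += mlt * h
                    es.append(predict_energy(model, fp))
                fd[d] = (-es[0] + 8 * es[1] - 8 * es[2] + es[3]) / (12 * h)
            assert np.abs(grad - fd).max() < 1e-6

    def test_vanishes_far_from_data(self, rng):
        X = _random_features(rng, 20)
        y = X[:, 1] ** 2
        model = train_atomic_model(X, y, TrainingConfig(seed=5))
        f = _random_features(rng, 1)[0]
        f[:3] += 500.0
        assert np.abs(predict_gradient(model, f)).max() < 1e-10

    def test_prediction_continuous_across_phi_branch_cut(self, rng):
        # the periodic kernel factor makes the model continuous at phi = +-pi
        X = _random_features(rng, 30)
        y = np.cos(X[:, 5]) + 0.3 * np.sin(X[:, 8])
        model = train_atomic_model(X, y, TrainingConfig(seed=6))
        f = _random_features(rng, 1)[0]
        eps = 1e-8
        lo, hi = f.copy(), f.copy()
        lo[5], hi[5] = -np.pi + eps, np.pi - eps
        assert predict_energy(model, lo) == pytest.approx(
            predict_energy(model, hi), abs=1e-6)
        g_lo = predict_gradient(model, lo)
        g_hi = predict_gradient(model, hi)
        assert np.abs(g_lo - g_hi).max() < 1e-6


class TestSerialization:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        X = _random_features(rng, 25)
        y = np.sin(X[:, 0])
        model = train_atomic_model(X, y, TrainingConfig(seed=7, n_restarts=2,
                                                        max_iter=60))
        path = tmp_path / "atom.npz"
        save_model(model, path)
        back = load_model(path)
        probe = _random_features(rng, 10)
        np.testing.assert_array_equal(predict_energies(back, probe),
                                      predict_energies(model, probe))
        assert back.alf == model.alf
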