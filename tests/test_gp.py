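import numpy as np
import pytest

from mlifpet.carotid_segmentation import IdifSet
from mlifpet.curves import TimeActivityCurve, window_0_to_6min
from mlifpet.gp_mlif import (
    NormalizationConstants,
    TrainingSet,
    build_training_set,
    fit_normalization,
    loo_cross_validate,
    matern52,
    normalize,
    predict,
    train,
)
from mlifpet.phantom import generate_aif

from conftest import gamma_bolus


def make_idifs(scale=1.0, delay=0.0, n=40):
    """Small synthetic IDIF triple on an n-point grid."""
    t = np.arange(float(n))
    base = gamma_bolus(t, amplitude=scale * 10.0, t0=5.0 + delay, tp=6.0, alpha=3.0)
    mk = lambda f: TimeActivityCurve(t, f * base + 0.01, grid_kind="uniform-1s")
    return IdifSet(mk(1.0), mk(0.7), mk(0.4))


def make_cohort(n_subjects=5, n=40, seed=0):
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        scale = rng.uniform(0.6, 1.4)
        delay = rng.uniform(-2, 2)
        idifs = make_idifs(scale=scale, delay=delay, n=n)
        t = np.arange(float(n))
        aif = TimeActivityCurve(
            t, gamma_bolus(t, amplitude=30.0 * scale, t0=4.0 + delay, tp=5.0), "uniform-1s"
        )
        cohort.append((idifs, aif))
    return cohort


class TestNormalization:
    def test_per_channel_cohort_maximum(self):
        a = make_idifs(scale=0.5)
        b = make_idifs(scale=0.8)
        norm = fit_normalization([a, b])
        assert norm.peak10 == pytest.approx(b.idif10.peak)
        assert norm.peak1000 == pytest.approx(b.idif1000.peak)

    def test_permutation_invariant(self):
        sets = [make_idifs(scale=s) for s in (0.5, 1.2, 0.9)]
        n1 = fit_normalization(sets)
        n2 = fit_normalization(sets[::-1])
        assert n1 == n2

    def test_cohort_max_curve_maps_to_one(self):
        a = make_idifs(scale=0.5)
        b = make_idifs(scale=0.8)
        norm = fit_normalization([a, b])
        x = normalize(b, norm)
        assert x.max() == pytest.approx(1.0)
        assert np.all(x >= 0) and np.all(x <= 1.0 + 1e-12)

    def test_normalize_is_linear_in_test_input(self):
        norm = NormalizationConstants(2.0, 3.0, 4.0)
        idifs = make_idifs()
        scaled = IdifSet(*(c.with_values(c.value * 3.0) for c in idifs.channels()))
        assert np.allclose(normalize(scaled, norm), 3.0 * normalize(idifs, norm))

    def test_single_subject_uses_own_peaks(self):
        a = make_idifs(scale=1.1)
        norm = fit_normalization([a])
        assert norm.peak100 == pytest.approx(a.idif100.peak)


class TestTraining:
    def test_training_is_deterministic(self):
        ts = build_training_set(make_cohort())
        m1, m2 = train(ts), train(ts)
        assert (m1.lengthscale, m1.signal_var, m1.noise_var) == (
            m2.lengthscale,
            m2.signal_var,
            m2.noise_var,
        )

    def test_optimization_does_not_decrease_marginal_likelihood(self):
        ts = build_training_set(make_cohort())
        init = (1.0, 10.0, 1.0)
        m_init = train(ts, init=init, optimize=False)
        m_opt = train(ts, init=init)
        assert m_opt.log_marginal_likelihood >= m_init.log_marginal_likelihood - 1e-9

    def test_lengthscale_recovered_from_matern_samples(self):
        """Self-consistency: data drawn from a Matern-5/2 GP with known
        lengthscale gives it back within 25% (N=40, T=50)."""
        rng = np.random.default_rng(12)
        true_ell, true_sf2, true_sn2 = 0.8, 4.0, 0.01
        X = rng.uniform(0, 2, size=(40, 3))
        K = matern52(X, X, true_ell, true_sf2) + true_sn2 * np.eye(40)
        L = np.linalg.cholesky(K)
        Y = L @ rng.standard_normal((40, 50))
        ts = TrainingSet(X, Y, NormalizationConstants(1.0, 1.0, 1.0))
        model = train(ts)
        assert model.lengthscale == pytest.approx(true_ell, rel=0.25)


class TestPrediction:
    def test_interpolates_training_subject_at_tiny_noise(self):
        cohort = make_cohort()
        ts = build_training_set(cohort)
        model = train(ts, init=(2.0, 10.0, 1e-8), optimize=False)
        pred = predict(model, cohort[2][0])
        assert np.allclose(pred.mean.value, cohort[2][1].value, atol=1e-3)

    def test_variance_smaller_at_training_input_than_far_away(self):
        cohort = make_cohort()
        model = train(build_training_set(cohort), init=(2.0, 10.0, 1e-6), optimize=False)
        near = predict(model, cohort[0][0])
        far = predict(model, make_idifs(scale=30.0))
        assert near.variance[0] <= far.variance[0]
        assert np.all(near.variance >= 0)

    def test_matches_dense_solve_oracle(self):
        """Conditional mean/variance equal brute-force matrix inversion."""
        cohort = make_cohort(n_subjects=5)
        ts = build_training_set(cohort)
        model = train(ts)
        test_idifs = make_idifs(scale=1.05, delay=0.5)
        pred = predict(model, test_idifs)
        # oracle: explicit inverse, same hyperparameters
        K = matern52(ts.X, ts.X, model.lengthscale, model.signal_var)
        Kinv = np.linalg.inv(K + (model.noise_var + 1e-10) * np.eye(5))
        x_star = normalize(test_idifs, ts.norm)[None, :]
        k_star = matern52(ts.X, x_star, model.lengthscale, model.signal_var)
        y_mean = ts.Y.mean(axis=0)
        mean_ref = y_mean + (k_star.T @ Kinv @ (ts.Y - y_mean)).ravel()
        var_ref = model.signal_var - (k_star.T @ Kinv @ k_star).item()
        assert np.allclose(pred.mean.value, mean_ref, rtol=1e-8, atol=1e-10)
        assert pred.variance[0] == pytest.approx(var_ref, rel=1e-8)

    def test_matches_sklearn_gp_cross_check(self):
        """Independent route: scikit-learn GPR with the same fixed kernel
        reproduces the conditional mean."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern

        cohort = make_cohort(n_subjects=6)
        ts = build_training_set(cohort)
        ell, sf2, sn2 = 1.5, 8.0, 0.05
        model = train(ts, init=(ell, sf2, sn2), optimize=False)
        test_idifs = make_idifs(scale=0.9, delay=-1.0)
        pred = predict(model, test_idifs)

        y_mean = ts.Y.mean(axis=0)
        gpr = GaussianProcessRegressor(
            kernel=ConstantKernel(sf2, "fixed") * Matern(ell, "fixed", nu=2.5),
            alpha=sn2,
            optimizer=None,
        )
        gpr.fit(ts.X, ts.Y - y_mean)
        ref = y_mean + gpr.predict(normalize(test_idifs, ts.norm)[None, :]).ravel()
        assert np.allclose(pred.mean.value, ref, rtol=1e-7, atol=1e-8)

    def test_predictions_invariant_to_training_permutation(self):
        cohort = make_cohort()
        test_idifs = make_idifs(scale=1.1)
        p1 = predict(train(build_training_set(cohort)), test_idifs)
        p2 = predict(train(build_training_set(cohort[::-1])), test_idifs)
        assert np.allclose(p1.mean.value, p2.mean.value, rtol=1e-6)

    def test_jitter_insensitive(self):
        cohort = make_cohort()
        ts = build_training_set(cohort)
        base = train(ts, init=(2.0, 10.0, 0.01), optimize=False)
        jit = train(ts, init=(2.0, 10.0, 0.01 + 1e-6 * 10.0), optimize=False)
        test_idifs = make_idifs(scale=1.1)
        a, b = predict(base, test_idifs), predict(jit, test_idifs)
        assert np.max(np.abs(a.mean.value - b.mean.value)) < 1e-3 * np.abs(a.mean.value).max()

    def test_grid_mismatch_rejected(self):
        model = train(build_training_set(make_cohort(n=40)))
        with pytest.raises(ValueError):
            predict(model, make_idifs(n=30))


class TestLeaveOneOut:
    def test_returns_one_prediction_per_subject(self):
        cohort = make_cohort(n_subjects=5)
        preds = loo_cross_validate(cohort)
        assert len(preds) == 5

    def test_duplicated_subject_predicted_by_its_twin(self):
        cohort = make_cohort(n_subjects=5)
        cohort.append(cohort[0])  # twin stays in every training fold
        preds = loo_cross_validate(cohort)
        err = np.abs(preds[0].mean.value - cohort[0][1].value).max()
        assert err < 0.05 * cohort[0][1].peak

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            loo_cross_validate(make_cohort(n_subjects=2))

    def test_phantom_cohort_heldout_curve_fidelity(self, phantom_cohort):
        """Held-out MLIF vs true local AIF: median per-subject r^2 > 0.8."""
        baseline, _, truth = phantom_cohort
        preds = loo_cross_validate([(r.idifs, r.aif) for r in baseline])
        from mlifpet.phantom import PhantomSubject

        r2 = []
        for rec, pred in zip(baseline, preds):
            subj = PhantomSubject(**truth[2 * rec.subject_id])
            true_aif = window_0_to_6min(generate_aif(subj))
            r2.append(np.corrcoef(pred.mean.value, true_aif.value)[0, 1] ** 2)
        assert np.median(r2) > 0.8
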