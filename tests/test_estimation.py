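import numpy as np
import pytest

from ctdynet import (
    CTFitOptions,
    CTModel,
    DTFitOptions,
    IrregularTimeSeries,
    ct_loglik,
    fit_ct_var,
    fit_dt_var,
    lagged_params,
    propagate_uncertainty,
    residual_cov,
    sample_ou_path,
)
from ctdynet.estimation import decode_ct_params, encode_ct_params
from ctdynet.synthetic_data import esm_schedule, random_stable_drift


def _scalar_model(a=-1.0, q=2.0):
    return CTModel(drift=np.array([[a]]), diffusion=np.array([[q]]))


class TestParameterCodec:
    def test_round_trip(self):
        A = random_stable_drift(3, seed=1)
        Q = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 0.5]])
        theta = encode_ct_params(A, Q)
        A2, Q2, mu = decode_ct_params(theta, 3)
        assert np.allclose(A2, A, atol=1e-12)
        assert np.allclose(Q2, Q, atol=1e-8)
        assert np.allclose(mu, 0.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode_ct_params(np.zeros(5), 2)


class TestCTLoglik:
    def test_single_pair_matches_scalar_gaussian_density(self):
        a, q, dt = -0.8, 1.5, 0.6
        y0, y1 = 0.4, -0.2
        data = IrregularTimeSeries(times=[0.0, dt], values=np.array([[y0], [y1]]))
        theta = encode_ct_params(np.array([[a]]), np.array([[q]]))
        # hand formula: y1 | y0 ~ N(e^{a dt} y0, q (1 - e^{2 a dt}) / (-2a))
        mean = np.exp(a * dt) * y0
        var = q * (1 - np.exp(2 * a * dt)) / (-2 * a)
        expected = -0.5 * (np.log(2 * np.pi * var) + (y1 - mean) ** 2 / var)
        assert ct_loglik(theta, data) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_time_origin(self):
        m = _scalar_model()
        times = np.array([0.0, 0.3, 1.1, 2.0, 5.7])
        ts = sample_ou_path(m, times, seed=4)
        theta = encode_ct_params(m.drift, m.diffusion)
        shifted = IrregularTimeSeries(times=times + 137.0, values=ts.values)
        assert ct_loglik(theta, ts) == pytest.approx(ct_loglik(theta, shifted), abs=1e-10)

    def test_unstable_drift_rejected_not_raised(self):
        data = IrregularTimeSeries(times=[0.0, 1.0], values=np.array([[0.1], [0.2]]))
        theta = encode_ct_params(np.array([[0.5]]), np.array([[1.0]]))
        assert ct_loglik(theta, data) == -np.inf

    def test_equal_interval_matches_dt_gaussian_likelihood(self):
        A = random_stable_drift(2, seed=8)
        Q = np.eye(2)
        m = CTModel(drift=A, diffusion=Q)
        dt = 0.9
        times = dt * np.arange(300.0)
        ts = sample_ou_path(m, times, seed=9)
        theta = encode_ct_params(A, Q)
        ll_ct = ct_loglik(theta, ts)
        phi = lagged_params(m, dt)
        psi = residual_cov(m, dt)
        resid = ts.values[1:] - ts.values[:-1] @ phi.T
        n = resid.shape[0]
        _, logdet = np.linalg.slogdet(psi)
        ll_dt = -0.5 * (n * (2 * np.log(2 * np.pi) + logdet)
                        + np.einsum("ki,ij,kj->", resid, np.linalg.inv(psi), resid))
        assert ll_ct == pytest.approx(ll_dt, abs=1e-8)

    def test_truth_dominates_perturbed_drift(self):
        # hours-scale drift: its dynamics are resolvable at ESM intervals
        A = np.array([[-0.6, 0.2], [0.3, -0.8]])
        m = CTModel(drift=A, diffusion=np.eye(2))
        wins = 0
        for seed in range(5):
            ts = sample_ou_path(m, esm_schedule(n_days=200, seed=seed), seed=seed + 50)
            good = ct_loglik(encode_ct_params(A, np.eye(2)), ts)
            Abad = A.copy()
            Abad[0, 1] += 0.5
            bad = ct_loglik(encode_ct_params(Abad, np.eye(2)), ts)
            wins += good > bad
        assert wins == 5


class TestFitCT:
    @pytest.fixture(scope="class")
    def small_fit(self):
        A = np.array([[-0.5, 0.25], [0.15, -0.9]])
        m = CTModel(drift=A, diffusion=np.eye(2))
        ts = sample_ou_path(m, esm_schedule(n_days=150, seed=61), seed=62)
        fit = fit_ct_var(ts, CTFitOptions(n_starts=2, seed=0))
        return m, ts, fit

    def test_recovers_drift_within_three_se(self, small_fit):
        m, _, fit = small_fit
        se = fit.se()[:4].reshape(2, 2)
        err = np.abs(fit.model.drift - m.drift)
        assert np.all(err < 3 * se)

    def test_converged_with_finite_loglik(self, small_fit):
        _, _, fit = small_fit
        assert fit.converged and np.isfinite(fit.loglik)
        assert fit.n_pairs > 0

    def test_information_grows_with_sample_size(self, small_fit):
        m, ts, fit_big = small_fit
        short = IrregularTimeSeries(times=ts.times[:200], values=ts.values[:200])
        fit_small = fit_ct_var(short, CTFitOptions(n_starts=1, seed=0))
        assert np.nanmean(fit_small.se()) > np.nanmean(fit_big.se())

    def test_too_few_pairs_rejected(self):
        data = IrregularTimeSeries(times=[0.0, 1.0, 2.0],
                                   values=np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError, match="pairs"):
            fit_ct_var(data)


class TestFitDT:
    def test_equal_interval_ols_recovery(self):
        rng = np.random.default_rng(70)
        phi = np.array([[0.5, 0.15], [-0.1, 0.4]])
        n = 2000
        y = np.zeros((n, 2))
        for k in range(1, n):
            y[k] = phi @ y[k - 1] + rng.normal(size=2)
        ts = IrregularTimeSeries(times=np.arange(float(n)), values=y)
        fit = fit_dt_var(ts)
        se = np.sqrt(np.diag(fit.vcov)).reshape(2, 3)[:, :2]
        assert np.all(np.abs(fit.model.lagged - phi) < 3 * se)

    def test_constant_column_is_rank_deficient(self):
        vals = np.column_stack([np.ones(30), np.random.default_rng(1).normal(size=30)])
        ts = IrregularTimeSeries(times=np.arange(30.0), values=vals)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_dt_var(ts, DTFitOptions(center=False))

    def test_mixed_intervals_blend_lagged_relations(self):
        # data alternating between short and long intervals: pooled OLS gives
        # a compromise that matches neither Phi(short) nor Phi(long)
        A = np.array([[-1.0, 0.0], [1.2, -1.0]])
        m = CTModel(drift=A, diffusion=np.eye(2))
        dts = np.tile([0.3, 3.0], 1500)  # equal counts: median interval 1.65
        times = np.concatenate([[0.0], np.cumsum(dts)])
        ts = sample_ou_path(m, times, seed=71)
        fit = fit_dt_var(ts)
        blend = fit.model.lagged[1, 0]
        short, long_ = lagged_params(m, 0.3)[1, 0], lagged_params(m, 3.0)[1, 0]
        lo, hi = sorted((short, long_))
        assert lo < blend < hi
        # and the blend is not the lagged matrix at the median interval
        med = lagged_params(m, float(np.median(np.diff(times))))[1, 0]
        assert abs(blend - med) > 0.05


class TestPropagateUncertainty:
    @pytest.fixture(scope="class")
    def fit(self):
        A = np.array([[-0.7, 0.3], [0.2, -0.6]])
        m = CTModel(drift=A, diffusion=np.eye(2))
        ts = sample_ou_path(m, esm_schedule(n_days=100, seed=81), seed=82)
        return fit_ct_var(ts, CTFitOptions(n_starts=1, seed=0))

    def test_zero_vcov_collapses_bands(self, fit):
        import dataclasses

        frozen = dataclasses.replace(fit, vcov=np.zeros_like(fit.vcov))
        bands = propagate_uncertainty(frozen, lambda th: th[:4], n_draws=50, seed=3)
        assert np.allclose(bands.lower, bands.point)
        assert np.allclose(bands.upper, bands.point)

    def test_same_seed_same_bands(self, fit):
        f = lambda model: np.array([model.drift[1, 0]])
        a = propagate_uncertainty(fit, f, n_draws=200, seed=11, pass_model=True)
        b = propagate_uncertainty(fit, f, n_draws=200, seed=11, pass_model=True)
        assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)

    def test_bands_widen_with_level(self, fit):
        f = lambda th: th[:2]
        wide = propagate_uncertainty(fit, f, n_draws=400, seed=5, level=0.99)
        narrow = propagate_uncertainty(fit, f, n_draws=400, seed=5, level=0.5)
        assert np.all(wide.upper - wide.lower >= narrow.upper - narrow.lower)

    def test_coverage_of_drift_entry(self):
        # scaled-down coverage study: 10 replications, 2 variables
        A = np.array([[-0.7, 0.3], [0.2, -0.6]])
        m = CTModel(drift=A, diffusion=np.eye(2))
        hits = 0
        for rep in range(10):
            ts = sample_ou_path(m, esm_schedule(n_days=140, seed=200 + rep), seed=300 + rep)
            fit = fit_ct_var(ts, CTFitOptions(n_starts=1, seed=rep))
            bands = propagate_uncertainty(
                fit, lambda model: np.array([model.drift[0, 1]]),
                n_draws=400, seed=rep, pass_model=True,
            )
            if bands.lower[0] <= A[0, 1] <= bands.upper[0]:
                hits += 1
        assert hits >= 8
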