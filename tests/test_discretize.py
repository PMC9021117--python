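import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdynet import (
    AliasingError,
    CTModel,
    DTModel,
    NonStationaryError,
    ct_to_dt,
    dt_to_ct,
    lagged_params,
    phi_curve,
    residual_cov,
    sign_switch_report,
    stationary_cov,
)
from ctdynet.synthetic_data import random_stable_drift


class TestLaggedParams:
    def test_decoupled_coordinates_scalar_exponentials(self):
        m = CTModel(drift=np.diag([-1.0, -2.0]), diffusion=np.eye(2))
        phi = lagged_params(m, 1.0)
        assert np.allclose(phi, np.diag([np.exp(-1.0), np.exp(-2.0)]), atol=1e-12)

    def test_zero_interval_is_identity(self, model_battery):
        for m in model_battery[:5]:
            assert np.array_equal(lagged_params(m, 0.0), np.eye(m.p))

    def test_nonfinite_interval_rejected(self):
        m = CTModel(drift=-np.eye(2), diffusion=np.eye(2))
        with pytest.raises(ValueError):
            lagged_params(m, np.nan)

    def test_halving_the_interval_squares_back(self, model_battery):
        for m in model_battery:
            full = lagged_params(m, 1.0)
            half = lagged_params(m, 0.5)
            assert np.max(np.abs(full - half @ half)) < 1e-10

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        s=st.floats(0.01, 5.0),
        t=st.floats(0.01, 5.0),
    )
    def test_semigroup_property(self, seed, s, t):
        A = random_stable_drift(3, seed=seed)
        lhs = lagged_params(A, s + t)
        rhs = lagged_params(A, s) @ lagged_params(A, t)
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_product_limit_oracle(self):
        A = random_stable_drift(4, seed=11)
        target = lagged_params(A, 1.0)
        errs = []
        for n in (100, 1000, 10_000):
            approx = np.linalg.matrix_power(np.eye(4) + A / n, n)
            errs.append(np.max(np.abs(approx - target)))
        assert errs[0] > errs[1] > errs[2]
        # error shrinks roughly like 1/n
        assert errs[0] / errs[1] == pytest.approx(10, rel=0.35)


class TestResidualCov:
    def test_scalar_closed_form(self):
        m = CTModel(drift=np.array([[-1.0]]), diffusion=np.array([[2.0]]))
        assert residual_cov(m, 1.0)[0, 0] == pytest.approx(1 - np.exp(-2.0), abs=1e-12)
        assert residual_cov(m, 0.0)[0, 0] == 0.0
        # dt -> infinity: stationary variance q / (-2a) = 1
        assert residual_cov(m, 50.0)[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_unstable_drift_rejected(self):
        m = CTModel(drift=np.array([[0.2]]), diffusion=np.array([[1.0]]))
        with pytest.raises(NonStationaryError):
            residual_cov(m, 1.0)

    def test_psd_and_loewner_monotone(self, model_battery):
        for m in model_battery[:8]:
            prev = np.zeros((m.p, m.p))
            for dt in (0.2, 0.5, 1.0, 2.0, 5.0):
                sig = residual_cov(m, dt)
                assert np.min(np.linalg.eigvalsh(sig)) >= -1e-10
                assert np.min(np.linalg.eigvalsh(sig - prev)) >= -1e-9
                prev = sig


class TestStationaryCov:
    def test_closed_form_identity_drift(self):
        m = CTModel(drift=-np.eye(3), diffusion=2.0 * np.eye(3))
        assert np.allclose(stationary_cov(m), np.eye(3), atol=1e-12)

    def test_defining_equation_residual(self):
        A = random_stable_drift(3, seed=21)
        Q = np.eye(3) + 0.2
        m = CTModel(drift=A, diffusion=Q)
        g = stationary_cov(m)
        assert np.max(np.abs(A @ g + g @ A.T + Q)) < 1e-9

    def test_residual_cov_limits_to_stationary(self):
        A = random_stable_drift(3, seed=22)
        m = CTModel(drift=A, diffusion=np.eye(3))
        horizon = 50.0 / np.max(np.abs(np.linalg.eigvals(A).real))
        assert np.allclose(residual_cov(m, horizon), stationary_cov(m), atol=1e-8)


def _real_eig_stable_drift(p, seed):
    """Stable drift with real eigenvalues: similarity transform of a diagonal."""
    rng = np.random.default_rng(seed)
    D = np.diag(-rng.uniform(0.3, 2.0, size=p))
    P = rng.normal(size=(p, p)) + 2 * np.eye(p)
    return P @ D @ np.linalg.inv(P)


class TestDTtoCT:
    def test_scalar_logarithm(self):
        m = DTModel(lagged=np.array([[0.5]]), interval=1.0, residual_cov=np.array([[1.0]]))
        ct = dt_to_ct(m)
        assert ct.drift[0, 0] == pytest.approx(np.log(0.5), abs=1e-12)

    def test_round_trip_recovers_drift(self):
        for seed in range(5):
            A = _real_eig_stable_drift(3, seed)
            m = CTModel(drift=A, diffusion=np.eye(3))
            dt_model = ct_to_dt(m, 0.7)
            back = dt_to_ct(dt_model)
            assert np.max(np.abs(back.drift - A)) < 1e-8
            # diffusion recovered through the discrete Lyapunov inversion
            assert np.max(np.abs(back.diffusion - np.eye(3))) < 1e-6

    def test_negative_autoregression_has_no_real_ct(self):
        m = DTModel(lagged=np.array([[-0.3]]), interval=1.0, residual_cov=np.array([[1.0]]))
        with pytest.raises(AliasingError, match="positive auto-regression"):
            dt_to_ct(m)

    def test_ct_to_dt_consistency(self, model_battery):
        m = model_battery[0]
        d = ct_to_dt(m, 1.3)
        assert np.allclose(d.lagged, lagged_params(m, 1.3))
        assert np.allclose(d.residual_cov, residual_cov(m, 1.3))


class TestPhiCurve:
    def test_single_zero_grid_point_is_identity(self, stress_model):
        pc = phi_curve(stress_model, np.array([0.0]))
        assert np.array_equal(pc.matrices[0], np.eye(4))

    def test_vanishes_for_long_intervals(self, model_battery):
        for m in model_battery[:5]:
            horizon = 50.0 / np.min(np.abs(np.linalg.eigvals(m.drift).real))
            phi = lagged_params(m, horizon)
            assert np.max(np.abs(phi)) < 1e-6

    def test_chain_entry_closed_form_and_peak(self):
        # A = [[-1, 0], [1.5, -1]]: phi_21(dt) = 1.5 dt e^{-dt}, peak at dt = 1
        m = CTModel(drift=np.array([[-1.0, 0.0], [1.5, -1.0]]), diffusion=np.eye(2))
        grid = np.round(np.arange(0.0, 3.0 + 1e-9, 0.05), 10)
        pc = phi_curve(m, grid)
        expected = 1.5 * grid * np.exp(-grid)
        assert np.max(np.abs(pc.entry(1, 0) - expected)) < 1e-10
        assert pc.peak_dt[1, 0] == pytest.approx(1.0, abs=0.051)

    def test_matches_pointwise_expm(self, stress_model):
        grid = np.array([0.1, 0.7, 2.3])
        pc = phi_curve(stress_model, grid)
        for k, dt in enumerate(grid):
            assert np.max(np.abs(pc.matrices[k] - lagged_params(stress_model, dt))) < 1e-10

    def test_empty_grid_rejected(self, stress_model):
        with pytest.raises(ValueError):
            phi_curve(stress_model, np.array([]))


class TestSignSwitchReport:
    def test_diagonal_drift_never_switches(self):
        m = CTModel(drift=np.diag([-1.0, -2.0]), diffusion=np.eye(2))
        pc = phi_curve(m)
        assert sign_switch_report(pc) == []

    def test_chain_entry_stays_nonnegative(self):
        m = CTModel(drift=np.array([[-1.0, 0.0], [1.5, -1.0]]), diffusion=np.eye(2))
        report = sign_switch_report(phi_curve(m))
        assert [r for r in report if (r.to_var, r.from_var) == (1, 0)] == []

    def test_negative_direct_positive_indirect_switches_once(self, stress_model):
        # Anxiety -> Discomfort: direct effect is strongly negative, the
        # indirect route through Self-Consciousness is positive, so the
        # lagged entry crosses zero exactly once over the default grid
        report = sign_switch_report(phi_curve(stress_model))
        hits = [r for r in report if (r.to_var, r.from_var) == (3, 1)]
        assert len(hits) == 1
        lo, hi = hits[0].bracket
        assert hi - lo <= 1e-4
        # the refined bracket actually brackets a sign change
        assert lagged_params(stress_model, lo)[3, 1] * lagged_params(stress_model, hi)[3, 1] <= 0
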