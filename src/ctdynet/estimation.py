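"""Maximum-likelihood estimation of CT-VAR models from irregularly sampled
series, OLS estimation of the DT-VAR baseline, and uncertainty propagation.

The CT likelihood conditions on the first observation and factors over
consecutive complete pairs: each transition contributes the Gaussian log
density of ``Y(t_tau)`` with mean ``e^{A dt_tau} Y(t_{tau-1})`` and
covariance ``Sigma(dt_tau)``, so unequal intervals are handled exactly and
long (overnight) gaps are naturally downweighted because ``Phi(dt)``
approaches zero. Parameters are unconstrained: the drift enters as p^2 free
reals and the diffusion through a Cholesky factor with log-transformed
diagonal. Unstable trial drifts are rejected through the likelihood (the
stationary covariance does not exist there), not by hard constraints, so
Hessian-based standard errors are undistorted at the optimum.

The DT baseline deliberately pools all consecutive pairs regardless of the
elapsed interval — the common (flawed) practice the CT model corrects — and
records the median observed interval as its nominal lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize

from .model_core import CTModel, DTModel, FitResult, IrregularTimeSeries

__all__ = [
    "CTFitOptions",
    "DTFitOptions",
    "ct_loglik",
    "fit_ct_var",
    "fit_dt_var",
    "propagate_uncertainty",
    "Bands",
    "encode_ct_params",
    "decode_ct_params",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter vector <-> (A, Q)

def _n_params(p: int, estimate_means: bool) -> int:
    return p * p + p * (p + 1) // 2 + (p if estimate_means else 0)


def encode_ct_params(drift: np.ndarray, diffusion: np.ndarray,
                     means: np.ndarray | None = None) -> np.ndarray:
    """Pack (A, Q[, mu]) into the unconstrained vector used by the optimizer."""
    p = drift.shape[0]
    jitter = 1e-10 * max(1.0, float(np.max(np.abs(diffusion))))
    L = np.linalg.cholesky(diffusion + jitter * np.eye(p))
    tril = []
    for i in range(p):
        for j in range(i + 1):
            tril.append(np.log(L[i, j]) if i == j else L[i, j])
    parts = [drift.ravel(), np.array(tril)]
    if means is not None:
        parts.append(np.asarray(means, dtype=float))
    return np.concatenate(parts)


def decode_ct_params(theta: np.ndarray, p: int,
                     estimate_means: bool = False):
    """Unpack the optimizer vector into (A, Q, mu)."""
    theta = np.asarray(theta, dtype=float)
    if theta.size != _n_params(p, estimate_means):
        raise ValueError(
            f"parameter vector has length {theta.size}, expected {_n_params(p, estimate_means)}"
        )
    A = theta[: p * p].reshape(p, p)
    L = np.zeros((p, p))
    k = p * p
    for i in range(p):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    Q = L @ L.T
    mu = theta[k: k + p] if estimate_means else np.zeros(p)
    return A, Q, mu


# ---------------------------------------------------------------------------
# likelihood

def _pairs_of(data: IrregularTimeSeries):
    dts, y0, y1 = data.complete_pairs()
    if dts.size == 0:
        raise ValueError("no usable consecutive pairs (all broken by missingness)")
    return dts, y0, y1


def _transition_mats(A: np.ndarray, dts: np.ndarray):
    """e^{A dt} for every dt at once via one eigendecomposition of A.

    Falls back to per-interval scipy expm when the eigenvector matrix is too
    ill-conditioned (nearly defective drift).
    """
    try:
        lam, V = np.linalg.eig(A)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        Vinv = np.linalg.inv(V)
        expd = np.exp(np.outer(dts, lam))
        return np.real((V[None, :, :] * expd[:, None, :]) @ Vinv)
    return np.stack([sla.expm(A * dt) for dt in dts])


def _loglik_core(A: np.ndarray, Q: np.ndarray, mu: np.ndarray,
                 dts: np.ndarray, y0: np.ndarray, y1: np.ndarray) -> float:
    p = A.shape[0]
    # one eigendecomposition yields the stationary covariance (Lyapunov
    # solution in the eigenbasis) and every transition matrix at once
    phis = None
    try:
        lam, V = np.linalg.eig(A)
    except np.linalg.LinAlgError:
        return -np.inf
    lam_max = float(np.max(lam.real))
    if not np.isfinite(lam_max) or lam_max >= 0:
        return -np.inf
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        Vinv = None
    if Vinv is not None and np.abs(V).sum(0).max() * np.abs(Vinv).sum(0).max() < 1e8:
        M = Vinv @ Q @ Vinv.conj().T
        X = -M / (lam[:, None] + lam.conj()[None, :])
        gamma = np.real(V @ X @ V.conj().T)
        expd = np.exp(dts[:, None] * lam[None, :])
        n = dts.size
        phis = np.real(
            ((V[None, :, :] * expd[:, None, :]).reshape(n * p, p) @ Vinv).reshape(n, p, p)
        )
    else:
        try:
            gamma = sla.solve_continuous_lyapunov(A, -Q)
        except Exception:
            return -np.inf
    gamma = 0.5 * (gamma + gamma.T)
    if phis is None:
        phis = _transition_mats(A, dts)
    n = dts.size
    tmp = (phis.reshape(n * p, p) @ gamma).reshape(n, p, p)
    sigs = gamma[None, :, :] - tmp @ np.transpose(phis, (0, 2, 1))
    sigs = 0.5 * (sigs + np.transpose(sigs, (0, 2, 1)))
    sigs += 1e-12 * np.eye(p)[None]
    resid = (y1 - mu) - (phis @ (y0 - mu)[:, :, None])[:, :, 0]
    try:
        chol = np.linalg.cholesky(sigs)
    except np.linalg.LinAlgError:
        return -np.inf
    z = np.linalg.solve(chol, resid[:, :, None])[:, :, 0]
    logdets = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    n = dts.size
    ll = -0.5 * (n * p * _LOG2PI + logdets.sum() + np.sum(z * z))
    return float(ll)


def ct_loglik(params: np.ndarray, data: IrregularTimeSeries,
              estimate_means: bool = False) -> float:
    """CT-VAR log likelihood of an unconstrained parameter vector.

    Sums the exact Gaussian transition density over consecutive fully
    observed pairs, conditioning on the first observation. Returns -inf
    (a rejected point, not an exception) when the drift is unstable or the
    implied transition covariance is not positive definite.
    """
    A, Q, mu = decode_ct_params(params, data.p, estimate_means)
    dts, y0, y1 = _pairs_of(data)
    return _loglik_core(A, Q, mu, dts, y0, y1)


# ---------------------------------------------------------------------------
# CT fit

@dataclass
class CTFitOptions:
    n_starts: int = 10
    seed: int = 0
    center: bool = True
    estimate_means: bool = False
    maxiter: int = 500
    #: iteration cap for the exploratory (non-warm) starts; the best start is
    #: re-polished with the full budget
    quick_maxiter: int = 60
    compute_vcov: bool = True
    start_scale: float = 0.3
    min_pairs: int | None = None  # default p(p+1)


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    k = x.size
    H = np.empty((k, k))
    hs = h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = hs[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / hs[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = hs[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * hs[i] * hs[j])
    return H


def fit_ct_var(data: IrregularTimeSeries, options: CTFitOptions | None = None) -> FitResult:
    """Maximum-likelihood CT-VAR fit by multi-start quasi-Newton optimization.

    The first start is warm: the principal matrix logarithm of the DT-OLS
    lagged matrix at the median interval, when that logarithm exists.
    Remaining starts are random perturbations of it; they get a short
    exploratory run and the best point is polished with the full iteration
    budget. The covariance of the estimates is the inverse numerical Hessian
    of the negative log likelihood.
    """
    opts = options or CTFitOptions()
    p = data.p
    work = data
    col_means = np.zeros(p)
    if opts.center and not opts.estimate_means:
        col_means = np.nanmean(data.values, axis=0)
        work = IrregularTimeSeries(
            times=data.times, values=data.values - col_means, labels=data.labels
        )
    dts, y0, y1 = _pairs_of(work)
    min_pairs = opts.min_pairs if opts.min_pairs is not None else p * (p + 1)
    if dts.size < min_pairs:
        raise ValueError(
            f"need at least {min_pairs} usable pairs for a p={p} model, have {dts.size}"
        )

    def neg_ll(theta: np.ndarray) -> float:
        A, Q, mu = decode_ct_params(theta, p, opts.estimate_means)
        ll = _loglik_core(A, Q, mu, dts, y0, y1)
        if np.isfinite(ll):
            return -ll
        lam_max = float(np.max(np.linalg.eigvals(A).real))
        return 1e6 * (1.0 + max(lam_max, 0.0)) ** 2

    # warm start from the DT-OLS fit via the matrix logarithm
    rng = np.random.default_rng(opts.seed)
    med_dt = float(np.median(dts))
    theta_warm = None
    try:
        dt_fit = fit_dt_var(work, DTFitOptions(center=False))
        phi = dt_fit.model.lagged
        eigs = np.linalg.eigvals(phi)
        if np.all((eigs.real > 0) | (np.abs(eigs.imag) > 1e-12)) and np.max(np.abs(eigs)) < 1.0:
            A0 = np.real(sla.logm(phi)) / med_dt
            if np.max(np.linalg.eigvals(A0).real) < 0:
                gamma0 = sla.solve_discrete_lyapunov(phi, dt_fit.model.residual_cov)
                Q0 = -(A0 @ gamma0 + gamma0 @ A0.T)
                Q0 = 0.5 * (Q0 + Q0.T)
                w, v = np.linalg.eigh(Q0)
                Q0 = (v * np.clip(w, 1e-8, None)) @ v.T
                theta_warm = encode_ct_params(
                    A0, Q0, np.zeros(p) if opts.estimate_means else None
                )
    except Exception:
        theta_warm = None
    if theta_warm is None:
        samp_cov = np.cov(np.vstack([y0, y1]).T)
        theta_warm = encode_ct_params(
            -np.eye(p) / max(med_dt, 1e-6),
            2.0 * np.atleast_2d(samp_cov) / max(med_dt, 1e-6),
            np.zeros(p) if opts.estimate_means else None,
        )

    starts = [theta_warm]
    for _ in range(max(0, opts.n_starts - 1)):
        starts.append(theta_warm + rng.normal(scale=opts.start_scale, size=theta_warm.size))

    per_start = []
    best = None
    best_start = 0
    for s, x0 in enumerate(starts):
        cap = opts.maxiter if s == 0 else opts.quick_maxiter
        try:
            res = minimize(neg_ll, x0, method="L-BFGS-B",
                           options={"maxiter": cap, "ftol": 1e-8, "gtol": 1e-4})
            per_start.append({"start": s, "fun": float(res.fun), "success": bool(res.success)})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best, best_start = res, s
        except Exception as exc:  # pragma: no cover - defensive
            per_start.append({"start": s, "error": str(exc)})
    if best is None:
        raise RuntimeError(f"all optimization starts failed: {per_start}")
    if best_start != 0:  # the winner only had the short exploratory budget
        res = minimize(neg_ll, best.x, method="L-BFGS-B",
                       options={"maxiter": opts.maxiter, "ftol": 1e-8, "gtol": 1e-4})
        if np.isfinite(res.fun) and res.fun <= best.fun:
            best = res

    theta_hat = best.x
    A_hat, Q_hat, mu_hat = decode_ct_params(theta_hat, p, opts.estimate_means)
    equilibrium = mu_hat + (col_means if opts.center and not opts.estimate_means else 0.0)
    model = CTModel(drift=A_hat, diffusion=Q_hat, equilibrium=equilibrium, labels=data.labels)
    if not model.is_stable:
        warnings.warn("fitted drift matrix is not stable", stacklevel=2)

    k = theta_hat.size
    vcov = np.full((k, k), np.nan)
    if opts.compute_vcov:
        H = _numerical_hessian(neg_ll, theta_hat)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
        vcov = 0.5 * (vcov + vcov.T)
    else:
        vcov = np.zeros((k, k))

    def decode(theta: np.ndarray) -> CTModel:
        A, Q, mu = decode_ct_params(theta, p, opts.estimate_means)
        w, v = np.linalg.eigh(0.5 * (Q + Q.T))
        Q = (v * np.clip(w, 0.0, None)) @ v.T
        return CTModel(drift=A, diffusion=Q, equilibrium=mu + equilibrium - mu_hat,
                       labels=data.labels)

    return FitResult(
        model=model,
        param_vector=theta_hat,
        vcov=vcov,
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_pairs=int(dts.size),
        details={
            "per_start": per_start,
            "decode": decode,
            "centered": opts.center,
            "column_means": col_means,
            "median_interval": med_dt,
        },
    )


# ---------------------------------------------------------------------------
# DT baseline

@dataclass
class DTFitOptions:
    center: bool = True
    intercept: bool = True


def fit_dt_var(data: IrregularTimeSeries, options: DTFitOptions | None = None) -> FitResult:
    """Per-equation OLS fit of the lag-one VAR, pooling all consecutive pairs
    regardless of their elapsed interval.

    When intervals are unequal, the estimate is a blend of the lagged
    relationships at the different intervals present in the data; the median
    interval is recorded as the model's nominal lag.
    """
    opts = options or DTFitOptions()
    p = data.p
    work = data
    if opts.center:
        work = IrregularTimeSeries(
            times=data.times,
            values=data.values - np.nanmean(data.values, axis=0),
            labels=data.labels,
        )
    dts, y0, y1 = _pairs_of(work)
    n = dts.size
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} usable pairs, have {n}")
    X = np.column_stack([y0, np.ones(n)]) if opts.intercept else y0
    q = X.shape[1]
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("regressor matrix is rank deficient (constant or collinear columns)")
    coef, _, _, _ = np.linalg.lstsq(X, y1, rcond=None)
    pred = X @ coef
    resid = y1 - pred
    dof = max(n - q, 1)
    psi = resid.T @ resid / dof
    phi = coef[:p, :].T
    c = coef[p, :] if opts.intercept else np.zeros(p)

    # classical per-equation OLS vcov; regressors are shared across equations
    xtx_inv = np.linalg.inv(X.T @ X)
    s2 = np.diag(psi)  # per-equation residual variance
    k = p * q
    vcov = np.zeros((k, k))
    for j in range(p):
        vcov[j * q:(j + 1) * q, j * q:(j + 1) * q] = s2[j] * xtx_inv
    param_vector = coef.T.ravel()  # equation-major: [phi_j1..phi_jp, c_j] per j

    model = DTModel(
        lagged=phi,
        interval=float(np.median(dts)),
        residual_cov=0.5 * (psi + psi.T),
        intercept=c,
        labels=data.labels,
    )
    # Gaussian log likelihood of the OLS solution, for comparability
    sign, logdet = np.linalg.slogdet(psi)
    ll = -0.5 * n * (p * _LOG2PI + logdet) - 0.5 * np.trace(
        resid @ np.linalg.solve(psi, resid.T)
    ) if sign > 0 else np.nan
    return FitResult(
        model=model,
        param_vector=param_vector,
        vcov=vcov,
        loglik=float(ll) if np.isfinite(ll) else np.nan,
        converged=True,
        n_pairs=int(n),
        details={"intercept": opts.intercept, "centered": opts.center},
    )


# ---------------------------------------------------------------------------
# uncertainty propagation

@dataclass
class Bands:
    """Pointwise percentile bands of a functional of the fitted parameters."""

    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95
    draws: int = 0


def propagate_uncertainty(fit: FitResult, functional, n_draws: int = 1000,
                          seed: int = 0, level: float = 0.95,
                          pass_model: bool = False) -> Bands:
    """Resample parameter vectors from the Gaussian likelihood approximation
    N(theta_hat, vcov) and map each through a functional, returning pointwise
    percentile bands.

    ``functional`` receives the raw parameter vector, or the decoded model
    when ``pass_model=True`` and the fit knows how to decode (CT fits do).
    Fixed seed implies identical bands. A non-PSD vcov is repaired to the
    nearest PSD matrix with a warning.
    """
    if not fit.converged:
        raise ValueError("cannot propagate uncertainty from a non-converged fit")
    if not np.all(np.isfinite(fit.vcov)):
        raise ValueError("fit has no finite vcov (was compute_vcov disabled?)")
    vcov = fit.vcov
    w, v = np.linalg.eigh(0.5 * (vcov + vcov.T))
    if w.min() < -1e-10 * max(1.0, w.max()):
        warnings.warn("vcov is not PSD; repairing by eigenvalue clipping", stacklevel=2)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)

    rng = np.random.default_rng(seed)

    def apply(theta):
        if pass_model and "decode" in fit.details:
            return np.asarray(functional(fit.details["decode"](theta)), dtype=float)
        return np.asarray(functional(theta), dtype=float)

    point = apply(fit.param_vector)
    draws_out = np.empty((n_draws,) + point.shape)
    for d in range(n_draws):
        theta = fit.param_vector + root @ rng.standard_normal(fit.param_vector.size)
        draws_out[d] = apply(theta)
    alpha = 0.5 * (1.0 - level)
    lower = np.quantile(draws_out, alpha, axis=0)
    upper = np.quantile(draws_out, 1.0 - alpha, axis=0)
    return Bands(point=point, lower=lower, upper=upper, level=level, draws=n_draws)
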