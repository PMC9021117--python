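"""Exact mappings between the continuous-time and discrete-time representations.

The lagged matrix implied by a drift matrix ``A`` at interval ``dt`` is the
matrix exponential ``Phi(dt) = e^{A dt}``; the residual covariance of the
exact discretization is ``Sigma(dt) = Gamma - e^{A dt} Gamma e^{A' dt}`` with
``Gamma`` the stationary covariance solving the continuous Lyapunov equation
``A Gamma + Gamma A' + Q = 0``. The inverse map (matrix logarithm) exists only
for lagged matrices whose eigenvalues avoid the closed negative real axis —
the positive-auto-regression regime assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla

from .model_core import CTModel, DTModel, NonStationaryError, dt_equilibrium

__all__ = [
    "PhiCurve",
    "lagged_params",
    "residual_cov",
    "stationary_cov",
    "transition_cov",
    "dt_to_ct",
    "ct_to_dt",
    "phi_curve",
    "sign_switch_report",
    "AliasingError",
    "default_grid",
]

#: default time-interval grid: 0 to 5 time units in steps of 0.05
DEFAULT_TMAX = 5.0
DEFAULT_STEP = 0.05


def default_grid(tmax: float = DEFAULT_TMAX, step: float = DEFAULT_STEP) -> np.ndarray:
    n = int(round(tmax / step))
    return np.linspace(0.0, n * step, n + 1)


class AliasingError(ValueError):
    """The lagged matrix has no real CT representation on the principal branch."""


def _drift_of(model) -> np.ndarray:
    if isinstance(model, CTModel):
        return model.drift
    return np.asarray(model, dtype=float)


def lagged_params(model: CTModel | np.ndarray, dt: float) -> np.ndarray:
    """Lagged-parameter matrix Phi(dt) = e^{A dt} implied by the drift matrix.

    ``dt = 0`` returns the identity exactly.
    """
    A = _drift_of(model)
    dt = float(dt)
    if not np.isfinite(dt) or dt < 0:
        raise ValueError(f"dt must be a finite nonnegative real, got {dt!r}")
    if dt == 0.0:
        return np.eye(A.shape[0])
    return sla.expm(A * dt)


def stationary_cov(model: CTModel) -> np.ndarray:
    """Stationary covariance Gamma of the OU process: A Gamma + Gamma A' = -Q."""
    if not model.is_stable:
        raise NonStationaryError("drift is not stable; stationary covariance undefined")
    gamma = sla.solve_continuous_lyapunov(model.drift, -model.diffusion)
    return 0.5 * (gamma + gamma.T)


def residual_cov(model: CTModel, dt: float) -> np.ndarray:
    """Exact-discretization residual covariance Sigma(dt).

    Zero at dt=0; approaches the stationary covariance Gamma as dt grows.
    """
    dt = float(dt)
    if not np.isfinite(dt) or dt < 0:
        raise ValueError(f"dt must be a finite nonnegative real, got {dt!r}")
    gamma = stationary_cov(model)
    if dt == 0.0:
        return np.zeros_like(gamma)
    phi = lagged_params(model, dt)
    sig = gamma - phi @ gamma @ phi.T
    return 0.5 * (sig + sig.T)


def transition_cov(drift: np.ndarray, diffusion: np.ndarray, dt: float) -> np.ndarray:
    """Covariance of the exact transition over dt via the Van Loan integral.

    Unlike :func:`residual_cov` this does not require a stable drift: it
    evaluates ``int_0^dt e^{A s} Q e^{A' s} ds`` directly from a block matrix
    exponential.
    """
    p = drift.shape[0]
    M = np.zeros((2 * p, 2 * p))
    M[:p, :p] = drift
    M[:p, p:] = diffusion
    M[p:, p:] = -drift.T
    F = sla.expm(M * dt)
    sig = F[:p, p:] @ F[:p, :p].T
    return 0.5 * (sig + sig.T)


def ct_to_dt(model: CTModel, dt: float) -> DTModel:
    """Exact DT-VAR representation of a stable CT model at interval dt."""
    return DTModel(
        lagged=lagged_params(model, dt),
        interval=dt,
        residual_cov=residual_cov(model, dt),
        intercept=(np.eye(model.p) - lagged_params(model, dt)) @ model.equilibrium,
        labels=model.labels,
    )


def dt_to_ct(model: DTModel, imag_tol: float = 1e-8) -> CTModel:
    """Recover the CT model whose exact discretization at ``model.interval``
    is the given DT-VAR, via the principal matrix logarithm.

    Raises
    ------
    AliasingError
        If the lagged matrix has an eigenvalue on the closed negative real
        axis (no real logarithm: the DT model exhibits negative
        auto-regression), or if the principal logarithm has an imaginary
        residual above tolerance (the drift is aliased: several real drifts
        are consistent with this lagged matrix).
    """
    phi = model.lagged
    eigs = np.linalg.eigvals(phi)
    on_negative_axis = (eigs.real <= 0) & (np.abs(eigs.imag) <= 1e-12 * max(1.0, np.max(np.abs(eigs))))
    if np.any(on_negative_axis) or np.any(np.abs(eigs) < 1e-300):
        raise AliasingError(
            "lagged matrix has a real eigenvalue <= 0: no real CT representation "
            "(positive auto-regression violated)"
        )
    logphi = sla.logm(phi)
    imag_resid = float(np.max(np.abs(np.imag(logphi))))
    if imag_resid > imag_tol:
        raise AliasingError(
            f"principal matrix logarithm has imaginary residual {imag_resid:.2e}; "
            "the drift matrix is aliased (multiple CT models consistent with this "
            "lagged matrix)"
        )
    A = np.real(logphi) / model.interval
    # recover Q from Psi: Gamma solves the discrete Lyapunov equation
    # Gamma = Phi Gamma Phi' + Psi, then Q = -(A Gamma + Gamma A').
    if np.max(np.abs(model.residual_cov)) > 0 and model.is_stationary:
        gamma = sla.solve_discrete_lyapunov(phi, model.residual_cov)
        q = -(A @ gamma + gamma @ A.T)
        q = 0.5 * (q + q.T)
        # numerical PSD repair at roundoff scale
        w, v = np.linalg.eigh(q)
        w = np.clip(w, 0.0, None)
        q = (v * w) @ v.T
    else:
        q = np.zeros_like(A)
    equilibrium = dt_equilibrium(model) if model.is_stationary else np.zeros(model.p)
    return CTModel(drift=A, diffusion=q, equilibrium=equilibrium, labels=model.labels)


@dataclass
class PhiCurve:
    """Lagged-parameter matrices over a grid of time-intervals.

    ``matrices[k]`` is Phi(grid[k]). ``peak_dt[j, i]`` records the grid dt at
    which entry (j, i) attains its maximum absolute value, and ``drift`` keeps
    the generating drift so sign switches can be refined off-grid.
    """

    grid: np.ndarray
    matrices: np.ndarray  # |grid| x p x p
    labels: Sequence[str]
    drift: np.ndarray | None = None
    peak_dt: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1)
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.shape[0] != self.grid.shape[0]:
            raise ValueError("one matrix per grid point required")
        self.labels = tuple(str(s) for s in self.labels)
        self.peak_dt = self.grid[np.argmax(np.abs(self.matrices), axis=0)]

    @property
    def p(self) -> int:
        return self.matrices.shape[1]

    def entry(self, to_var: int, from_var: int) -> np.ndarray:
        return self.matrices[:, to_var, from_var]

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, dt in enumerate(self.grid):
            for j in range(self.p):
                for i in range(self.p):
                    rows.append((dt, self.labels[i], self.labels[j], self.matrices[k, j, i]))
        return pd.DataFrame(rows, columns=["dt", "from_label", "to_label", "value"])


def phi_curve(model: CTModel, grid: np.ndarray | None = None) -> PhiCurve:
    """Evaluate Phi(dt) on a grid of time-intervals."""
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float).reshape(-1)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing and nonnegative")
    A = model.drift
    mats = np.empty((grid.size, A.shape[0], A.shape[0]))
    # eigendecomposition route: one decomposition serves every grid point
    try:
        lam, V = np.linalg.eig(A)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        expd = np.exp(np.outer(grid, lam))  # |grid| x p
        mats = np.real(np.einsum("ij,kj,jl->kil", V, expd, Vinv))
        mats[grid == 0.0] = np.eye(A.shape[0])
    else:
        for k, dt in enumerate(grid):
            mats[k] = lagged_params(A, dt)
    return PhiCurve(grid=grid, matrices=mats, labels=model.labels, drift=A.copy())


@dataclass
class SignSwitch:
    to_var: int
    from_var: int
    bracket: tuple[float, float]


def sign_switch_report(curve: PhiCurve, tol: float = 1e-4) -> list[SignSwitch]:
    """Report every grid-adjacent sign change of every Phi(dt) entry.

    Each switch is refined by bisection (when the generating drift is stored
    on the curve) to a bracket of width ``tol`` in dt; otherwise the grid
    bracket is returned as-is. Entries touching exact zero without crossing
    are not reported.
    """
    if curve.grid.size < 2:
        raise ValueError("curve needs at least 2 grid points")
    report: list[SignSwitch] = []
    g = curve.grid
    for j in range(curve.p):
        for i in range(curve.p):
            vals = curve.matrices[:, j, i]
            s = np.sign(vals)
            for k in range(len(g) - 1):
                if s[k] != 0 and s[k + 1] != 0 and s[k] != s[k + 1]:
                    lo, hi = float(g[k]), float(g[k + 1])
                    if curve.drift is not None:
                        f = lambda t: lagged_params(curve.drift, t)[j, i]
                        flo = f(lo)
                        while hi - lo > tol:
                            mid = 0.5 * (lo + hi)
                            fm = f(mid)
                            if np.sign(fm) == np.sign(flo):
                                lo, flo = mid, fm
                            else:
                                hi = mid
                    report.append(SignSwitch(to_var=j, from_var=i, bracket=(lo, hi)))
    return report
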