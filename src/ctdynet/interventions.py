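"""Pulse and press do-interventions on continuous-time network models.

Trajectories are *expected values* of the intervened system (the Wiener input
averages out of a linear model), so a pulse trajectory is simply
``e^{A t} y0`` with ``y0`` carrying the do-assignment, and a press trajectory
follows the free-subsystem dynamics toward a new equilibrium while the
pressed variables are clamped.

Every closed-form trajectory also has a ``method="rk4"`` route — a classical
fixed-step 4th-order integration of the clamped differential equation with
step halving — which serves as an independent numerical oracle for the
matrix-exponential computations elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .model_core import CTModel, InterventionSpec

__all__ = [
    "TrajectorySet",
    "pulse_trajectory",
    "press_trajectory",
    "press_equilibrium",
    "press_stability",
    "clamped_trajectory",
    "PressStability",
]


@dataclass
class TrajectorySet:
    """Expected trajectories of all variables under an intervention."""

    times: np.ndarray
    states: np.ndarray  # |times| x p
    spec: InterventionSpec
    labels: tuple[str, ...]

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, t in enumerate(self.times):
            for j, lab in enumerate(self.labels):
                rows.append((t, lab, self.states[k, j]))
        return pd.DataFrame(rows, columns=["t", "node", "value"])


def _check_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float).reshape(-1)
    if g.size == 0 or g[0] != 0.0 or np.any(np.diff(g) <= 0):
        raise ValueError("trajectory grid must start at 0 and be strictly increasing")
    return g


def _rk4_clamped(A: np.ndarray, y0: np.ndarray, grid: np.ndarray,
                 clamp_idx: np.ndarray, clamp_vals: np.ndarray,
                 tol: float = 1e-8, h0: float = 1e-2, max_halvings: int = 8) -> np.ndarray:
    """Fixed-step RK4 of dy/dt = A y with components `clamp_idx` held fixed.

    The step is halved until two successive answers agree to ``tol`` in sup
    norm. Used as the numerical oracle for closed-form trajectories.
    """

    def deriv(y):
        d = A @ y
        d[clamp_idx] = 0.0
        return d

    def run(h):
        out = np.empty((grid.size, y0.size))
        y = y0.copy()
        y[clamp_idx] = clamp_vals
        out[0] = y
        t = 0.0
        for k in range(1, grid.size):
            target = grid[k]
            while t < target - 1e-14:
                step = min(h, target - t)
                k1 = deriv(y)
                k2 = deriv(y + 0.5 * step * k1)
                k3 = deriv(y + 0.5 * step * k2)
                k4 = deriv(y + step * k3)
                y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                y[clamp_idx] = clamp_vals
                t += step
            out[k] = y
        return out

    h = h0
    prev = run(h)
    for _ in range(max_halvings):
        h *= 0.5
        cur = run(h)
        if np.max(np.abs(cur - prev)) < tol:
            return cur
        prev = cur
    return prev


def pulse_trajectory(model: CTModel, spec: InterventionSpec, grid,
                     method: str = "exact") -> TrajectorySet:
    """Expected trajectory after an instantaneous do-assignment at t=0.

    All non-target variables start at equilibrium (0, centered convention);
    for a stable model every component decays back to rest.
    """
    if spec.mode != "pulse":
        raise ValueError("spec must be a pulse intervention")
    grid = _check_grid(grid)
    import warnings

    if not model.is_stable:
        warnings.warn("model is unstable; pulse trajectories diverge", stacklevel=2)
    y0 = np.zeros(model.p)
    y0[list(spec.targets)] = spec.values
    if method == "exact":
        states = np.stack([sla.expm(model.drift * t) @ y0 for t in grid])
    elif method == "rk4":
        states = _rk4_clamped(model.drift, y0, grid, np.array([], dtype=int), np.array([]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrajectorySet(times=grid, states=states, spec=spec, labels=model.labels)


def _partition(p: int, targets: tuple[int, ...]):
    S = np.array(sorted(targets), dtype=int)
    free = np.array([i for i in range(p) if i not in set(targets)], dtype=int)
    return S, free


def press_equilibrium(model: CTModel, targets, values) -> np.ndarray:
    """New equilibrium when the targets are held fixed indefinitely.

    The free components settle at ``-A_ff^{-1} A_fs v``: the point where their
    rate of change under the clamped inputs is zero. Pressing at the old
    equilibrium value (0) produces no displacement at all.
    """
    targets = tuple(model.index(t) for t in np.atleast_1d(targets))
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if len(values) != len(targets):
        raise ValueError("one value per pressed target required")
    S, free = _partition(model.p, targets)
    order = np.argsort(np.asarray(targets))
    v = values[order]
    out = np.zeros(model.p)
    out[S] = v
    if free.size:
        Aff = model.drift[np.ix_(free, free)]
        Afs = model.drift[np.ix_(free, S)]
        try:
            out[free] = np.linalg.solve(Aff, -Afs @ v)
        except np.linalg.LinAlgError:
            eigs = np.linalg.eigvals(Aff)
            raise ValueError(
                f"free-subsystem drift is singular (eigenvalues {eigs}); "
                "press equilibrium undefined"
            )
    return out


@dataclass
class PressStability:
    eigenvalues: np.ndarray
    stable: bool


def press_stability(model: CTModel, targets) -> PressStability:
    """Stability of the free subsystem under an indefinite press.

    Pressing can destabilize an otherwise stable system (and vice versa):
    the eigenvalues of the free-subsystem block A_ff, not of A, govern
    whether the unpressed variables settle.
    """
    targets = tuple(model.index(t) for t in np.atleast_1d(targets))
    if len(targets) == 0:
        raise ValueError("press target set must be nonempty")
    if len(set(targets)) >= model.p:
        raise ValueError("pressing all nodes leaves no free subsystem")
    _, free = _partition(model.p, targets)
    eigs = np.linalg.eigvals(model.drift[np.ix_(free, free)])
    return PressStability(eigenvalues=eigs, stable=bool(np.all(eigs.real < 0)))


def press_trajectory(model: CTModel, spec: InterventionSpec, grid,
                     init: np.ndarray | None = None,
                     method: str = "exact") -> TrajectorySet:
    """Expected trajectory under a press starting at t=0.

    The pressed components are constant at their set values over the press
    window; the free components relax toward the press equilibrium
    y* along ``y(t) = e^{A_ff t}(y0 - y*) + y*``. With a finite duration the
    unpressed dynamics take over from the release state.
    """
    if spec.mode != "press":
        raise ValueError("spec must be a press intervention")
    grid = _check_grid(grid)
    S, free = _partition(model.p, spec.targets)
    order = np.argsort(np.asarray(spec.targets))
    v = np.asarray(spec.values, dtype=float)[order]
    y_init = np.zeros(model.p) if init is None else np.asarray(init, dtype=float).copy()

    ystar = press_equilibrium(model, S, v) if free.size else None
    Aff = model.drift[np.ix_(free, free)] if free.size else None

    def pressed_state(t: float, y_from: np.ndarray) -> np.ndarray:
        out = np.empty(model.p)
        out[S] = v
        if free.size:
            out[free] = sla.expm(Aff * t) @ (y_from[free] - ystar[free]) + ystar[free]
        return out

    if method == "rk4":
        dur = spec.duration
        if dur is None or dur >= grid[-1]:
            states = _rk4_clamped(model.drift, y_init, grid, S, v)
        else:
            pre = grid[grid <= dur]
            if pre.size == 0 or pre[-1] != dur:
                pre = np.append(pre, dur)
            seg1 = _rk4_clamped(model.drift, y_init, pre, S, v)
            rel = seg1[-1].copy()
            post = grid[grid > dur] - dur
            seg2 = _rk4_clamped(model.drift, rel, np.insert(post, 0, 0.0),
                                np.array([], dtype=int), np.array([]))
            states = np.vstack([seg1[: np.sum(grid <= dur)], seg2[1:]])
    elif method == "exact":
        states = np.empty((grid.size, model.p))
        dur = spec.duration
        release_state = None
        for k, t in enumerate(grid):
            if dur is None or t <= dur:
                states[k] = pressed_state(t, y_init)
            else:
                if release_state is None:
                    release_state = pressed_state(dur, y_init)
                states[k] = sla.expm(model.drift * (t - dur)) @ release_state
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrajectorySet(times=grid, states=states, spec=spec, labels=model.labels)


def clamped_trajectory(model: CTModel, pulse_targets, pulse_values, clamp, grid,
                       method: str = "exact") -> TrajectorySet:
    """Pulse on some variables while a clamp set is press-held at equilibrium.

    This combined do-operation realizes the direct effect: component j of the
    trajectory at time dt, after a unit pulse on i with mediators clamped at
    0, equals direct_effect(i -> j, M, dt). The rk4 route integrates the
    *original* drift with the clamped components forcibly held at zero, so it
    is an oracle independent of the modified-drift matrix exponential.
    """
    pulse_targets = tuple(model.index(t) for t in np.atleast_1d(pulse_targets))
    clamp_list = [] if clamp is None else list(np.atleast_1d(clamp))
    clamp = tuple(sorted(model.index(c) for c in clamp_list))
    if set(pulse_targets) & set(clamp):
        raise ValueError("pulse targets must be disjoint from the clamp set")
    grid = _check_grid(grid)
    y0 = np.zeros(model.p)
    y0[list(pulse_targets)] = np.atleast_1d(np.asarray(pulse_values, dtype=float))

    Ci = np.array(clamp, dtype=int)
    if method == "rk4":
        states = _rk4_clamped(model.drift, y0, grid, Ci, np.zeros(Ci.size))
    elif method == "exact":
        S, free = _partition(model.p, clamp)
        states = np.zeros((grid.size, model.p))
        if free.size:
            Aff = model.drift[np.ix_(free, free)]
            for k, t in enumerate(grid):
                states[k, free] = sla.expm(Aff * t) @ y0[free]
    else:
        raise ValueError(f"unknown method {method!r}")
    spec = InterventionSpec(mode="pulse", targets=pulse_targets,
                            values=tuple(np.atleast_1d(np.asarray(pulse_values, dtype=float))))
    return TrajectorySet(times=grid, states=states, spec=spec, labels=model.labels)
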