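"""Time-interval-resolved total, direct, and indirect effects.

In a continuous-time linear network the lagged matrix at any interval is a
sum over all paths through intermediate latent "waves" of the process, so the
entry ``[e^{A dt}]_{j,i}`` is the *total* effect of a unit pulse on variable i
on the expected value of variable j a time dt later. The *direct* effect
relative to a mediator set M is obtained by press-holding the mediators at
equilibrium, which for a linear system amounts to computing the exponential
of a modified drift matrix with the off-diagonal rows and columns of M
zeroed. The *indirect* effect is the difference: IE = TE - DE, by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .discretize import lagged_params
from .model_core import CTModel, EffectCurve

__all__ = [
    "MediatorBlockSpec",
    "total_effect",
    "blocked_drift",
    "direct_effect",
    "indirect_effect",
    "effect_curve",
    "path_trace_oracle",
]


@dataclass
class MediatorBlockSpec:
    """A mediator set together with the drift matrix it induces."""

    mediators: tuple[int, ...]
    modified_drift: np.ndarray


def _resolve(model: CTModel, var) -> int:
    return model.index(var)


def _resolve_set(model: CTModel, mediators: Iterable) -> tuple[int, ...]:
    out = tuple(sorted({model.index(m) for m in mediators}))
    return out


def total_effect(model: CTModel, cause, effect, dt: float) -> float:
    """Total effect of a unit pulse on `cause` on `effect` a time dt later.

    This is the expected-value contrast of do(Y_cause(t)=1) versus
    do(Y_cause(t)=0), read off as entry [effect, cause] of e^{A dt}.
    """
    i = _resolve(model, cause)
    j = _resolve(model, effect)
    return float(lagged_params(model, dt)[j, i])


def blocked_drift(model: CTModel, mediators: Iterable) -> MediatorBlockSpec:
    """Drift matrix with mediators press-held at equilibrium.

    All off-diagonal entries in rows and columns indexed by the mediator set
    are zeroed: inputs to the mediators are severed, and the mediators'
    (zero-valued) outputs contribute nothing. Diagonal auto-effects are left
    untouched. Idempotent.
    """
    M = _resolve_set(model, mediators)
    A = model.drift.copy()
    if M:
        idx = np.array(M, dtype=int)
        diag = np.diag(A).copy()
        A[idx, :] = 0.0
        A[:, idx] = 0.0
        A[np.arange(A.shape[0]), np.arange(A.shape[0])] = diag
    return MediatorBlockSpec(mediators=M, modified_drift=A)


def direct_effect(model: CTModel, cause, effect, mediators: Iterable, dt: float) -> float:
    """Direct effect of `cause` on `effect` not mediated by the given set.

    Equals the expected-value contrast of a unit pulse on the cause while the
    mediators are press-held at their equilibrium value. With an empty
    mediator set this coincides with the total effect.
    """
    i = _resolve(model, cause)
    j = _resolve(model, effect)
    M = _resolve_set(model, mediators)
    if i in M or j in M:
        raise ValueError("mediator set must not contain the cause or the effect")
    spec = blocked_drift(model, M)
    return float(lagged_params(spec.modified_drift, dt)[j, i])


def indirect_effect(model: CTModel, cause, effect, mediators: Iterable, dt: float) -> float:
    """Indirect effect through the mediator set: IE(dt) = TE(dt) - DE(dt).

    A positive value means press-holding the mediators *decreases* the effect
    of the pulse on the cause; a negative value means the press *increases*
    it (as happens when the mediators carry a compensating negative feedback).
    """
    M = _resolve_set(model, mediators)
    if not M:
        raise ValueError("indirect effect undefined without mediators")
    te = total_effect(model, cause, effect, dt)
    de = direct_effect(model, cause, effect, M, dt)
    return te - de


def effect_curve(model: CTModel, kind: str, cause, effect, mediators: Iterable = (), grid=None) -> EffectCurve:
    """Evaluate a total/direct/indirect effect on a grid of time-intervals."""
    from .discretize import default_grid, phi_curve

    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float).reshape(-1)
    i = _resolve(model, cause)
    j = _resolve(model, effect)
    M = _resolve_set(model, mediators)
    if kind in ("direct", "indirect") and (i in M or j in M):
        raise ValueError("mediator set must not contain the cause or the effect")
    if kind == "indirect" and not M:
        raise ValueError("indirect effect undefined without mediators")

    te_vals = phi_curve(model, grid).matrices[:, j, i]
    if kind == "total":
        vals = te_vals
    else:
        spec = blocked_drift(model, M)
        blocked_model = CTModel(
            drift=spec.modified_drift, diffusion=model.diffusion, labels=model.labels
        )
        de_vals = phi_curve(blocked_model, grid).matrices[:, j, i]
        vals = de_vals if kind == "direct" else te_vals - de_vals
    return EffectCurve(
        kind=kind, cause=i, effect=j, mediators=M, grid=grid,
        effect_values=vals, labels=model.labels,
    )


def path_trace_oracle(model: CTModel, kind: str, cause, effect, mediators: Iterable, dt: float, n_steps: int) -> float:
    """Brute-force product-limit approximation of an effect; test oracle only.

    Builds the one-step matrix (I + A dt/n) — with mediator rows/columns
    blocked for direct effects — raises it to the n-th power, and reads entry
    (effect, cause). Converges to the closed-form matrix-exponential value as
    n grows, mirroring path tracing through n latent waves.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    i = _resolve(model, cause)
    j = _resolve(model, effect)
    M = _resolve_set(model, mediators)

    def product_limit(A: np.ndarray) -> float:
        step = np.eye(A.shape[0]) + A * (dt / n_steps)
        return float(np.linalg.matrix_power(step, n_steps)[j, i])

    if kind == "total":
        return product_limit(model.drift)
    if kind == "direct":
        return product_limit(blocked_drift(model, M).modified_drift)
    if kind == "indirect":
        return product_limit(model.drift) - product_limit(blocked_drift(model, M).modified_drift)
    raise ValueError(f"unknown effect kind {kind!r}")
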