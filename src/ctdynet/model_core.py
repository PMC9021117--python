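"""Core domain types for continuous-time (CT) and discrete-time (DT) dynamical
network models.

A CT network is parameterized by a drift matrix ``A`` whose entry ``A[j, i]``
is the moment-to-moment effect of variable ``i`` on the rate of change of
variable ``j`` (a weighted local dependence graph), together with a diffusion
covariance ``Q`` giving the covariance rate of the Wiener input of the
stochastic differential equation

    dY(t)/dt = A Y(t) + W(t).

A DT network is the familiar lag-one VAR: ``Y_tau = c + Phi Y_{tau-1} + eps``,
where ``Phi`` refers to one specific time-interval between occasions.

All vectors/matrices are plain numpy arrays; variables are addressed by label
in user-facing code and by 0-based index internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "NonStationaryError",
    "CTModel",
    "DTModel",
    "IrregularTimeSeries",
    "EffectCurve",
    "CentralityCurve",
    "InterventionSpec",
    "FitResult",
    "CTDiagnostics",
    "validate_ct",
    "dt_equilibrium",
]

#: relative tolerance used for symmetry / positive-semidefiniteness checks
SYMMETRY_RTOL = 1e-8
#: most negative eigenvalue tolerated in a PSD matrix
PSD_EIG_FLOOR = -1e-10


class ValidationError(ValueError):
    """A model or data object violates one of its structural invariants."""


class NonStationaryError(ValueError):
    """Raised when an operation requires a stationary/stable model."""


def _as_matrix(x, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be a square matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValidationError(f"{name} contains non-finite entries")
    return m


def _check_symmetric_psd(m: np.ndarray, name: str, rtol: float = SYMMETRY_RTOL) -> np.ndarray:
    scale = max(1.0, float(np.max(np.abs(m))))
    if np.max(np.abs(m - m.T)) > rtol * scale:
        raise ValidationError(f"{name} is not symmetric within tolerance")
    sym = 0.5 * (m + m.T)
    eigs = np.linalg.eigvalsh(sym)
    if eigs.min() < PSD_EIG_FLOOR * scale:
        raise ValidationError(
            f"{name} has a negative eigenvalue ({eigs.min():.3e}) beyond tolerance"
        )
    return sym


def _default_labels(p: int) -> tuple[str, ...]:
    return tuple(f"Y{i + 1}" for i in range(p))


@dataclass
class CTModel:
    """First-order linear stochastic-differential-equation (OU) model.

    Parameters
    ----------
    drift
        p x p drift matrix ``A``; ``drift[j, i]`` is the effect of variable i
        on dY_j/dt, in per-time-unit rates. Diagonal auto-effects are
        typically negative for a mean-reverting process.
    diffusion
        p x p symmetric PSD covariance rate ``Q`` of the Wiener input.
    equilibrium
        Length-p equilibrium (attractor). Defaults to zeros — the centered
        convention used throughout.
    labels
        Variable names, length p.
    """

    drift: np.ndarray
    diffusion: np.ndarray
    equilibrium: np.ndarray | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.drift = _as_matrix(self.drift, "drift")
        p = self.drift.shape[0]
        self.diffusion = _as_matrix(self.diffusion, "diffusion")
        if self.diffusion.shape[0] != p:
            raise ValidationError("diffusion dimension does not match drift")
        self.diffusion = _check_symmetric_psd(self.diffusion, "diffusion")
        if self.equilibrium is None:
            self.equilibrium = np.zeros(p)
        self.equilibrium = np.asarray(self.equilibrium, dtype=float).reshape(-1)
        if self.equilibrium.shape[0] != p:
            raise ValidationError("equilibrium length does not match drift")
        if self.labels is None:
            self.labels = _default_labels(p)
        self.labels = tuple(str(s) for s in self.labels)
        if len(self.labels) != p:
            raise ValidationError("labels length does not match drift dimension")

    @property
    def p(self) -> int:
        return self.drift.shape[0]

    @property
    def is_stable(self) -> bool:
        """True iff every eigenvalue of the drift has strictly negative real part."""
        return bool(np.all(np.linalg.eigvals(self.drift).real < 0.0))

    def index(self, var: int | str) -> int:
        """Resolve a variable given by label or 0-based index."""
        if isinstance(var, str):
            try:
                return self.labels.index(var)
            except ValueError:
                raise KeyError(f"unknown variable label {var!r}; have {self.labels}")
        i = int(var)
        if not 0 <= i < self.p:
            raise IndexError(f"variable index {i} out of range for p={self.p}")
        return i

    def to_dict(self) -> dict:
        return {
            "model_kind": "ct",
            "labels": list(self.labels),
            "drift": self.drift.tolist(),
            "diffusion": self.diffusion.tolist(),
            "equilibrium": self.equilibrium.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CTModel":
        return cls(
            drift=np.asarray(d["drift"], dtype=float),
            diffusion=np.asarray(d["diffusion"], dtype=float),
            equilibrium=np.asarray(d.get("equilibrium", None), dtype=float)
            if d.get("equilibrium") is not None
            else None,
            labels=d.get("labels"),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "CTModel":
        d = _load_json(source)
        return cls.from_dict(d)


@dataclass
class DTModel:
    """Lag-one vector-autoregressive model tied to a specific time-interval."""

    lagged: np.ndarray
    interval: float
    residual_cov: np.ndarray
    intercept: np.ndarray | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.lagged = _as_matrix(self.lagged, "lagged")
        p = self.lagged.shape[0]
        self.interval = float(self.interval)
        if not (np.isfinite(self.interval) and self.interval > 0):
            raise ValidationError("interval must be a positive real")
        self.residual_cov = _as_matrix(self.residual_cov, "residual_cov")
        if self.residual_cov.shape[0] != p:
            raise ValidationError("residual_cov dimension does not match lagged")
        self.residual_cov = _check_symmetric_psd(self.residual_cov, "residual_cov")
        if self.intercept is None:
            self.intercept = np.zeros(p)
        self.intercept = np.asarray(self.intercept, dtype=float).reshape(-1)
        if self.intercept.shape[0] != p:
            raise ValidationError("intercept length does not match lagged")
        if self.labels is None:
            self.labels = _default_labels(p)
        self.labels = tuple(str(s) for s in self.labels)
        if len(self.labels) != p:
            raise ValidationError("labels length does not match lagged dimension")

    @property
    def p(self) -> int:
        return self.lagged.shape[0]

    @property
    def is_stationary(self) -> bool:
        """True iff the spectral radius of the lagged matrix is < 1."""
        return bool(np.max(np.abs(np.linalg.eigvals(self.lagged))) < 1.0)

    def index(self, var: int | str) -> int:
        if isinstance(var, str):
            try:
                return self.labels.index(var)
            except ValueError:
                raise KeyError(f"unknown variable label {var!r}; have {self.labels}")
        i = int(var)
        if not 0 <= i < self.p:
            raise IndexError(f"variable index {i} out of range for p={self.p}")
        return i

    def to_dict(self) -> dict:
        return {
            "model_kind": "dt",
            "labels": list(self.labels),
            "lagged": self.lagged.tolist(),
            "interval": self.interval,
            "residual_cov": self.residual_cov.tolist(),
            "intercept": self.intercept.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DTModel":
        return cls(
            lagged=np.asarray(d["lagged"], dtype=float),
            interval=float(d["interval"]),
            residual_cov=np.asarray(d["residual_cov"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float) if d.get("intercept") is not None else None,
            labels=d.get("labels"),
        )

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "DTModel":
        return cls.from_dict(_load_json(source))


def _load_json(source) -> dict:
    if isinstance(source, dict):
        return source
    if isinstance(source, str) and source.lstrip().startswith("{"):
        return json.loads(source)
    with open(source) as fh:
        return json.load(fh)


def load_model(source):
    """Load a CTModel or DTModel from a JSON document, dispatching on model_kind."""
    d = _load_json(source)
    kind = d.get("model_kind", "ct" if "drift" in d else "dt")
    return CTModel.from_dict(d) if kind == "ct" else DTModel.from_dict(d)


@dataclass
class IrregularTimeSeries:
    """Timestamped multivariate observations with strictly increasing times.

    Missing entries are represented as NaN. Times must share the unit of the
    drift rates (hours, by package convention).
    """

    times: np.ndarray
    values: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != self.times.shape[0]:
            raise ValidationError("values row count must equal times length")
        if not np.all(np.isfinite(self.times)):
            raise ValidationError("times must be finite")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            bad = self.times[1:][diffs <= 0][0]
            raise ValidationError(
                f"times must be strictly increasing (violation at t={bad!r})"
            )
        if self.labels is None:
            self.labels = _default_labels(self.values.shape[1])
        self.labels = tuple(str(s) for s in self.labels)
        if len(self.labels) != self.values.shape[1]:
            raise ValidationError("labels length does not match number of columns")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def intervals(self) -> np.ndarray:
        """Elapsed time between consecutive occasions."""
        return np.diff(self.times)

    def complete_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Consecutive pairs with both rows fully observed.

        Returns (dts, y_prev, y_next) where rows with any NaN in either member
        of the pair are dropped (listwise by pair).
        """
        ok_row = ~np.any(np.isnan(self.values), axis=1)
        use = ok_row[:-1] & ok_row[1:]
        dts = np.diff(self.times)[use]
        return dts, self.values[:-1][use], self.values[1:][use]


@dataclass
class EffectCurve:
    """A path-specific effect evaluated on a grid of time-intervals."""

    kind: str  # "total" | "direct" | "indirect"
    cause: int
    effect: int
    mediators: tuple[int, ...]
    grid: np.ndarray
    effect_values: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("total", "direct", "indirect"):
            raise ValidationError(f"unknown effect kind {self.kind!r}")
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1)
        self.effect_values = np.asarray(self.effect_values, dtype=float).reshape(-1)
        if np.any(self.grid < 0) or np.any(np.diff(self.grid) <= 0):
            raise ValidationError("grid must be strictly increasing and nonnegative")
        if self.grid.shape != self.effect_values.shape:
            raise ValidationError("grid and effect_values length mismatch")
        self.mediators = tuple(int(m) for m in self.mediators)
        if self.cause in self.mediators or self.effect in self.mediators:
            raise ValidationError("mediators must exclude cause and effect")

    def to_frame(self):
        import pandas as pd

        lab = self.labels or _default_labels(max(self.cause, self.effect, *(self.mediators or (0,))) + 1)
        med = ";".join(lab[m] for m in self.mediators)
        return pd.DataFrame(
            {
                "dt": self.grid,
                "kind": self.kind,
                "cause": lab[self.cause],
                "effect": lab[self.effect],
                "mediators": med,
                "value": self.effect_values,
            }
        )


@dataclass
class CentralityCurve:
    """A per-variable centrality measure evaluated on a grid of time-intervals."""

    measure: str
    grid: np.ndarray
    node_values: np.ndarray  # |grid| x p
    labels: Sequence[str]
    source: str = "ct"  # "ct" or "dt"

    VALID = ("TEC", "IEC", "EI1", "EI2", "OutStrength", "BC")

    def __post_init__(self) -> None:
        if self.measure not in self.VALID:
            raise ValidationError(f"unknown centrality measure {self.measure!r}")
        self.grid = np.asarray(self.grid, dtype=float).reshape(-1)
        self.node_values = np.asarray(self.node_values, dtype=float)
        if self.node_values.shape[0] != self.grid.shape[0]:
            raise ValidationError("node_values rows must match grid length")
        if not np.all(np.isfinite(self.node_values)):
            raise ValidationError("node_values must be finite")
        self.labels = tuple(str(s) for s in self.labels)

    def peak_intervals(self) -> dict[str, float]:
        """Per node, the grid dt at which |value| is largest."""
        idx = np.argmax(np.abs(self.node_values), axis=0)
        return {lab: float(self.grid[k]) for lab, k in zip(self.labels, idx)}

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, dt in enumerate(self.grid):
            for j, lab in enumerate(self.labels):
                rows.append((dt, self.measure, lab, self.node_values[k, j]))
        return pd.DataFrame(rows, columns=["dt", "measure", "node", "value"])


@dataclass
class InterventionSpec:
    """A do-operation: pulse (instantaneous set) or press (hold over a window)."""

    mode: str  # "pulse" | "press"
    targets: tuple[int, ...]
    values: tuple[float, ...]
    start: float = 0.0
    duration: float | None = None  # press only; None = indefinite

    def __post_init__(self) -> None:
        if self.mode not in ("pulse", "press"):
            raise ValidationError(f"unknown intervention mode {self.mode!r}")
        self.targets = tuple(int(t) for t in self.targets)
        self.values = tuple(float(v) for v in self.values)
        if len(self.targets) == 0:
            raise ValidationError("targets must be nonempty")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("targets must be distinct")
        if len(self.values) != len(self.targets):
            raise ValidationError("one value per target required")
        if not all(np.isfinite(self.values)):
            raise ValidationError("intervention values must be finite")
        if self.duration is not None and self.duration <= 0:
            raise ValidationError("press duration must be positive")


@dataclass
class FitResult:
    """Output of a maximum-likelihood or OLS fit."""

    model: CTModel | DTModel
    param_vector: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n_pairs: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.param_vector = np.asarray(self.param_vector, dtype=float).reshape(-1)
        self.vcov = np.asarray(self.vcov, dtype=float)
        k = self.param_vector.shape[0]
        if self.vcov.shape != (k, k):
            raise ValidationError("vcov shape must match param_vector")
        if np.max(np.abs(self.vcov - self.vcov.T)) > 1e-8 * max(1.0, np.max(np.abs(self.vcov))):
            raise ValidationError("vcov must be symmetric")

    def se(self) -> np.ndarray:
        d = np.diag(self.vcov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)


@dataclass
class CTDiagnostics:
    eigenvalues: np.ndarray
    stable: bool
    warnings: list[str]


def validate_ct(model: CTModel) -> CTDiagnostics:
    """Validate a CT model and report stability diagnostics.

    Non-negative diagonal drift entries produce a warning (auto-effects of a
    mean-reverting process are typically negative) but not a failure; the
    dataclass constructor has already enforced the structural invariants.
    """
    eigs = np.linalg.eigvals(model.drift)
    stable = bool(np.all(eigs.real < 0.0))
    warnings: list[str] = []
    diag = np.diag(model.drift)
    for i, a in enumerate(diag):
        if a >= 0:
            warnings.append(
                f"auto-effect for {model.labels[i]} is non-negative ({a:g}); "
                "auto-effects are typically negative"
            )
    if not stable:
        warnings.append("drift has an eigenvalue with non-negative real part; model is unstable")
    return CTDiagnostics(eigenvalues=eigs, stable=stable, warnings=warnings)


def dt_equilibrium(model: DTModel) -> np.ndarray:
    """Equilibrium (multivariate mean) of a stationary DT-VAR: (I - Phi)^-1 c."""
    if not model.is_stationary:
        raise NonStationaryError(
            "lagged matrix has spectral radius >= 1; equilibrium undefined"
        )
    p = model.p
    return np.linalg.solve(np.eye(p) - model.lagged, model.intercept)
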