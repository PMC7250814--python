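"""Structured fast-transition predator-prey models.

The fast time scale is described by two coupled linear-in-state systems:
prey densities ``x`` (length ``m``) evolve under a spontaneous transition
matrix ``A`` plus predator-mediated transitions encoded in a rank-3 tensor
``B``; predator densities ``y`` (length ``n``) evolve under ``D`` plus
prey-mediated transitions ``C``.  All transition matrices are conservative
(columns sum to zero), so the totals ``X = sum(x)`` and ``Y = sum(y)`` are
invariants of the fast dynamics.

Index convention (fixed throughout the package):

* ``A[k, i]`` — spontaneous prey transition rate from state ``i`` to ``k``
  (``k != i``); ``A[i, i]`` is minus the total exit rate.
* ``B[k, i, j]`` — rate coefficient (per unit predator density) for the
  prey transition ``i -> k`` mediated by predators in state ``j``.
  Tensor axes are ``[destination, source, mediator]``.
* ``D``, ``C`` — identical conventions for the predator, with prey states
  as mediators in ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "TransitionModel",
    "DemographyRates",
    "PopulationState",
    "ShapeError",
    "Violation",
    "ValidationReport",
    "validate_consistency",
    "fast_vector_field",
    "effective_matrices",
    "CONSISTENCY_ATOL",
]

#: Absolute tolerance for the column-sum-zero consistency conditions.
CONSISTENCY_ATOL = 1e-12


class ShapeError(ValueError):
    """Structural error: an array does not have its declared shape."""


def _as_array(value, shape: Tuple[int, ...], name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != shape:
        raise ShapeError(f"{name} must have shape {shape}, got {arr.shape}")
    return arr


@dataclass
class TransitionModel:
    """Fast-dynamics specification (matrices ``A``, ``D``, tensors ``B``, ``C``).

    Parameters
    ----------
    A : (m, m) array_like
        Spontaneous prey transitions, destination-major.
    B : (m, m, n) array_like
        Predator-mediated prey transitions, ``[destination, source, mediator]``.
    C : (n, n, m) array_like
        Prey-mediated predator transitions.
    D : (n, n) array_like
        Spontaneous predator transitions.
    relaxed : bool
        Allow zero diagonal entries in ``A`` / ``D``.  Models in which a
        state has no spontaneous exit (all exits mediated, or none at all)
        require this flag.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    relaxed: bool = False

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ShapeError(f"A must be a square matrix, got shape {A.shape}")
        m = A.shape[0]
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ShapeError(f"D must be a square matrix, got shape {D.shape}")
        n = D.shape[0]
        self.A = A
        self.D = D
        self.B = _as_array(self.B, (m, m, n), "B")
        self.C = _as_array(self.C, (n, n, m), "C")

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.D.shape[0]

    def validate(self, relaxed: Optional[bool] = None) -> "ValidationReport":
        return validate_consistency(self, relaxed=relaxed)


def _simplex(vec, size: int, name: str) -> np.ndarray:
    if vec is None:
        return np.full(size, 1.0 / size)
    arr = _as_array(vec, (size,), name)
    if np.any(arr < 0) or not np.isclose(arr.sum(), 1.0, atol=1e-10):
        raise ValueError(f"{name} must be a probability vector over {size} states")
    return arr


@dataclass
class DemographyRates:
    """Slow-scale demographic rates attached to a :class:`TransitionModel`.

    ``beta[i, j]`` is the capture rate of prey state ``i`` by predator
    state ``j`` (per predator density per time); ``gamma[i, j]`` the
    per-capture fecundity for that channel.  ``pred_birth[j]`` is an
    occupancy-based per-capita birth rate of predator state ``j`` — it
    covers models where reproduction is tied to time spent in a state
    (e.g. handling) rather than to the capture event itself.
    """

    beta: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    pred_birth: Optional[np.ndarray] = None
    prey_offspring: Optional[np.ndarray] = None
    pred_offspring: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if beta.ndim != 2:
            raise ShapeError(f"beta must be a matrix, got shape {beta.shape}")
        m, n = beta.shape
        self.beta = beta
        self.lam = _as_array(self.lam, (m,), "lam")
        self.mu = _as_array(self.mu, (m,), "mu")
        self.gamma = _as_array(self.gamma, (m, n), "gamma")
        self.delta = _as_array(self.delta, (n,), "delta")
        if self.pred_birth is None:
            self.pred_birth = np.zeros(n)
        else:
            self.pred_birth = _as_array(self.pred_birth, (n,), "pred_birth")
        self.prey_offspring = _simplex(self.prey_offspring, m, "prey_offspring")
        self.pred_offspring = _simplex(self.pred_offspring, n, "pred_offspring")
        for name in ("beta", "lam", "mu", "gamma", "delta", "pred_birth"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and nonnegative")

    @property
    def m(self) -> int:
        return self.beta.shape[0]

    @property
    def n(self) -> int:
        return self.beta.shape[1]

    @classmethod
    def zero(cls, m: int, n: int) -> "DemographyRates":
        """All-zero demography (pure fast dynamics)."""
        return cls(
            beta=np.zeros((m, n)),
            lam=np.zeros(m),
            mu=np.zeros(m),
            gamma=np.zeros((m, n)),
            delta=np.zeros(n),
        )


@dataclass
class PopulationState:
    """Per-state densities ``x`` (prey) and ``y`` (predator)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        for name, arr in (("x", self.x), ("y", self.y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def X(self) -> float:
        return float(self.x.sum())

    @property
    def Y(self) -> float:
        return float(self.y.sum())


@dataclass
class Violation:
    """A single consistency violation, locating the offending column."""

    array: str
    slice_index: Optional[int]
    column: int
    residual: float
    kind: str  # "column_sum", "off_diagonal_sign", "diagonal_sign", "nonfinite"

    def __str__(self) -> str:
        where = self.array
        if self.slice_index is not None:
            where += f"[:, :, {self.slice_index}]"
        return f"{self.kind} in {where} column {self.column} (residual {self.residual:g})"


@dataclass
class ValidationReport:
    violations: List[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def raise_if_invalid(self) -> None:
        if not self.ok:
            msgs = "; ".join(str(v) for v in self.violations)
            raise ValueError(f"inconsistent transition model: {msgs}")


def _check_matrix(
    M: np.ndarray,
    name: str,
    slice_index: Optional[int],
    violations: List[Violation],
    strict_diagonal: bool,
) -> None:
    k = M.shape[0]
    for col in range(k):
        if not np.all(np.isfinite(M[:, col])):
            violations.append(Violation(name, slice_index, col, np.inf, "nonfinite"))
            continue
        csum = float(M[:, col].sum())
        if abs(csum) > CONSISTENCY_ATOL:
            violations.append(Violation(name, slice_index, col, csum, "column_sum"))
        off = np.delete(M[:, col], col)
        if off.size and float(off.min()) < -CONSISTENCY_ATOL:
            violations.append(
                Violation(name, slice_index, col, float(off.min()), "off_diagonal_sign")
            )
        if strict_diagonal and M[col, col] >= 0:
            violations.append(
                Violation(name, slice_index, col, float(M[col, col]), "diagonal_sign")
            )


def validate_consistency(
    model: TransitionModel, relaxed: Optional[bool] = None
) -> ValidationReport:
    """Check the conservativity (column-sum-zero) and sign conditions.

    Parameters
    ----------
    relaxed : bool, optional
        Skip the strictly-negative-diagonal check on ``A`` and ``D``.
        Defaults to ``model.relaxed``.

    Returns
    -------
    ValidationReport
        Empty iff the model satisfies every invariant within
        :data:`CONSISTENCY_ATOL`.
    """
    if relaxed is None:
        relaxed = model.relaxed
    violations: List[Violation] = []
    _check_matrix(model.A, "A", None, violations, strict_diagonal=not relaxed)
    _check_matrix(model.D, "D", None, violations, strict_diagonal=not relaxed)
    for j in range(model.n):
        _check_matrix(model.B[:, :, j], "B", j, violations, strict_diagonal=False)
    for j in range(model.m):
        _check_matrix(model.C[:, :, j], "C", j, violations, strict_diagonal=False)
    return ValidationReport(violations)


def effective_matrices(
    model: TransitionModel, state: PopulationState
) -> Tuple[np.ndarray, np.ndarray]:
    """Mediator-contracted transition matrices at the given state.

    Returns ``(A + B(y), C(x) + D)`` where ``B(y)[k, i] = sum_j B[k, i, j] y_j``
    and ``C(x)[k, i] = sum_j C[k, i, j] x_j``.  The fast vector field is
    ``(M_prey @ x, M_pred @ y)``.
    """
    M_prey = model.A + model.B @ state.y
    M_pred = model.D + model.C @ state.x
    return M_prey, M_pred


def fast_vector_field(
    model: TransitionModel, state: PopulationState
) -> Tuple[np.ndarray, np.ndarray]:
    """Time derivative of the per-state densities under the fast dynamics."""
    M_prey, M_pred = effective_matrices(model, state)
    return M_prey @ state.x, M_pred @ state.y


def fast_jacobian(
    model: TransitionModel, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Analytic Jacobian of the fast vector field at ``(x, y)``.

    Block structure ``[[A + B(y), dB/dy @ x], [dC/dx @ y, C(x) + D]]``; the
    off-diagonal blocks are ``B`` and ``C`` contracted against the state of
    the *other* species along the source axis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = model.m, model.n
    J = np.zeros((m + n, m + n))
    J[:m, :m] = model.A + model.B @ y
    J[m:, m:] = model.D + model.C @ x
    # d(dx_k)/d(y_j) = sum_i B[k, i, j] x_i
    J[:m, m:] = np.einsum("kij,i->kj", model.B, x)
    J[m:, :m] = np.einsum("kij,i->kj", model.C, y)
    return J
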