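"""Steady states of the fast behavioural dynamics at fixed totals.

At fixed totals ``(X, Y)`` the fast dynamics is a pair of coupled
conservative linear systems.  Each half-problem — prey distribution given
the predator distribution and vice versa — is a continuous-time Markov
chain stationary-distribution solve, so the nonlinear equilibrium is
computed by damped alternation of exact linear solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_model import (
    PopulationState,
    TransitionModel,
    effective_matrices,
    fast_jacobian,
    fast_vector_field,
)

__all__ = [
    "FastEquilibrium",
    "StabilityReport",
    "UniquenessReport",
    "ReducibleMatrixError",
    "RelaxedModelError",
    "solve_linear_stationary",
    "solve_triangular",
    "solve_nonlinear",
    "assess_stability",
    "probe_uniqueness",
    "birth_death_chain_equilibrium",
]


class ReducibleMatrixError(ValueError):
    """The transition matrix does not have a unique stationary distribution."""

    def __init__(self, message: str, components: Sequence[Sequence[int]]):
        super().__init__(message)
        self.components = [list(c) for c in components]


class RelaxedModelError(ValueError):
    """A solver was given a relaxed (degenerate-diagonal) model without override."""


@dataclass
class FastEquilibrium:
    """Fast-dynamics steady state at fixed totals."""

    x_hat: np.ndarray
    y_hat: np.ndarray
    residual: float
    iterations: int
    converged: bool

    @property
    def X(self) -> float:
        return float(self.x_hat.sum())

    @property
    def Y(self) -> float:
        return float(self.y_hat.sum())

    def state(self) -> PopulationState:
        return PopulationState(x=self.x_hat.copy(), y=self.y_hat.copy())


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray
    zero_count: int
    max_nonzero_real_part: float
    hyperbolically_stable: bool


@dataclass
class UniquenessReport:
    equilibria: List[Tuple[np.ndarray, np.ndarray]]
    n_starts: int
    n_failed: int
    seed: Optional[int]
    merge_tol: float = 1e-6

    @property
    def n_distinct(self) -> int:
        return len(self.equilibria)


def _terminal_components(M: np.ndarray) -> Tuple[int, List[List[int]]]:
    """Strongly connected components of the positive off-diagonal digraph,
    and which of them are terminal (no edge leaving the component)."""
    k = M.shape[0]
    adj = (M > 0).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=True, connection="strong"
    )
    comps = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
    terminal = []
    for c, members in enumerate(comps):
        # edge i -> k exists when M[k, i] > 0 (destination-major convention)
        outgoing = False
        for i in members:
            dests = np.flatnonzero(M[:, i] > 0)
            if np.any(labels[dests] != c):
                outgoing = True
                break
        if not outgoing:
            terminal.append(members)
    return len(comps), terminal


def solve_linear_stationary(
    M: np.ndarray, total: float, check_irreducible: bool = True
) -> np.ndarray:
    """Stationary vector of a conservative transition-rate matrix.

    Solves ``M v = 0`` with ``sum(v) = total`` via the bordered system
    ``(M + E) v = total * 1`` where ``E`` is the all-ones matrix.

    Raises
    ------
    ReducibleMatrixError
        If the digraph of positive off-diagonal entries has more than one
        terminal strongly connected component, so the stationary
        distribution is not unique.
    """
    M = np.asarray(M, dtype=float)
    k = M.shape[0]
    if M.shape != (k, k):
        raise ValueError(f"M must be square, got {M.shape}")
    if total < 0:
        raise ValueError("total must be nonnegative")
    if k == 1:
        return np.array([float(total)])
    if check_irreducible:
        _, terminal = _terminal_components(M)
        if len(terminal) != 1:
            raise ReducibleMatrixError(
                "transition matrix has no unique stationary distribution; "
                f"terminal strongly connected components: {terminal}",
                terminal,
            )
    if total == 0.0:
        return np.zeros(k)
    v = _gth_stationary(M)
    if v is None:
        # bordered normalization trick: M v = 0 and sum(v) = total combine
        # into the nonsingular system (M + E) v = total * 1.  Rescaling M
        # keeps the system well conditioned for very large rates.
        scale = np.abs(M).max()
        Ms = M / scale if scale > 0 else M
        v = np.linalg.solve(Ms + np.ones((k, k)), np.ones(k))
        v = np.clip(v, 0.0, None)
    return float(total) * v / v.sum()


def _gth_stationary(M: np.ndarray) -> Optional[np.ndarray]:
    """Unnormalised stationary vector by GTH state elimination.

    Subtraction-free, so every entry carries full relative accuracy even
    when the stationary vector spans many orders of magnitude.  Returns
    ``None`` when an elimination pivot vanishes (possible for chains that
    are not irreducible), in which case the caller falls back to the
    bordered linear solve.
    """
    k = M.shape[0]
    R = M.T.copy()  # row convention: R[i, j] is the rate i -> j
    np.fill_diagonal(R, 0.0)
    pivots = np.empty(k)
    for s in range(k - 1, 0, -1):
        pivot = R[s, :s].sum()
        if not pivot > 0:
            return None
        pivots[s] = pivot
        R[:s, :s] += np.outer(R[:s, s], R[s, :s]) / pivot
    v = np.empty(k)
    v[0] = 1.0
    for s in range(1, k):
        v[s] = (v[:s] @ R[:s, s]) / pivots[s]
    return v


def _require_not_relaxed(model: TransitionModel, allow_relaxed: bool) -> None:
    if model.relaxed and not allow_relaxed:
        raise RelaxedModelError(
            "model is flagged 'relaxed' (zero diagonals allowed); pass "
            "allow_relaxed=True to solve it anyway"
        )


def solve_triangular(
    model: TransitionModel,
    X: float,
    Y: float,
    allow_relaxed: bool = False,
) -> FastEquilibrium:
    """Equilibrium for the triangular case (prey unaffected by predators).

    Requires ``B == 0``: the prey distribution is the stationary vector of
    ``A`` alone, and the predator distribution follows from the prey-
    contracted matrix ``C(x_hat) + D``.
    """
    _require_not_relaxed(model, allow_relaxed)
    if np.any(model.B != 0):
        raise ValueError(
            "solve_triangular requires B == 0 (prey transitions independent "
            "of the predator); use solve_nonlinear for the general case"
        )
    x_hat = solve_linear_stationary(model.A, X)
    M_pred = model.D + model.C @ x_hat
    y_hat = solve_linear_stationary(M_pred, Y)
    state = PopulationState(x=x_hat, y=y_hat)
    dx, dy = fast_vector_field(model, state)
    residual = float(max(np.abs(dx).max(initial=0.0), np.abs(dy).max(initial=0.0)))
    return FastEquilibrium(
        x_hat=x_hat, y_hat=y_hat, residual=residual, iterations=2, converged=True
    )


def solve_nonlinear(
    model: TransitionModel,
    X: float,
    Y: float,
    tol: float = 1e-13,
    max_iter: int = 10_000,
    damping: float = 0.5,
    x0: Optional[np.ndarray] = None,
    y0: Optional[np.ndarray] = None,
    allow_relaxed: bool = False,
) -> FastEquilibrium:
    """Damped alternating fixed-point solve of the coupled equilibrium.

    Given the predator distribution, the prey distribution is the exact
    stationary vector of ``A + B(y)``, and vice versa.  Iterates
    ``v <- (1 - damping) v + damping v_target`` until the max-norm change
    of both halves falls below ``tol * (1 + X + Y)``.

    Non-convergence within ``max_iter`` is reported through the
    ``converged`` flag, never as an exception.
    """
    _require_not_relaxed(model, allow_relaxed)
    if X < 0 or Y < 0:
        raise ValueError("totals must be nonnegative")
    m, n = model.m, model.n
    x = np.full(m, X / m) if x0 is None else np.asarray(x0, dtype=float).copy()
    y = np.full(n, Y / n) if y0 is None else np.asarray(y0, dtype=float).copy()
    if x.sum() > 0:
        x *= X / x.sum()
    else:
        x = np.full(m, X / m)
    if y.sum() > 0:
        y *= Y / y.sum()
    else:
        y = np.full(n, Y / n)

    scale = 1.0 + X + Y
    step_tol = tol * scale
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        M_prey = model.A + model.B @ y
        x_target = solve_linear_stationary(M_prey, X) if m > 1 else np.array([X])
        x_new = (1.0 - damping) * x + damping * x_target
        M_pred = model.D + model.C @ x_new
        y_target = solve_linear_stationary(M_pred, Y) if n > 1 else np.array([Y])
        y_new = (1.0 - damping) * y + damping * y_target
        delta = max(
            np.abs(x_new - x).max(initial=0.0), np.abs(y_new - y).max(initial=0.0)
        )
        x, y = x_new, y_new
        if delta < step_tol:
            converged = True
            break

    # undamped polish: each half-step is an exact stationary solve, so for
    # triangular couplings this lands on the equilibrium to entrywise
    # precision and otherwise contracts the remaining damped-iteration tail
    for _ in range(3):
        if m > 1:
            x = solve_linear_stationary(model.A + model.B @ y, X)
        if n > 1:
            y = solve_linear_stationary(model.D + model.C @ x, Y)

    state = PopulationState(x=np.clip(x, 0.0, None), y=np.clip(y, 0.0, None))
    dx, dy = fast_vector_field(model, state)
    residual = float(max(np.abs(dx).max(initial=0.0), np.abs(dy).max(initial=0.0)))
    return FastEquilibrium(
        x_hat=state.x,
        y_hat=state.y,
        residual=residual,
        iterations=iterations,
        converged=converged,
    )


#: Relative tolerance for classifying Jacobian eigenvalues as zero.
ZERO_EIG_RTOL = 1e-8


def assess_stability(model: TransitionModel, eq: FastEquilibrium) -> StabilityReport:
    """Hyperbolic stability of a fast equilibrium.

    The Jacobian of the fast dynamics always has (at least) two zero
    eigenvalues from the two conservation laws; the equilibrium is
    hyperbolically stable when those are the only ones on the imaginary
    axis and every other eigenvalue has negative real part.
    """
    if not eq.converged:
        raise ValueError("stability assessment requires a converged equilibrium")
    J = fast_jacobian(model, eq.x_hat, eq.y_hat)
    eigs = np.linalg.eigvals(J)
    magnitude = np.abs(eigs)
    zero_tol = ZERO_EIG_RTOL * max(1.0, magnitude.max(initial=0.0))
    is_zero = magnitude <= zero_tol
    zero_count = int(is_zero.sum())
    nonzero = eigs[~is_zero]
    max_re = float(nonzero.real.max()) if nonzero.size else -np.inf
    return StabilityReport(
        eigenvalues=eigs,
        zero_count=zero_count,
        max_nonzero_real_part=max_re,
        hyperbolically_stable=(zero_count == 2 and max_re < 0),
    )


def integrate_fast(
    model: TransitionModel,
    x0: np.ndarray,
    y0: np.ndarray,
    t_end: float = 200.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate the pure fast dynamics forward and return the end state."""
    m = model.m

    def rhs(_t, z):
        state = PopulationState(x=np.clip(z[:m], 0.0, None), y=np.clip(z[m:], 0.0, None))
        dx, dy = fast_vector_field(model, state)
        return np.concatenate([dx, dy])

    def jac(_t, z):
        return fast_jacobian(model, np.clip(z[:m], 0.0, None), np.clip(z[m:], 0.0, None))

    z0 = np.concatenate([np.asarray(x0, float), np.asarray(y0, float)])
    sol = solve_ivp(
        rhs, (0.0, t_end), z0, method="BDF", jac=jac, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise RuntimeError(f"fast-dynamics integration failed: {sol.message}")
    z = sol.y[:, -1]
    return np.clip(z[:m], 0.0, None), np.clip(z[m:], 0.0, None)


def probe_uniqueness(
    model: TransitionModel,
    X: float,
    Y: float,
    n_starts: int = 20,
    seed: Optional[int] = 0,
    merge_tol: float = 1e-6,
    allow_relaxed: bool = False,
    t_end: float = 200.0,
) -> UniquenessReport:
    """Search for distinct fast equilibria from random simplex starts.

    Each start is attempted both through :func:`solve_nonlinear` and by
    direct forward integration of the fast dynamics; candidate end points
    with small residual are merged when closer than ``merge_tol`` in
    max-norm after normalising by ``X + Y``.
    """
    rng = np.random.default_rng(seed)
    scale = X + Y
    if scale <= 0:
        raise ValueError("X + Y must be positive")
    resid_tol = 1e-8 * max(1.0, scale)
    candidates: List[Tuple[np.ndarray, np.ndarray]] = []
    n_failed = 0
    for _ in range(n_starts):
        x0 = X * rng.dirichlet(np.ones(model.m))
        y0 = Y * rng.dirichlet(np.ones(model.n))
        try:
            eq = solve_nonlinear(
                model, X, Y, x0=x0, y0=y0, allow_relaxed=allow_relaxed
            )
            if eq.converged and eq.residual < resid_tol:
                candidates.append((eq.x_hat, eq.y_hat))
            else:
                n_failed += 1
        except (ReducibleMatrixError, RelaxedModelError, np.linalg.LinAlgError):
            n_failed += 1
        try:
            xe, ye = integrate_fast(model, x0, y0, t_end=t_end)
            state = PopulationState(x=xe, y=ye)
            dx, dy = fast_vector_field(model, state)
            resid = max(np.abs(dx).max(initial=0.0), np.abs(dy).max(initial=0.0))
            if resid < resid_tol:
                candidates.append((xe, ye))
        except RuntimeError:
            n_failed += 1

    distinct: List[Tuple[np.ndarray, np.ndarray]] = []
    for cx, cy in candidates:
        is_new = True
        for dx_, dy_ in distinct:
            dist = max(
                np.abs(cx - dx_).max(initial=0.0), np.abs(cy - dy_).max(initial=0.0)
            ) / scale
            if dist <= merge_tol:
                is_new = False
                break
        if is_new:
            distinct.append((cx, cy))
    return UniquenessReport(
        equilibria=distinct,
        n_starts=n_starts,
        n_failed=n_failed,
        seed=seed,
        merge_tol=merge_tol,
    )


def birth_death_chain_equilibrium(
    up_rates: Sequence[float], down_rates: Sequence[float], X: float
) -> np.ndarray:
    """Stationary occupancy of a birth-death chain scaled to total ``X``.

    ``up_rates[i]`` is the rate from state ``i`` to ``i+1`` and
    ``down_rates[i]`` the rate from ``i+1`` back to ``i`` (detailed
    balance: occupancy ratios are products of up/down rate ratios).
    """
    up = np.asarray(up_rates, dtype=float)
    down = np.asarray(down_rates, dtype=float)
    if up.shape != down.shape or up.ndim != 1:
        raise ValueError("up_rates and down_rates must be 1-D of equal length")
    if np.any(down <= 0):
        raise ValueError("down_rates must be strictly positive")
    if np.any(up <= 0):
        raise ValueError("up_rates must be strictly positive")
    weights = np.concatenate([[1.0], np.cumprod(up / down)])
    return X * weights / weights.sum()
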