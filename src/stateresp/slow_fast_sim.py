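"""Two-timescale simulation and validation of the quasi-steady-state reduction.

The full system couples the fast behavioural transitions, sped up by a
factor ``1/epsilon``, with slow demographic terms of order one: prey
births routed over states by ``prey_offspring``, natural deaths, capture
losses, predator births (per-capture and occupancy-based) routed by
``pred_offspring``, and predator mortality.  The reduced system tracks
only the totals ``(X, Y)`` and closes the dynamics through the responses
evaluated at the fast equilibrium.  As ``epsilon`` shrinks the full
totals converge to the reduced trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .core_model import (
    DemographyRates,
    PopulationState,
    TransitionModel,
    fast_jacobian,
    fast_vector_field,
)
from .fast_equilibrium import solve_nonlinear
from .responses import (
    functional_response,
    predator_numerical_response,
    prey_numerical_response,
)

__all__ = [
    "Trajectory",
    "full_system_rhs",
    "full_system_jacobian",
    "simulate_full",
    "simulate_reduced",
    "compare_reduction",
    "ReductionError",
]

_UNDERSHOOT_TOL = 1e-13


@dataclass
class Trajectory:
    """Time series of either per-state densities or totals.

    ``states`` has one row per time point.  For a full simulation the
    columns are ``(x_1..x_m, y_1..y_n)``; for a reduced one they are
    ``(X, Y)``.
    """

    times: np.ndarray
    states: np.ndarray
    kind: str  # "full" or "reduced"
    m: int
    n: int
    metadata: Dict[str, object] = field(default_factory=dict)

    def totals(self) -> np.ndarray:
        """``(len(times), 2)`` array of ``(X, Y)`` totals."""
        if self.kind == "reduced":
            return self.states
        return np.column_stack(
            [self.states[:, : self.m].sum(axis=1), self.states[:, self.m :].sum(axis=1)]
        )


def _slow_terms(
    model: TransitionModel,
    rates: DemographyRates,
    x: np.ndarray,
    y: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    prey_births = float(rates.lam @ x)
    capture_loss = (rates.beta @ y) * x  # per prey state
    dx = rates.prey_offspring * prey_births - rates.mu * x - capture_loss
    pred_births = float(x @ (rates.gamma * rates.beta) @ y + rates.pred_birth @ y)
    dy = rates.pred_offspring * pred_births - rates.delta * y
    return dx, dy


def full_system_rhs(
    model: TransitionModel,
    rates: DemographyRates,
    epsilon: float,
    state: PopulationState,
) -> Tuple[np.ndarray, np.ndarray]:
    """Derivative of the full system: fast field at ``1/epsilon`` plus demography."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    fx, fy = fast_vector_field(model, state)
    sx, sy = _slow_terms(model, rates, state.x, state.y)
    return fx / epsilon + sx, fy / epsilon + sy


def full_system_jacobian(
    model: TransitionModel,
    rates: DemographyRates,
    epsilon: float,
    x: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Analytic Jacobian of the full system (fast part plus slow part)."""
    m, n = model.m, model.n
    J = fast_jacobian(model, x, y) / epsilon
    # slow prey block
    J[:m, :m] += np.outer(rates.prey_offspring, rates.lam)
    J[:m, :m] -= np.diag(rates.mu + rates.beta @ y)
    J[:m, m:] -= rates.beta * x[:, None]
    # slow predator block
    gb = rates.gamma * rates.beta
    J[m:, :m] += np.outer(rates.pred_offspring, gb @ y)
    J[m:, m:] += np.outer(rates.pred_offspring, x @ gb + rates.pred_birth)
    J[m:, m:] -= np.diag(rates.delta)
    return J


def simulate_full(
    model: TransitionModel,
    rates: DemographyRates,
    epsilon: float,
    init: PopulationState,
    t_span: Tuple[float, float],
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
) -> Trajectory:
    """Stiff integration of the full two-timescale system."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    m, n = model.m, model.n

    def rhs(_t, z):
        x = np.clip(z[:m], 0.0, None)
        y = np.clip(z[m:], 0.0, None)
        dx, dy = full_system_rhs(model, rates, epsilon, PopulationState(x=x, y=y))
        return np.concatenate([dx, dy])

    def jac(_t, z):
        return full_system_jacobian(
            model, rates, epsilon, np.clip(z[:m], 0.0, None), np.clip(z[m:], 0.0, None)
        )

    z0 = np.concatenate([init.x, init.y])
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 201)
    sol = solve_ivp(
        rhs,
        t_span,
        z0,
        method=method,
        jac=jac,
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"full-system integration failed (epsilon={epsilon:g}; the system "
            f"is stiff for small epsilon — consider an implicit method): {sol.message}"
        )
    states = sol.y.T.copy()
    undershoot = states.min(initial=0.0)
    if undershoot < -_UNDERSHOOT_TOL * max(1.0, np.abs(states).max()):
        warnings.warn(
            f"negative densities down to {undershoot:g} clipped to zero",
            RuntimeWarning,
            stacklevel=2,
        )
    states = np.clip(states, 0.0, None)
    return Trajectory(
        times=sol.t.copy(),
        states=states,
        kind="full",
        m=m,
        n=n,
        metadata={"epsilon": epsilon, "rtol": rtol, "atol": atol, "method": method},
    )


class ReductionError(RuntimeError):
    """The fast equilibrium failed to converge along a reduced trajectory."""


def simulate_reduced(
    model: TransitionModel,
    rates: DemographyRates,
    X0: float,
    Y0: float,
    t_span: Tuple[float, float],
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    **solver_kwargs,
) -> Trajectory:
    """Integrate the reduced totals-only dynamics.

    The right-hand side re-solves the fast equilibrium at the current
    totals (warm-started from the previous evaluation) and assembles
    ``dX/dt = g X - f Y`` and ``dY/dt = (gamma f - delta) Y``.
    """
    if X0 < 0 or Y0 < 0:
        raise ValueError("initial totals must be nonnegative")
    m, n = model.m, model.n
    warm: Dict[str, Optional[np.ndarray]] = {"x": None, "y": None}

    def rhs(_t, z):
        X = max(z[0], 0.0)
        Y = max(z[1], 0.0)
        eq = solve_nonlinear(
            model, X, Y, x0=warm["x"], y0=warm["y"], **solver_kwargs
        )
        if not eq.converged:
            raise ReductionError(
                f"fast equilibrium not converged at X={X:g}, Y={Y:g} "
                f"(residual {eq.residual:g})"
            )
        warm["x"], warm["y"] = eq.x_hat, eq.y_hat
        dX = 0.0
        if X > 0:
            g = prey_numerical_response(model, rates, X, Y, eq=eq)
            dX += g * X
        if Y > 0:
            f = functional_response(model, rates, X, Y, eq=eq)
            pr = predator_numerical_response(model, rates, X, Y, eq=eq)
            dX -= f * Y
            dY = pr.net * Y
        else:
            dY = 0.0
        return [dX, dY]

    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 201)
    sol = solve_ivp(
        rhs,
        t_span,
        [float(X0), float(Y0)],
        method="LSODA",
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reduced-system integration failed: {sol.message}")
    return Trajectory(
        times=sol.t.copy(),
        states=np.clip(sol.y.T.copy(), 0.0, None),
        kind="reduced",
        m=m,
        n=n,
        metadata={"rtol": rtol, "atol": atol},
    )


@dataclass
class ReductionReport:
    sup_norm: float
    l2: float
    times: np.ndarray


def compare_reduction(full: Trajectory, reduced: Trajectory) -> ReductionReport:
    """Deviation between full and reduced trajectories on the totals.

    The reduced totals are interpolated onto the full trajectory's time
    grid; the report carries the sup-norm and the (trapezoidal) L2 norm
    of the difference of the ``(X, Y)`` curves.
    """
    t = full.times
    ft = full.totals()
    rt = reduced.totals()
    interp = np.column_stack(
        [np.interp(t, reduced.times, rt[:, k]) for k in range(2)]
    )
    diff = ft - interp
    sup = float(np.abs(diff).max())
    l2 = float(np.sqrt(np.trapezoid((diff ** 2).sum(axis=1), t))) if t.size > 1 else sup
    return ReductionReport(sup_norm=sup, l2=l2, times=t)
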