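"""Population-level functional and numerical responses.

Given the fast-dynamics equilibrium distribution at fixed totals
``(X, Y)``, the slow-scale responses are occupancy-weighted averages:

* functional response ``f = sum_ij beta_ij x_i y_j / Y``;
* prey numerical response ``g = sum_i (lam_i - mu_i) x_i / X``;
* predator numerical response ``gamma * f - delta`` where the birth term
  ``gamma * f = (sum_ij gamma_ij beta_ij x_i y_j + sum_j birth_j y_j) / Y``
  collects both per-capture fecundity and occupancy-based reproduction,
  and ``delta = sum_j delta_j y_j / Y``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_model import DemographyRates, TransitionModel
from .fast_equilibrium import FastEquilibrium, solve_nonlinear

__all__ = [
    "PredatorResponse",
    "ResponseSurface",
    "NonConvergedEquilibriumError",
    "functional_response",
    "prey_numerical_response",
    "predator_numerical_response",
    "response_surface",
]


class NonConvergedEquilibriumError(RuntimeError):
    """A response was requested from a non-converged fast equilibrium."""

    def __init__(self, residual: float):
        super().__init__(
            f"fast equilibrium did not converge (residual {residual:g})"
        )
        self.residual = residual


@dataclass
class PredatorResponse:
    """Predator numerical response split into its factors.

    ``gamma_factor`` is ``None`` when no prey are captured (``f == 0``):
    the conversion factor has no interpretation there, while the product
    ``gamma * f`` (held in ``birth_rate``) is well defined and zero-safe.
    """

    gamma_factor: Optional[float]
    delta_factor: float
    birth_rate: float  # gamma * f, per predator per time

    @property
    def net(self) -> float:
        return self.birth_rate - self.delta_factor


def _equilibrium(model, X, Y, eq, **solver_kwargs) -> FastEquilibrium:
    if eq is None:
        eq = solve_nonlinear(model, X, Y, **solver_kwargs)
    if not eq.converged:
        raise NonConvergedEquilibriumError(eq.residual)
    return eq


def functional_response(
    model: TransitionModel,
    rates: DemographyRates,
    X: float,
    Y: float,
    eq: Optional[FastEquilibrium] = None,
    **solver_kwargs,
) -> float:
    """Average number of prey captured per predator per unit time."""
    if Y <= 0:
        raise ValueError("functional response is undefined at Y = 0")
    eq = _equilibrium(model, X, Y, eq, **solver_kwargs)
    return float(eq.x_hat @ rates.beta @ eq.y_hat) / Y


def prey_numerical_response(
    model: TransitionModel,
    rates: DemographyRates,
    X: float,
    Y: float,
    eq: Optional[FastEquilibrium] = None,
    **solver_kwargs,
) -> float:
    """Per-capita net growth rate of the prey from births and natural deaths."""
    if X <= 0:
        raise ValueError("prey numerical response is undefined at X = 0")
    eq = _equilibrium(model, X, Y, eq, **solver_kwargs)
    return float((rates.lam - rates.mu) @ eq.x_hat) / X


def predator_numerical_response(
    model: TransitionModel,
    rates: DemographyRates,
    X: float,
    Y: float,
    eq: Optional[FastEquilibrium] = None,
    **solver_kwargs,
) -> PredatorResponse:
    """Conversion factor, mortality factor and per-capita birth rate."""
    if Y <= 0:
        raise ValueError("predator numerical response is undefined at Y = 0")
    eq = _equilibrium(model, X, Y, eq, **solver_kwargs)
    captures = float(eq.x_hat @ rates.beta @ eq.y_hat)
    births = float(
        eq.x_hat @ (rates.gamma * rates.beta) @ eq.y_hat
        + rates.pred_birth @ eq.y_hat
    )
    f = captures / Y
    birth_rate = births / Y
    gamma_factor = births / captures if f > 0 else None
    delta_factor = float(rates.delta @ eq.y_hat) / Y
    return PredatorResponse(
        gamma_factor=gamma_factor,
        delta_factor=delta_factor,
        birth_rate=birth_rate,
    )


@dataclass
class ResponseSurface:
    """Responses evaluated on the product grid ``X_grid x Y_grid``.

    All matrices have shape ``(len(X_grid), len(Y_grid))``; ``gamma`` is
    NaN where the conversion factor is undefined (no captures) and every
    non-converged cell is flagged in ``converged`` rather than filled.
    """

    X_grid: np.ndarray
    Y_grid: np.ndarray
    f: np.ndarray
    g: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    net: np.ndarray
    converged: np.ndarray


def response_surface(
    model: TransitionModel,
    rates: DemographyRates,
    X_grid,
    Y_grid,
    **solver_kwargs,
) -> ResponseSurface:
    """Sweep the responses over an ``(X, Y)`` grid.

    Cells are solved with the nonlinear solver warm-started from the
    previous cell along the row, which keeps the iteration on the same
    equilibrium branch and amortises the solve cost.
    """
    X_grid = np.asarray(X_grid, dtype=float)
    Y_grid = np.asarray(Y_grid, dtype=float)
    for name, grid in (("X_grid", X_grid), ("Y_grid", Y_grid)):
        if grid.ndim != 1 or grid.size == 0 or np.any(grid <= 0):
            raise ValueError(f"{name} must be a nonempty vector of positive values")
        if grid.size > 1 and np.any(np.diff(grid) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    shape = (X_grid.size, Y_grid.size)
    f = np.full(shape, np.nan)
    g = np.full(shape, np.nan)
    gamma = np.full(shape, np.nan)
    delta = np.full(shape, np.nan)
    net = np.full(shape, np.nan)
    converged = np.zeros(shape, dtype=bool)

    warm_x = warm_y = None
    for ix, X in enumerate(X_grid):
        for iy, Y in enumerate(Y_grid):
            eq = solve_nonlinear(
                model, X, Y, x0=warm_x, y0=warm_y, **solver_kwargs
            )
            converged[ix, iy] = eq.converged
            if not eq.converged:
                continue
            warm_x, warm_y = eq.x_hat, eq.y_hat
            f[ix, iy] = functional_response(model, rates, X, Y, eq=eq)
            g[ix, iy] = prey_numerical_response(model, rates, X, Y, eq=eq)
            pr = predator_numerical_response(model, rates, X, Y, eq=eq)
            gamma[ix, iy] = np.nan if pr.gamma_factor is None else pr.gamma_factor
            delta[ix, iy] = pr.delta_factor
            net[ix, iy] = pr.net
    return ResponseSurface(
        X_grid=X_grid,
        Y_grid=Y_grid,
        f=f,
        g=g,
        gamma=gamma,
        delta=delta,
        net=net,
        converged=converged,
    )
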