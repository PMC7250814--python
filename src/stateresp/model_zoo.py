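"""Builders and closed-form evaluators for the worked model applications.

Each builder returns a :class:`ZooModel` bundling the generic
:class:`~stateresp.core_model.TransitionModel` /
:class:`~stateresp.core_model.DemographyRates` representation with the
model's closed-form equilibrium and responses, so the generic solver path
can always be cross-validated against the analytic one.

Models
------
tiered_prey
    Prey move up a ladder of protection states at predator-density-
    proportional rates and relax back spontaneously; two-state
    searching/handling predator.  ``m = 1`` is Holling II, ``m = 2`` is a
    generalised Beddington-DeAngelis response.
dd_handling
    One prey state; handling predators abandon the carcass at a
    prey-density-dependent rate, giving a Holling II response with
    density-dependent handling time.
starvation
    Searching predators split into well-fed and starving classes with
    different attack rates, fecundities and mortalities; yields a
    type III functional response with non-constant conversion and
    mortality factors.
experience
    Same functional response as ``starvation``, reinterpreted as
    experienced/inexperienced searchers with a single handling class.
panic
    Two prey states (exposed/protected) and two predator states
    (searching/handling) with fully coupled transitions; induces an Allee
    effect in the predator's slow dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

from .core_model import DemographyRates, TransitionModel

__all__ = [
    "ZooModel",
    "tiered_prey",
    "two_state_prey",
    "dd_handling",
    "starvation",
    "experience",
    "panic",
    "two_state_prey_closed_forms",
    "two_state_prey_f_as_printed",
    "dd_handling_closed_forms",
    "starvation_closed_forms",
    "experience_closed_forms",
    "panic_closed_forms",
    "holling_bd_mappings",
    "CanonicalResponse",
    "ZOO_BUILDERS",
]


@dataclass
class ZooModel:
    """A named application model with closed-form reference evaluators."""

    name: str
    params: Dict[str, float]
    model: TransitionModel
    rates: DemographyRates
    closed_f: Callable[[float, float], float]
    closed_equilibrium: Optional[
        Callable[[float, float], Tuple[np.ndarray, np.ndarray]]
    ] = None
    closed_gamma: Optional[Callable[[float, float], Optional[float]]] = None
    closed_delta: Optional[Callable[[float, float], float]] = None
    closed_gamma_f: Optional[Callable[[float, float], float]] = None
    extras: Dict[str, Callable] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tiered prey ladder (Holling II at m=1, generalised Beddington-DeAngelis
# at m=2)
# ---------------------------------------------------------------------------


def tiered_prey(
    m: int,
    A_spont: Sequence[float],
    A_pred: Sequence[float],
    c: Sequence[float],
    d: float,
) -> ZooModel:
    """Prey protection ladder with a searching/handling predator.

    Parameters
    ----------
    m : int
        Number of prey states.
    A_spont : (m-1,) array_like
        Spontaneous relaxation rates from state ``k+1`` back to ``k``.
    A_pred : (m-1,) array_like
        Per-predator-density escalation rates from state ``k`` to ``k+1``
        (the actual rate is ``A_pred[k] * Y``).
    c : (m,) array_like
        Attack rate of searching predators on each prey state.
    d : float
        Handling-completion rate (``1/d`` is the mean handling time).
    """
    A_spont = np.asarray(A_spont, dtype=float)
    A_pred = np.asarray(A_pred, dtype=float)
    c = np.asarray(c, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if A_spont.shape != (m - 1,) or A_pred.shape != (m - 1,):
        raise ValueError("A_spont and A_pred must have length m - 1")
    if c.shape != (m,):
        raise ValueError("c must have length m")
    if m > 1 and (np.any(A_spont <= 0) or np.any(A_pred <= 0)):
        raise ValueError("ladder rates must be strictly positive")
    if d <= 0 or np.any(c < 0):
        raise ValueError("rates must be positive")

    n = 2  # searching, handling
    A = np.zeros((m, m))
    for k in range(m - 1):
        A[k, k + 1] += A_spont[k]
        A[k + 1, k + 1] -= A_spont[k]
    B = np.zeros((m, m, n))
    for k in range(m - 1):
        for j in range(n):  # escalation driven by the *total* predator density
            B[k + 1, k, j] += A_pred[k]
            B[k, k, j] -= A_pred[k]
    C = np.zeros((n, n, m))
    for i in range(m):
        C[1, 0, i] += c[i]
        C[0, 0, i] -= c[i]
    D = np.zeros((n, n))
    D[0, 1] += d
    D[1, 1] -= d
    model = TransitionModel(A=A, B=B, C=C, D=D, relaxed=True)
    rates = DemographyRates(
        beta=np.column_stack([c, np.zeros(m)]),
        lam=np.zeros(m),
        mu=np.zeros(m),
        gamma=np.zeros((m, n)),
        delta=np.zeros(n),
        pred_birth=np.array([0.0, 1.0]),  # only handlers reproduce
    )

    ratios = np.concatenate([[1.0], np.cumprod(A_pred / A_spont)]) if m > 1 else np.array([1.0])

    def weights(Y: float) -> np.ndarray:
        return ratios * Y ** np.arange(m)

    def closed_equilibrium(X: float, Y: float) -> Tuple[np.ndarray, np.ndarray]:
        w = weights(Y)
        x_hat = X * w / w.sum()
        cx = float(c @ x_hat)
        S = Y / (1.0 + cx / d)
        return x_hat, np.array([S, Y - S])

    def closed_f(X: float, Y: float) -> float:
        w = weights(Y)
        cw = float(c @ w)
        return X * cw / (w.sum() + (X / d) * cw)

    def closed_gamma_f(X: float, Y: float) -> float:
        return closed_f(X, Y) / d  # handler occupancy

    return ZooModel(
        name="tiered",
        params={
            "m": m,
            "A_spont": A_spont,
            "A_pred": A_pred,
            "c": c,
            "d": d,
        },
        model=model,
        rates=rates,
        closed_f=closed_f,
        closed_equilibrium=closed_equilibrium,
        closed_gamma_f=closed_gamma_f,
    )


def two_state_prey(A12: float, A1: float, c1: float, c2: float, d: float) -> ZooModel:
    """Two-state prey ladder (generalised Beddington-DeAngelis response)."""
    zm = tiered_prey(2, [A12], [A1], [c1, c2], d)
    zm.name = "two_state_prey"
    zm.params = {"A12": A12, "A1": A1, "c1": c1, "c2": c2, "d": d}
    return zm


def two_state_prey_closed_forms(
    A12: float, A1: float, c1: float, c2: float, d: float, X: float, Y: float
) -> Tuple[float, float, float]:
    """Closed-form prey equilibrium and functional response at ``m = 2``.

    Returns ``(x1_hat, x2_hat, f2)`` with the algebraically consistent
    response ``f2 = cx / (1 + cx / d)``, ``cx = c1 x1_hat + c2 x2_hat``.
    """
    denom = A12 + A1 * Y
    x1 = A12 * X / denom
    x2 = A1 * Y * X / denom
    cx = c1 * x1 + c2 * x2
    return x1, x2, cx / (1.0 + cx / d)


def two_state_prey_f_as_printed(
    A12: float, A1: float, c1: float, c2: float, d: float, X: float, Y: float
) -> float:
    """The response exactly as printed in the source derivation.

    Kept for comparison only: its numerator carries an extra overall
    factor ``A12`` relative to the internally consistent form, so the two
    agree only when ``A12 == 1``.
    """
    num = c1 * A12 * X + c2 * A1 * X * Y
    den = 1.0 + (A1 / A12) * Y + c1 * X / d + (c2 * A1 / (A12 * d)) * X * Y
    return num / den


# ---------------------------------------------------------------------------
# density-dependent handling time
# ---------------------------------------------------------------------------


def dd_handling(c1: float, c2: float, d: float) -> ZooModel:
    """Holling II with prey-density-dependent handling time ``1/(c2 X + d)``."""
    if c1 <= 0 or c2 < 0 or d <= 0:
        raise ValueError("rates must be positive (c2 may be zero)")
    A = np.zeros((1, 1))
    B = np.zeros((1, 1, 2))
    C = np.zeros((2, 2, 1))
    C[1, 0, 0] = c1
    C[0, 0, 0] = -c1
    C[0, 1, 0] = c2
    C[1, 1, 0] = -c2
    D = np.zeros((2, 2))
    D[0, 1] = d
    D[1, 1] = -d
    model = TransitionModel(A=A, B=B, C=C, D=D, relaxed=True)
    rates = DemographyRates(
        beta=np.array([[c1, 0.0]]),
        lam=np.zeros(1),
        mu=np.zeros(1),
        gamma=np.zeros((1, 2)),
        delta=np.zeros(2),
        pred_birth=np.array([0.0, 1.0]),
    )

    def closed_equilibrium(X: float, Y: float) -> Tuple[np.ndarray, np.ndarray]:
        S, H, _, _ = dd_handling_closed_forms(c1, c2, d, X)
        return np.array([X]), Y * np.array([S, H])

    def closed_f(X: float, _Y: float) -> float:
        return dd_handling_closed_forms(c1, c2, d, X)[2]

    def closed_gamma(X: float, _Y: float) -> float:
        return dd_handling_closed_forms(c1, c2, d, X)[3]

    return ZooModel(
        name="dd_handling",
        params={"c1": c1, "c2": c2, "d": d},
        model=model,
        rates=rates,
        closed_f=closed_f,
        closed_equilibrium=closed_equilibrium,
        closed_gamma=closed_gamma,
        closed_gamma_f=lambda X, Y: closed_gamma(X, Y) * closed_f(X, Y),
    )


def dd_handling_closed_forms(
    c1: float, c2: float, d: float, X: float
) -> Tuple[float, float, float, float]:
    """``(S_hat/Y, H_hat/Y, f, gamma)`` for the density-dependent-handling model."""
    denom = d + (c1 + c2) * X
    s_frac = (d + c2 * X) / denom
    h_frac = c1 * X / denom
    f = c1 * X * (c2 * X + d) / denom
    gamma = 1.0 / (c2 * X + d)
    return s_frac, h_frac, f, gamma


# ---------------------------------------------------------------------------
# starvation-structured searchers (type III response)
# ---------------------------------------------------------------------------


def _starvation_denominator(c1, c2, d1, d2, X):
    return d2 * (1.0 + c2 * X / d1) + c2 * X * (1.0 + c1 * X / d1)


def starvation(
    c1: float,
    c2: float,
    d1: float,
    d2: float,
    Gamma1: float = 1.0,
    Gamma2: float = 1.0,
    delta1: float = 0.0,
    delta2: float = 0.0,
) -> ZooModel:
    """Well-fed / starving searchers with separate handling classes.

    Predator states are ordered ``(S1, S2, H1, H2)``: well-fed searchers
    attack at ``c1``, starving searchers at ``c2``; handlers of either
    origin finish at ``d1`` (returning to ``S1``) and well-fed searchers
    decay to starving at ``d2``.  Fecundities ``Gamma1``/``Gamma2``
    attach to the ``H1``/``H2`` occupancies, mortalities
    ``delta1``/``delta2`` to ``S1``/``S2``; offspring start starving.
    """
    if min(c1, c2, d1, d2) <= 0:
        raise ValueError("c1, c2, d1, d2 must be strictly positive")
    A = np.zeros((1, 1))
    B = np.zeros((1, 1, 4))
    C = np.zeros((4, 4, 1))
    C[2, 0, 0] = c1  # S1 -> H1 on prey encounter
    C[0, 0, 0] = -c1
    C[3, 1, 0] = c2  # S2 -> H2
    C[1, 1, 0] = -c2
    D = np.zeros((4, 4))
    D[1, 0] = d2  # S1 -> S2 (getting hungry)
    D[0, 0] = -d2
    D[0, 2] = d1  # H1 -> S1
    D[2, 2] = -d1
    D[0, 3] = d1  # H2 -> S1
    D[3, 3] = -d1
    model = TransitionModel(A=A, B=B, C=C, D=D, relaxed=True)
    rates = DemographyRates(
        beta=np.array([[c1, c2, 0.0, 0.0]]),
        lam=np.zeros(1),
        mu=np.zeros(1),
        gamma=np.zeros((1, 4)),
        delta=np.array([delta1, delta2, 0.0, 0.0]),
        pred_birth=np.array([0.0, 0.0, Gamma1, Gamma2]),
        pred_offspring=np.array([0.0, 1.0, 0.0, 0.0]),
    )

    def closed_equilibrium(X: float, Y: float) -> Tuple[np.ndarray, np.ndarray]:
        cf = starvation_closed_forms(
            c1, c2, d1, d2, Gamma1, Gamma2, delta1, delta2, X
        )
        return np.array([X]), Y * np.asarray(cf["equilibrium"])

    def closed(X, key):
        return starvation_closed_forms(
            c1, c2, d1, d2, Gamma1, Gamma2, delta1, delta2, X
        )[key]

    return ZooModel(
        name="starvation",
        params={
            "c1": c1,
            "c2": c2,
            "d1": d1,
            "d2": d2,
            "Gamma1": Gamma1,
            "Gamma2": Gamma2,
            "delta1": delta1,
            "delta2": delta2,
        },
        model=model,
        rates=rates,
        closed_f=lambda X, Y: closed(X, "f"),
        closed_equilibrium=closed_equilibrium,
        closed_gamma=lambda X, Y: closed(X, "gamma"),
        closed_delta=lambda X, Y: closed(X, "delta"),
        closed_gamma_f=lambda X, Y: closed(X, "gamma_f"),
    )


def starvation_closed_forms(
    c1: float,
    c2: float,
    d1: float,
    d2: float,
    Gamma1: float,
    Gamma2: float,
    delta1: float,
    delta2: float,
    X: float,
) -> Dict[str, object]:
    """All closed forms of the starvation model at prey density ``X``.

    Returns a dict with keys ``equilibrium`` (per-unit-Y 4-vector over
    ``(S1, S2, H1, H2)``), ``f``, ``gamma``, ``gamma_f``, ``delta`` and
    ``is_type3`` (the small-``X`` convexity criterion
    ``c1/c2 > 1 + d2/d1``).
    """
    denom = _starvation_denominator(c1, c2, d1, d2, X)
    s1 = c2 * X / denom
    s2 = d2 / denom
    h1 = (c1 * c2 / d1) * X * X / denom
    h2 = (c2 * d2 / d1) * X / denom
    f = c2 * X * (d2 + c1 * X) / denom
    gamma = (Gamma1 * c1 * X + Gamma2 * d2) / (d1 * (d2 + c1 * X))
    gamma_f = (c2 * X / d1) * (Gamma1 * c1 * X + Gamma2 * d2) / denom
    delta = (delta1 * c2 * X + delta2 * d2) / denom
    return {
        "equilibrium": np.array([s1, s2, h1, h2]),
        "f": f,
        "gamma": gamma,
        "gamma_f": gamma_f,
        "delta": delta,
        "is_type3": c1 / c2 > 1.0 + d2 / d1,
    }


def experience(c1: float, c2: float, d1: float, d2: float) -> ZooModel:
    """Experience-structured searchers: same response, single handler class.

    Predator states ``(S1, S2, H)``: experienced searchers (``S1``)
    attack at ``c1``, inexperienced (``S2``) at ``c2``; both enter ``H``
    on capture, handlers finish at ``d1`` into ``S1``, and experience is
    lost at ``d2``.
    """
    if min(c1, c2, d1, d2) <= 0:
        raise ValueError("c1, c2, d1, d2 must be strictly positive")
    A = np.zeros((1, 1))
    B = np.zeros((1, 1, 3))
    C = np.zeros((3, 3, 1))
    C[2, 0, 0] = c1
    C[0, 0, 0] = -c1
    C[2, 1, 0] = c2
    C[1, 1, 0] = -c2
    D = np.zeros((3, 3))
    D[1, 0] = d2
    D[0, 0] = -d2
    D[0, 2] = d1
    D[2, 2] = -d1
    model = TransitionModel(A=A, B=B, C=C, D=D, relaxed=True)
    rates = DemographyRates(
        beta=np.array([[c1, c2, 0.0]]),
        lam=np.zeros(1),
        mu=np.zeros(1),
        gamma=np.zeros((1, 3)),
        delta=np.zeros(3),
        pred_birth=np.array([0.0, 0.0, 1.0]),
    )

    def closed_equilibrium(X: float, Y: float) -> Tuple[np.ndarray, np.ndarray]:
        s1, s2, h = experience_closed_forms(c1, c2, d1, d2, X)
        return np.array([X]), Y * np.array([s1, s2, h])

    def closed_f(X: float, _Y: float) -> float:
        denom = _starvation_denominator(c1, c2, d1, d2, X)
        return c2 * X * (d2 + c1 * X) / denom

    return ZooModel(
        name="experience",
        params={"c1": c1, "c2": c2, "d1": d1, "d2": d2},
        model=model,
        rates=rates,
        closed_f=closed_f,
        closed_equilibrium=closed_equilibrium,
    )


def experience_closed_forms(
    c1: float, c2: float, d1: float, d2: float, X: float
) -> Tuple[float, float, float]:
    """``(S1_hat/Y, S2_hat/Y, H_hat/Y)`` for the experience model."""
    denom = _starvation_denominator(c1, c2, d1, d2, X)
    s1 = c2 * X / denom
    s2 = d2 / denom
    h = (c1 * c2 * X * X / d1 + c2 * d2 * X / d1) / denom
    return s1, s2, h


# ---------------------------------------------------------------------------
# panic model (fully coupled two-by-two states, predator Allee effect)
# ---------------------------------------------------------------------------


def panic(
    a: float,
    b: float,
    c: float,
    d: float,
    delta1: float = 0.0,
    delta2: float = 0.0,
    mu1: float = 0.0,
    mu2: float = 0.0,
    lam_P: float = 0.0,
) -> ZooModel:
    """Exposed/protected prey against searching/handling predators.

    Prey states ``(E, P)``: exposed prey seek protection spontaneously at
    rate ``a``; searching predators flush protected prey out at
    per-predator rate ``b``.  Predator states ``(S, H)``: searchers
    capture exposed prey at rate ``c`` and handle for ``1/d`` on average.
    Only protected prey reproduce (rate ``lam_P``) and only handlers give
    birth; ``mu1``/``mu2`` and ``delta1``/``delta2`` are the per-state
    natural mortalities.
    """
    if min(a, b, c, d) <= 0:
        raise ValueError("a, b, c, d must be strictly positive")
    A = np.array([[-a, 0.0], [a, 0.0]])
    B = np.zeros((2, 2, 2))
    B[0, 1, 0] = b  # P -> E flushed out by searchers
    B[1, 1, 0] = -b
    C = np.zeros((2, 2, 2))
    C[1, 0, 0] = c  # S -> H on catching an exposed prey
    C[0, 0, 0] = -c
    D = np.array([[0.0, d], [0.0, -d]])
    model = TransitionModel(A=A, B=B, C=C, D=D, relaxed=True)
    rates = DemographyRates(
        beta=np.array([[c, 0.0], [0.0, 0.0]]),
        lam=np.array([0.0, lam_P]),
        mu=np.array([mu1, mu2]),
        gamma=np.zeros((2, 2)),
        delta=np.array([delta1, delta2]),
        pred_birth=np.array([0.0, 1.0]),
        prey_offspring=np.array([0.0, 1.0]),
        pred_offspring=np.array([1.0, 0.0]),
    )

    def closed_equilibrium(X: float, Y: float) -> Tuple[np.ndarray, np.ndarray]:
        cf = panic_closed_forms(a, b, c, d, X, Y, delta1, delta2, mu1, mu2)
        return (
            np.array([cf["E"], cf["P"]]),
            np.array([cf["S"], cf["H"]]),
        )

    def closed_f(X: float, Y: float) -> float:
        return panic_closed_forms(a, b, c, d, X, Y)["f"]

    def closed_delta(X: float, Y: float) -> float:
        return panic_closed_forms(a, b, c, d, X, Y, delta1, delta2)["pred_death"]

    return ZooModel(
        name="panic",
        params={
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "delta1": delta1,
            "delta2": delta2,
            "mu1": mu1,
            "mu2": mu2,
            "lam_P": lam_P,
        },
        model=model,
        rates=rates,
        closed_f=closed_f,
        closed_equilibrium=closed_equilibrium,
        closed_delta=closed_delta,
        closed_gamma_f=lambda X, Y: closed_f(X, Y) / d,
    )


def panic_closed_forms(
    a: float,
    b: float,
    c: float,
    d: float,
    X: float,
    Y: float,
    delta1: float = 0.0,
    delta2: float = 0.0,
    mu1: float = 0.0,
    mu2: float = 0.0,
) -> Dict[str, float]:
    """Closed-form equilibrium and responses of the panic model.

    Uses ``p = a/b``, ``q = d/c`` and the discriminant
    ``Delta = q (p^2 q + 2 p (q + 2X) Y + q Y^2)``.  The equilibrium is
    evaluated in conjugate (cancellation-free) form::

        E_hat = 2 q X Y / (q (p + Y) + sqrt(Delta))
        H_hat = 2 X Y^2 / (p q + q Y + 2 X Y + sqrt(Delta))

    which is algebraically identical to the quadratic-root expressions
    but stable at small ``X`` or ``Y``.
    """
    if X < 0 or Y < 0 or (X == 0 and Y == 0):
        raise ValueError("X, Y must be nonnegative and not both zero")
    p = a / b
    q = d / c
    disc = q * (p * p * q + 2.0 * p * (q + 2.0 * X) * Y + q * Y * Y)
    s = math.sqrt(disc)
    E = 2.0 * q * X * Y / (q * (p + Y) + s)
    P = X - E
    H = 2.0 * X * Y * Y / (p * q + q * Y + 2.0 * X * Y + s)
    S = Y - H
    h_frac = 2.0 * X * Y / (p * q + q * Y + 2.0 * X * Y + s)  # H/Y, Y-safe
    f = d * h_frac
    out: Dict[str, float] = {
        "E": E,
        "P": P,
        "S": S,
        "H": H,
        "f": f,
        "pred_birth_prop": h_frac,
        "pred_death": delta1 * (1.0 - f / d) + delta2 * (f / d),
    }
    if X > 0:
        out["prey_birth_prop"] = P / X
        out["prey_death"] = mu1 * E / X + mu2 * P / X
    return out


# ---------------------------------------------------------------------------
# canonical-form coefficient mappings
# ---------------------------------------------------------------------------


@dataclass
class CanonicalResponse:
    """Coefficients of a textbook functional-response form plus evaluator."""

    kind: str
    coefficients: Dict[str, float]
    evaluate: Callable[..., float]
    as_printed: Optional[Dict[str, float]] = None


def holling_bd_mappings(kind: str, params: Dict[str, float]) -> CanonicalResponse:
    """Map mechanistic parameters onto canonical response coefficients.

    ``kind`` is one of ``"holling2"`` (needs ``c1, d``; form
    ``aX/(1+bX)``), ``"holling3"`` (needs ``c1, c2, d1, d2``; form
    ``(aX+bX^2)/(1+cX+dX^2)``) or ``"beddington_deangelis"`` (needs
    ``A12, A1, c1, d``; form ``aX/(1+bX+cY)``).
    """
    if kind == "holling2":
        c1, d = params["c1"], params["d"]
        coeffs = {"a": c1, "b": c1 / d}

        def evaluate(X, Y=None, _c=coeffs):
            return _c["a"] * X / (1.0 + _c["b"] * X)

        return CanonicalResponse("holling2", coeffs, evaluate)
    if kind == "holling3":
        c1, c2, d1, d2 = params["c1"], params["c2"], params["d1"], params["d2"]
        coeffs = {
            "a": c2,
            "b": c1 * c2 / d2,
            "c": c2 * (1.0 / d1 + 1.0 / d2),
            "d": c1 * c2 / (d1 * d2),
        }

        def evaluate(X, Y=None, _c=coeffs):
            return (_c["a"] * X + _c["b"] * X * X) / (
                1.0 + _c["c"] * X + _c["d"] * X * X
            )

        return CanonicalResponse("holling3", coeffs, evaluate)
    if kind == "beddington_deangelis":
        A12, A1, c1, d = params["A12"], params["A1"], params["c1"], params["d"]
        coeffs = {"a": c1, "b": c1 / d, "c": A1 / A12}

        def evaluate(X, Y, _c=coeffs):
            return _c["a"] * X / (1.0 + _c["b"] * X + _c["c"] * Y)

        # the printed mapping carries the same spurious A12 factor in `a`
        # as the printed two-state response
        return CanonicalResponse(
            "beddington_deangelis",
            coeffs,
            evaluate,
            as_printed={"a": c1 * A12, "b": c1 / d, "c": A1 / A12},
        )
    raise ValueError(f"unknown canonical response kind: {kind!r}")


#: Builders addressable by name (used by the CLI).
ZOO_BUILDERS: Dict[str, Callable[..., ZooModel]] = {
    "tiered": tiered_prey,
    "two_state_prey": two_state_prey,
    "dd_handling": dd_handling,
    "starvation": starvation,
    "experience": experience,
    "panic": panic,
}
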