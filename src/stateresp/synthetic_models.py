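"""Random consistency-valid models and curated degenerate fixtures."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np

from .core_model import TransitionModel

__all__ = ["random_model", "degenerate_fixtures"]


def _random_conservative(
    rng: np.random.Generator, k: int, density: float, rate_scale: float
) -> np.ndarray:
    """Random transition-rate matrix, irreducible via a random spanning cycle."""
    M = np.zeros((k, k))
    if k == 1:
        return M
    mask = rng.random((k, k)) < density
    np.fill_diagonal(mask, False)
    M[mask] = rate_scale * rng.uniform(0.1, 1.0, size=int(mask.sum()))
    # spanning cycle guarantees strong connectivity (and negative diagonals)
    perm = rng.permutation(k)
    for idx in range(k):
        src = perm[idx]
        dst = perm[(idx + 1) % k]
        M[dst, src] += rate_scale * rng.uniform(0.1, 1.0)
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, -M.sum(axis=0))
    return M


def _random_mediated(
    rng: np.random.Generator, k: int, n_med: int, density: float, rate_scale: float
) -> np.ndarray:
    """Random mediated-transition tensor with exact column-sum-zero slices."""
    T = np.zeros((k, k, n_med))
    if k == 1:
        return T
    for j in range(n_med):
        mask = rng.random((k, k)) < density
        np.fill_diagonal(mask, False)
        slice_ = np.zeros((k, k))
        slice_[mask] = rate_scale * rng.uniform(0.1, 1.0, size=int(mask.sum()))
        np.fill_diagonal(slice_, -slice_.sum(axis=0))
        T[:, :, j] = slice_
    return T


def random_model(
    m: int,
    n: int,
    density: float = 0.5,
    rate_scale: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TransitionModel:
    """Draw a random consistency-valid, irreducible transition model.

    Spontaneous matrices always contain a random spanning cycle, so the
    effective matrices are irreducible for every nonnegative mediating
    state.  The same seed reproduces the same model exactly.
    """
    if m < 1 or n < 1:
        raise ValueError("m, n must be >= 1")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    A = _random_conservative(rng, m, density, rate_scale)
    D = _random_conservative(rng, n, density, rate_scale)
    B = _random_mediated(rng, m, n, density, rate_scale)
    C = _random_mediated(rng, n, m, density, rate_scale)
    relaxed = m == 1 or n == 1  # single-state species has a zero diagonal
    return TransitionModel(A=A, B=B, C=C, D=D, relaxed=relaxed)


def degenerate_fixtures() -> Dict[str, Dict[str, object]]:
    """Curated pathological fixtures for exercising failure paths.

    Returns a name-keyed dict, each entry holding a ``model`` and a
    description of the expected behaviour:

    * ``"free"`` — all transition rates zero (relaxed): every point of
      the state space is an equilibrium, so a uniqueness probe must
      report several distinct ones.
    * ``"reducible"`` — the prey chain splits into two disconnected
      components; the linear stationary solve must raise.
    * ``"empty_prey"`` — a well-behaved model intended to be solved at
      ``X = 0``, where the prey distribution collapses to zero.
    """
    free = TransitionModel(
        A=np.zeros((2, 2)),
        B=np.zeros((2, 2, 2)),
        C=np.zeros((2, 2, 2)),
        D=np.zeros((2, 2)),
        relaxed=True,
    )
    A_red = np.zeros((4, 4))
    A_red[0, 1] = A_red[1, 0] = 1.0
    A_red[2, 3] = A_red[3, 2] = 2.0
    np.fill_diagonal(A_red, 0.0)
    np.fill_diagonal(A_red, -A_red.sum(axis=0))
    reducible = TransitionModel(
        A=A_red,
        B=np.zeros((4, 4, 2)),
        C=np.zeros((2, 2, 4)),
        D=np.array([[-1.0, 1.0], [1.0, -1.0]]),
    )
    C_bp = np.zeros((2, 2, 1))
    C_bp[1, 0, 0] = 1.0
    C_bp[0, 0, 0] = -1.0
    boundary = TransitionModel(
        A=np.zeros((1, 1)),
        B=np.zeros((1, 1, 2)),
        C=C_bp,
        D=np.array([[0.0, 1.0], [0.0, -1.0]]),
        relaxed=True,
    )
    return {
        "free": {
            "model": free,
            "expect": "multiple distinct equilibria from a uniqueness probe",
        },
        "reducible": {
            "model": reducible,
            "expect": "ReducibleMatrixError from the linear stationary solve",
        },
        "empty_prey": {
            "model": boundary,
            "expect": "x_hat == 0 when solved at X = 0",
            "totals": (0.0, 1.0),
        },
    }
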