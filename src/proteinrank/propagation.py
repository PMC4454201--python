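"""Random walk with restart (RWR) on a column-stochastic transition matrix.

The walk iterates

    p_{t+1} = (1 - r) * W @ p_t + r * p0

from ``p_0 = p0`` until the L1 change falls below a tolerance.  Its fixed
point solves the linear system ``(I - (1 - r) W) p = r p0``, which
:func:`rwr_exact` computes directly; the two backends cross-check each other
and the direct solve doubles as the batch backend for computing many walks
on one network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import TransitionMatrix

__all__ = ["WalkConfig", "StationaryVector", "rwr", "rwr_exact", "rwr_batch"]


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the restart walk.

    restart_prob is the per-step probability of teleporting back to the
    start distribution (0.4 by default, the value used throughout the drug
    resistance study this package reimplements); tol is the L1 convergence
    threshold; max_iter bounds the iteration count.
    """

    restart_prob: float = 0.4
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError(f"restart_prob must be in (0, 1], got {self.restart_prob}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class StationaryVector:
    """Converged importance vector of one restart walk."""

    values: np.ndarray
    iterations_used: int
    converged: bool


def _check_inputs(W: TransitionMatrix, p0: np.ndarray) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float).ravel()
    if W.matrix.shape[0] != p0.shape[0]:
        raise ValueError(
            f"dimension mismatch: W is {W.matrix.shape}, p0 has length {p0.shape[0]}"
        )
    if not np.all(np.isfinite(W.matrix.data)):
        raise ValueError("transition matrix contains non-finite entries")
    if not np.all(np.isfinite(p0)):
        raise ValueError("start vector contains non-finite entries")
    if np.any(p0 < 0):
        raise ValueError("start vector has negative entries")
    s = p0.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"start vector must sum to 1, sums to {s}")
    return p0


def rwr(W: TransitionMatrix, p0: np.ndarray, cfg: WalkConfig) -> StationaryVector:
    """Iterative restart walk from distribution ``p0``."""
    p0 = _check_inputs(W, p0)
    r = cfg.restart_prob
    if r == 1.0:
        return StationaryVector(values=p0.copy(), iterations_used=0, converged=True)
    M = W.matrix
    p = p0.copy()
    for it in range(1, cfg.max_iter + 1):
        p_next = (1.0 - r) * (M @ p) + r * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.tol:
            return StationaryVector(values=p, iterations_used=it, converged=True)
    warnings.warn(
        f"RWR did not converge in {cfg.max_iter} iterations (last L1 step {delta:.3e})",
        RuntimeWarning,
        stacklevel=2,
    )
    return StationaryVector(values=p, iterations_used=cfg.max_iter, converged=False)


def rwr_exact(W: TransitionMatrix, p0: np.ndarray, r: float) -> StationaryVector:
    """Direct solve of the fixed point ``(I - (1-r) W) p = r p0``."""
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    p0 = _check_inputs(W, p0)
    if r == 1.0:
        return StationaryVector(values=p0.copy(), iterations_used=0, converged=True)
    A = _system_matrix(W, r)
    p = spla.spsolve(A, r * p0)
    return StationaryVector(values=np.asarray(p).ravel(), iterations_used=0, converged=True)


def _system_matrix(W: TransitionMatrix, r: float) -> sp.csc_matrix:
    n = W.n
    return (sp.identity(n, format="csc") - (1.0 - r) * W.matrix).tocsc()


def rwr_batch(
    W: TransitionMatrix, starts: list[np.ndarray], cfg: WalkConfig
) -> list[StationaryVector]:
    """Solve many walks on one network, factorizing the system once.

    Elementwise equivalent to mapping :func:`rwr` over ``starts`` (both
    compute the same fixed point; the batch path solves it exactly).
    """
    r = cfg.restart_prob
    checked = [_check_inputs(W, p0) for p0 in starts]
    if r == 1.0:
        return [
            StationaryVector(values=p0.copy(), iterations_used=0, converged=True)
            for p0 in checked
        ]
    lu = spla.splu(_system_matrix(W, r))
    out = []
    for p0 in checked:
        p = lu.solve(r * p0)
        out.append(StationaryVector(values=p, iterations_used=0, converged=True))
    return out


def impact_vector_matrix(W: TransitionMatrix, r: float) -> np.ndarray:
    """Dense matrix whose column u is the walk started from the unit vector e_u.

    Equals ``r * (I - (1-r) W)^{-1}`` and stacks every node's impact vector;
    practical for networks up to a few thousand nodes.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability must be in (0, 1], got {r}")
    n = W.n
    if r == 1.0:
        return np.eye(n)
    lu = spla.splu(_system_matrix(W, r))
    return lu.solve(r * np.eye(n))
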