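"""Derivative-free pattern search for ODE parameter estimation.

Generalized pattern search with coordinate polling on a box-constrained,
internally normalized domain: poll the 2d axial neighbors of the incumbent
at the current mesh size, move to the best improving point (expanding the
mesh), otherwise contract.  Deterministic given the start point; no
gradients, which suits noisy simulate-and-compare objectives.

An optional batched objective evaluates a whole poll set in one call so the
underlying simulator can vectorize over candidate parameter vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class PatternSearchResult:
    x: np.ndarray
    fun: float
    nfev: int
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)  # (nfev, best objective) pairs


def pattern_search(
    fun: Callable[[np.ndarray], float],
    x0: Sequence[float],
    lower: Sequence[float],
    upper: Sequence[float],
    fun_batch: Callable[[np.ndarray], np.ndarray] | None = None,
    max_evals: int = 2000,
    mesh0: float = 0.25,
    mesh_tol: float = 1e-6,
    contraction: float = 0.5,
    expansion: float = 2.0,
) -> PatternSearchResult:
    """Minimize ``fun`` over the box [lower, upper].

    ``fun_batch``, if given, maps an (m, d) array of candidates to m
    objective values and is used to evaluate each poll set in one call.
    The search runs in [0, 1]-normalized coordinates; ``mesh0`` is the
    initial mesh as a fraction of each parameter's range.
    """
    lo = np.asarray(lower, dtype=float)
    hi = np.asarray(upper, dtype=float)
    if np.any(hi < lo):
        raise ValueError("upper < lower")
    span = np.where(hi > lo, hi - lo, 1.0)
    d = len(lo)

    def denorm(z):
        return lo + np.asarray(z) * span

    def eval_batch(Z):
        X = lo[None, :] + np.asarray(Z) * span[None, :]
        if fun_batch is not None:
            return np.asarray(fun_batch(X), dtype=float)
        return np.array([fun(x) for x in X], dtype=float)

    z = np.clip((np.asarray(x0, dtype=float) - lo) / span, 0.0, 1.0)
    f = float(eval_batch(z[None, :])[0])
    nfev = 1
    trace = [(nfev, f)]
    mesh = mesh0
    n_iter = 0
    while nfev < max_evals and mesh > mesh_tol:
        n_iter += 1
        polls = []
        for i in range(d):
            for s in (+1.0, -1.0):
                cand = z.copy()
                cand[i] = np.clip(cand[i] + s * mesh, 0.0, 1.0)
                if not np.allclose(cand, z):
                    polls.append(cand)
        if not polls:
            break
        Z = np.array(polls)
        F = eval_batch(Z)
        F = np.where(np.isfinite(F), F, np.inf)
        nfev += len(polls)
        k = int(np.argmin(F))
        if F[k] < f:
            z, f = Z[k], float(F[k])
            mesh = min(mesh * expansion, 0.5)
        else:
            mesh *= contraction
        trace.append((nfev, f))
    return PatternSearchResult(
        x=denorm(z), fun=f, nfev=nfev, n_iter=n_iter,
        converged=mesh <= mesh_tol, trace=trace,
    )
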