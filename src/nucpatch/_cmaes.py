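"""Minimal (mu/mu_w, lambda) CMA-ES minimizer.

Covariance Matrix Adaptation Evolution Strategy with rank-one and rank-mu
covariance updates and cumulative step-size adaptation, following the
standard tutorial formulation.  Deliberately small: dense covariance,
no restarts, no constraint handling beyond box clipping of candidates.
Deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["cmaes_minimize", "CMAESResult"]


@dataclass
class CMAESResult:
    x: np.ndarray
    fun: float
    history: np.ndarray  # best-so-far error per generation (non-increasing)
    n_gen: int
    converged: bool = True


def cmaes_minimize(
    f,
    x0,
    sigma0: float,
    generations: int = 200,
    popsize: int | None = None,
    bounds=None,
    seed: int = 0,
    ftarget: float = -np.inf,
) -> CMAESResult:
    """Minimize ``f`` starting from ``x0`` with initial step size ``sigma0``.

    ``bounds``, if given, is an (lb, ub) pair of arrays; candidates are
    clipped into the box before evaluation.  ``popsize`` defaults to the
    standard 4 + floor(3 ln n).  The returned history tracks the best
    objective value seen so far (elitist bookkeeping; the search itself is
    non-elitist).
    """
    rng = np.random.default_rng(seed)
    mean = np.asarray(x0, dtype=float).copy()
    n = mean.size
    sigma = float(sigma0)

    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)

    if bounds is not None:
        lb = np.asarray(bounds[0], dtype=float)
        ub = np.asarray(bounds[1], dtype=float)

    best_x = mean.copy()
    best_f = np.inf
    history = np.empty(generations)

    for g in range(generations):
        try:
            A = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            C = np.eye(n)
            A = np.eye(n)
        z = rng.standard_normal((lam, n))
        y = z @ A.T
        x = mean + sigma * y
        if bounds is not None:
            x = np.clip(x, lb, ub)
        fvals = np.array([f(xi) for xi in x])
        order = np.argsort(fvals)
        if fvals[order[0]] < best_f:
            best_f = float(fvals[order[0]])
            best_x = x[order[0]].copy()
        history[g] = best_f

        xsel = x[order[:mu]]
        y_w = (xsel - mean) / sigma
        mean_new = mean + sigma * (w @ y_w)
        yw = (mean_new - mean) / sigma

        # cumulative step-size adaptation in the whitened frame
        C_inv_sqrt = np.linalg.inv(A)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (C_inv_sqrt @ yw)
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (g + 1))) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * yw

        rank_mu = (y_w * w[:, None]).T @ y_w
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        C = (C + C.T) / 2
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = float(np.clip(sigma, 1e-12, 1e6))
        mean = mean_new

        if best_f <= ftarget:
            history = history[: g + 1]
            break

    return CMAESResult(
        x=best_x, fun=best_f, history=history, n_gen=history.size
    )
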