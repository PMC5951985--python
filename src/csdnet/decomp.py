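"""Sparse factorization of the inverse cross-spectral density.

Any factorization C^{-1} = B* B is preserved under B -> U B with U unitary,
so the factor recovered from data alone is ambiguous.  Under the assumption
that the generating network is sparse, the representative with minimal
off-diagonal L1 norm is selected:

    minimize  Gamma(U B0) = sum_{i != j} |(U B0)_{ij}|   over  U U* = I

starting from B0, the unique Hermitian positive-definite square root of
C^{-1}.  The optimization is a Riemannian conjugate-gradient descent on the
unitary group: the Euclidean gradient of a smoothed cost is projected onto
the skew-Hermitian tangent space and the iterate moves along geodesics
U <- exp(-mu H) U with an Armijo backtracking line search.  The |z| kinks of
the L1 cost are smoothed as sqrt(|z|^2 + eps) with eps annealed over a
geometric schedule; the reported final cost is the un-smoothed Gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, svd

__all__ = [
    "SpectralFactor",
    "initial_factor",
    "offdiag_l1",
    "optimize_unitary",
    "fix_phases",
]


@dataclass
class SpectralFactor:
    """A factor B of an inverse CSD slice: B* B = C^{-1}.

    ``b0`` is the positive-definite square-root start, ``u`` the accumulated
    unitary rotation and ``b = u @ b0``.  ``cost_trace`` holds the smoothed
    cost at every accepted iterate (non-increasing); ``cost`` is the final
    un-smoothed off-diagonal L1 value.
    """

    b0: np.ndarray
    frequency: float = float("nan")
    u: np.ndarray | None = None
    b: np.ndarray | None = None
    cost_trace: np.ndarray | None = None
    cost: float = float("nan")
    converged: bool = False
    n_iterations: int = 0
    regularization: float = 0.0
    condition_number: float = float("nan")


def offdiag_l1(m: np.ndarray) -> float:
    """Sum of complex moduli of the strictly off-diagonal entries."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    a = np.abs(m).copy()
    np.fill_diagonal(a, 0.0)  # masking, not subtraction: exact for any diagonal
    return float(a.sum())


def initial_factor(
    csd_slice: np.ndarray,
    ridge: float | None = None,
    *,
    frequency: float = float("nan"),
    herm_tol: float = 1e-8,
) -> SpectralFactor:
    """Hermitian positive-definite square root of the inverse CSD slice.

    ``ridge=None`` applies Tikhonov stabilization ``ridge_eff * I`` with
    ``ridge_eff = 1e-8 * trace/n`` only if the slice is numerically
    singular; an explicit value is always added.  The applied value and the
    condition number are recorded on the result.
    """
    c = np.asarray(csd_slice, dtype=complex)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("CSD slice must be square")
    n = c.shape[0]
    herm_err = np.linalg.norm(c - c.conj().T) / max(np.linalg.norm(c), 1e-300)
    if herm_err > herm_tol:
        raise ValueError(f"slice is not Hermitian (relative asymmetry {herm_err:.2e})")
    c = 0.5 * (c + c.conj().T)

    applied = 0.0
    if ridge is not None and ridge > 0:
        applied = ridge
        c = c + applied * np.eye(n)
    evals, vecs = eigh(c)
    eps_sing = np.finfo(float).eps * n * max(evals[-1], 0.0)
    if evals[0] <= eps_sing:
        if ridge is None:
            applied = 1e-8 * np.trace(c).real / n
            c = c + applied * np.eye(n)
            evals, vecs = eigh(c)
        if evals[0] <= 0:
            raise np.linalg.LinAlgError(
                f"CSD slice singular: smallest eigenvalue {evals[0]:.3e} "
                f"(ridge {applied:.3e})"
            )
    b0 = (vecs * (evals**-0.5)) @ vecs.conj().T
    return SpectralFactor(
        b0=b0,
        frequency=frequency,
        regularization=applied,
        condition_number=float(evals[-1] / evals[0]),
    )


def _haar_unitary(n: int, rng: np.random.Generator) -> np.ndarray:
    z = (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))) / np.sqrt(2)
    q, r = np.linalg.qr(z)
    return q * (np.diag(r) / np.abs(np.diag(r)))


def _smoothed_cost(m: np.ndarray, eps: float, offmask: np.ndarray) -> float:
    return float(np.sqrt(np.abs(m[offmask]) ** 2 + eps).sum())


def _cg_descent(
    b0: np.ndarray,
    u0: np.ndarray,
    eps_schedule: np.ndarray,
    max_iter_stage: int,
    tol: float,
) -> tuple[np.ndarray, list[float], bool, int]:
    """Conjugate-gradient descent over all smoothing stages from start u0."""
    n = b0.shape[0]
    offmask = ~np.eye(n, dtype=bool)
    u = u0.copy()
    m = u @ b0
    trace: list[float] = []
    total_iters = 0
    converged = True
    reset_period = max(n * n, 20)

    for eps in eps_schedule:
        cost = _smoothed_cost(m, eps, offmask)
        trace.append(cost)
        g_prev = None
        h = None
        gp2 = 0.0
        mu = 1.0
        stage_converged = False
        since_reset = 0
        for _ in range(max_iter_stage):
            total_iters += 1
            # Euclidean gradient wrt conj(M): M / (2 sqrt(|M|^2+eps)) off-diag
            w = 0.5 / np.sqrt(np.abs(m) ** 2 + eps)
            np.fill_diagonal(w, 0.0)
            gu = (w * m) @ b0.conj().T
            # Riemannian (skew-Hermitian) gradient
            g = gu @ u.conj().T
            g = g - g.conj().T
            g2 = float(np.real(np.vdot(g, g)))
            if g2 < 1e-30:
                stage_converged = True
                break
            if h is None or since_reset >= reset_period:
                h = g.copy()
                since_reset = 0
            else:
                beta = float(np.real(np.vdot(g, g - g_prev))) / gp2  # Polak-Ribiere
                h = g + max(beta, 0.0) * h
            # directional derivative of cost along U(mu) = exp(-mu h) u
            slope = -2.0 * float(np.real(np.sum(gu.conj() * (h @ u))))
            if slope >= 0:  # not a descent direction: reset to steepest descent
                h = g.copy()
                since_reset = 0
                slope = -2.0 * float(np.real(np.sum(gu.conj() * (h @ u))))
                if slope >= 0:
                    stage_converged = True
                    break
            g_prev, gp2 = g, g2
            since_reset += 1
            # geodesic step via eigendecomposition of the Hermitian i*h
            lam, v = eigh(1j * h)
            vhu = v.conj().T @ u
            mu = min(mu * 2.0, 1e3 / max(np.max(np.abs(lam)), 1e-12))
            accepted = False
            for _bt in range(40):
                u_try = v @ (np.exp(1j * mu * lam)[:, None] * vhu)
                m_try = u_try @ b0
                c_try = _smoothed_cost(m_try, eps, offmask)
                if c_try <= cost + 1e-4 * mu * slope:
                    accepted = True
                    break
                mu *= 0.5
            if not accepted:
                stage_converged = True  # line search exhausted: at a minimum
                break
            rel_drop = (cost - c_try) / max(abs(cost), 1e-300)
            u, m, cost = u_try, m_try, c_try
            trace.append(cost)
            if total_iters % 100 == 0:  # curb unitarity drift
                uu, _s, vv = svd(u)
                u = uu @ vv
                m = u @ b0
            if not np.isfinite(cost):
                raise FloatingPointError("non-finite cost in unitary optimization")
            if rel_drop < tol:
                stage_converged = True
                break
        converged = converged and stage_converged
    return u, trace, converged, total_iters


def optimize_unitary(
    factor: SpectralFactor,
    *,
    max_iter: int = 2000,
    tol: float = 1e-6,
    smoothing_eps: tuple[float, float] = (1e-4, 1e-8),
    n_stages: int = 3,
    restarts: int = 3,
    seed: int = 0,
) -> SpectralFactor:
    """Minimize the off-diagonal L1 norm of U @ b0 over unitary U.

    ``smoothing_eps`` gives the annealing range of the smoothing parameter,
    relative to the squared entry scale of b0 (so the schedule is invariant
    to an overall rescaling of the spectrum).  ``restarts`` counts
    initializations: the identity first, then Haar-random unitaries drawn
    from ``seed``.  The best final (un-smoothed) cost wins.

    The cost landscape has several local basins at small n while a single
    descent there costs microseconds, so for ``restarts > 1`` the start
    count is raised to at least ``48/n`` (capped at 24); ``restarts=1``
    always means exactly the identity start.
    """
    b0 = np.asarray(factor.b0, dtype=complex)
    n = b0.shape[0]
    scale2 = float(np.mean(np.abs(b0) ** 2))
    eps_sched = scale2 * np.geomspace(smoothing_eps[0], smoothing_eps[1], n_stages)
    max_iter_stage = max(1, max_iter // n_stages)
    rng = np.random.default_rng(seed)

    n_starts = max(1, restarts)
    if restarts > 1:
        n_starts = max(restarts, min(24, -(-48 // n)))

    best = None
    for r in range(n_starts):
        u0 = np.eye(n, dtype=complex) if r == 0 else _haar_unitary(n, rng)
        u, trace, converged, iters = _cg_descent(
            b0, u0, eps_sched, max_iter_stage, tol
        )
        final = offdiag_l1(u @ b0)
        if best is None or final < best[0]:
            best = (final, u, trace, converged, iters)

    final, u, trace, converged, iters = best
    if not converged:
        warnings.warn(
            f"unitary optimization did not fully converge in {iters} iterations "
            f"(frequency {factor.frequency})",
            RuntimeWarning,
            stacklevel=2,
        )
    factor.u = u
    factor.b = u @ b0
    factor.cost_trace = np.asarray(trace)
    factor.cost = final
    factor.converged = converged
    factor.n_iterations = iters
    return factor


def fix_phases(b: np.ndarray) -> np.ndarray:
    """Resolve the residual diagonal-phase ambiguity of the factor.

    Left-multiplying B by a diagonal unitary changes no entry modulus, so the
    L1 cost is blind to row phases.  Each row is rotated so its diagonal
    entry becomes real and positive; rows with an (exactly) zero diagonal are
    left untouched with a warning.  Idempotent.
    """
    b = np.asarray(b, dtype=complex)
    d = np.diagonal(b).copy()
    zero = np.abs(d) == 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} row(s) have zero diagonal; phases left unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        d[zero] = 1.0
    phases = np.conj(d / np.abs(d))
    return phases[:, None] * b
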