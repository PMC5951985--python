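"""Independent reference implementations used as test oracles."""

import itertools

import numpy as np
from scipy.optimize import minimize


def random_hermitian_pd(n, rng, cond=10.0):
    q = np.linalg.qr(rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))[0]
    evals = np.linspace(1.0, cond, n)
    return (q * evals) @ q.conj().T


def brute_min_2x2(b0):
    """Global minimum of the off-diagonal L1 cost over U(2).

    The cost is invariant to left diagonal phases, so U(2) reduces to a
    rotation angle and one relative phase; dense grid search plus
    Nelder-Mead polish.
    """

    def cost(params):
        th, ps = params
        c, s = np.cos(th), np.sin(th)
        u = np.array([[c, s * np.exp(1j * ps)], [-s * np.exp(-1j * ps), c]])
        m = u @ b0
        return abs(m[0, 1]) + abs(m[1, 0])

    best = np.inf
    best_p = None
    for th in np.linspace(0, np.pi, 60):
        for ps in np.linspace(0, 2 * np.pi, 60, endpoint=False):
            v = cost((th, ps))
            if v < best:
                best, best_p = v, (th, ps)
    res = minimize(cost, best_p, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    return min(best, res.fun)


def pair_counting_auc(scores, truth):
    """P(random true edge outranks random non-edge), ties counted half."""
    n = truth.shape[0]
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    pos = [abs(scores[i, j]) for i, j in off if truth[i, j]]
    neg = [abs(scores[i, j]) for i, j in off if not truth[i, j]]
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0
        for p, q in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))
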