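"""Independent reference implementations used to validate the package.

Everything here deliberately avoids the package's own numerical paths:
dense normal-equations solves instead of banded solvers, textbook stepwise
definitions instead of library calls. Slow and simple on purpose.
"""

from __future__ import annotations

import numpy as np


def second_difference_matrix(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    return D


def dense_whittaker(y: np.ndarray, lam: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Weighted Whittaker smoother by a dense normal-equations solve."""
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    D = second_difference_matrix(n)
    A = np.diag(w) + lam * D.T @ D
    return np.linalg.solve(A, w * y)


def dense_asls(y: np.ndarray, lam: float, p: float, max_iter: int = 10, tol: float = 1e-6) -> np.ndarray:
    """AsLS baseline via the dense solver, mirroring the published iteration
    (weights start at 1; w = p above the baseline, 1-p below)."""
    w = np.ones(len(y))
    for _ in range(max_iter):
        z = dense_whittaker(y, lam, w)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.abs(w_new - w).sum() < tol:
            w = w_new
            break
        w = w_new
    return dense_whittaker(y, lam, w)


def holm_stepwise(pvals: np.ndarray) -> np.ndarray:
    """Holm by direct stepwise definition: sort ascending, multiply the i-th
    smallest (0-based) by (m - i), running maximum, cap at 1, unsort."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


def _dummy(codes) -> np.ndarray:
    levels = sorted(set(codes))
    return np.column_stack([(np.asarray(codes) == l).astype(float) for l in levels[1:]])


def anova_type2_f(y, a, b) -> dict[str, float]:
    """Type-II two-way ANOVA F statistics from dense nested least-squares
    fits (RSS differences between reduced and fuller models)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    one = np.ones((n, 1))
    A = _dummy(a)
    B = _dummy(b)
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    full = np.column_stack([one, A, B, AB])
    rss_ab = rss(np.column_stack([one, A, B]))
    ss = {
        "A": rss(np.column_stack([one, B])) - rss_ab,
        "B": rss(np.column_stack([one, A])) - rss_ab,
        "A:B": rss_ab - rss(full),
    }
    df = {"A": A.shape[1], "B": B.shape[1], "A:B": AB.shape[1]}
    df_res = n - full.shape[1]
    mse = rss(full) / df_res
    return {k: (ss[k] / df[k]) / mse for k in ss}


def pearson_direct(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p straight from the defining formulas."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    r = num / den
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(r), float(2 * tdist.sf(abs(t), n - 2))


def random_band_spectrum(rng: np.random.Generator, n: int = 300):
    """A smooth positive test spectrum: a few Gaussian bands on a sloped
    background with mild noise, on a unit grid. Returns (x, y)."""
    x = np.arange(n, dtype=float)
    y = 1.0 + 0.5 * rng.random() + (rng.random() - 0.5) * 1e-3 * x
    for _ in range(rng.integers(2, 6)):
        c = rng.uniform(0.1, 0.9) * n
        w = rng.uniform(3, 12)
        a = rng.uniform(0.2, 2.0)
        y = y + a * np.exp(-0.5 * ((x - c) / w) ** 2)
    y = y + 0.01 * rng.standard_normal(n)
    return x, y
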