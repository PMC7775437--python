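"""Independent oracles used by the tests.

Each is a deliberately naive re-derivation of a quantity the package
computes by a different route: a proximal-gradient lasso solver, an
exhaustive grid-likelihood read-age evaluator, and a per-read loop for
beta values. They share no code with the implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np


def ista_lasso(X: np.ndarray, y: np.ndarray, lam: float, n_iter: int = 20000) -> np.ndarray:
    """Proximal-gradient (ISTA) minimiser of (1/2n)||y-Xb||^2 + lam*||b||_1."""
    n, p = X.shape
    L = np.linalg.eigvalsh(X.T @ X / n).max()
    step = 1.0 / max(L, 1e-12)
    b = np.zeros(p)
    for _ in range(n_iter):
        grad = X.T @ (X @ b - y) / n
        z = b - step * grad
        b_new = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0.0)
        if np.max(np.abs(b_new - b)) < 1e-13:
            b = b_new
            break
        b = b_new
    return b


def lasso_objective(X: np.ndarray, y: np.ndarray, b: np.ndarray, lam: float) -> float:
    resid = y - X @ b
    return float(0.5 * np.mean(resid**2) + lam * np.sum(np.abs(b)))


def exhaustive_read_age(pattern, slopes, intercepts, epsilon) -> int:
    """Brute-force argmax of the Bernoulli log-likelihood over ages 0..200,
    lowest age on ties; pure-python loops, NaN entries skipped."""
    best_age, best_ll = None, -math.inf
    for age in range(201):
        ll = 0.0
        for x, m, b in zip(pattern, slopes, intercepts):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                continue
            p = min(max(b + m * age, epsilon), 1.0 - epsilon)
            ll += x * math.log(p) + (1.0 - x) * math.log(1.0 - p)
        if ll > best_ll:
            best_ll, best_age = ll, age
    return best_age


def per_read_beta(counts: dict[str, int], n_cpgs: int) -> list[float]:
    """Beta per CpG by literally expanding every pattern into reads."""
    meth = [0] * n_cpgs
    obs = [0] * n_cpgs
    for pat, c in counts.items():
        for _ in range(c):
            for i, ch in enumerate(pat):
                if ch == "?":
                    continue
                obs[i] += 1
                meth[i] += int(ch)
    return [m / o if o else float("nan") for m, o in zip(meth, obs)]
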