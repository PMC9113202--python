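"""Independent reference implementations used only to check the library.

These deliberately restate the definitions in the most literal (and slow)
form possible, sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def lz76_phrases_bruteforce(symbols) -> int:
    """Literal O(n^3) LZ76 exhaustive-history parse.

    A candidate word ``symbols[m..j]`` is reproducible from the prior text
    iff some copy of it starts at a position before ``m`` and ends no later
    than position ``j - 1`` (self-overlap allowed); reproducibility is
    checked by exhaustive positional comparison.
    """
    s = list(symbols)
    n = len(s)

    def reproducible(m: int, j: int) -> bool:
        length = j - m + 1
        for p in range(m):  # copy start strictly before the word
            if p + length - 1 > j - 1:
                continue  # copy would need the word's final character
            if all(s[p + t] == s[m + t] for t in range(length)):
                return True
        return False

    c = 0
    m = 0
    while m < n:
        j = m
        while j < n and reproducible(m, j):
            j += 1
        c += 1
        if j == n:
            break
        m = j + 1
    return c


def logistic_ml_reference(y, x):
    """Direct maximisation of the Bernoulli log-likelihood (BFGS).

    Returns (beta0, beta1, se0, se1, loglik), with standard errors from the
    inverse of the analytic observed information at the optimum.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)

    def negll(beta):
        eta = beta[0] + beta[1] * x
        return -(y * eta - np.logaddexp(0.0, eta)).sum()

    def grad(beta):
        eta = beta[0] + beta[1] * x
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = y - mu
        return -np.array([r.sum(), (r * x).sum()])

    res = optimize.minimize(negll, np.zeros(2), jac=grad, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    b0, b1 = res.x
    eta = b0 + b1 * x
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    cov = np.linalg.inv(info)
    return b0, b1, np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1]), -res.fun
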