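"""Independent oracles used by the test suite.

Everything here is written from the mathematical definitions, deliberately
avoiding the package's computational paths (MME identity, Woodbury,
factorized solves), so agreement is evidence and not tautology.
"""

from __future__ import annotations

import math

import numpy as np

LOG2PI = math.log(2 * math.pi)


def naive_restricted_loglik(y, X, Z, G, R) -> float:
    """From-definition REML criterion with dense V = Z G Z' + R:
    -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ]."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    V = Z @ G @ Z.T + R if Z.size else np.asarray(R, float)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * LOG2PI + ldV + ldX + float(y @ P @ y))


def naive_blups(y, X, Z, G, R) -> np.ndarray:
    """u_hat = G Z' V^-1 (y - X beta_hat) with GLS beta_hat."""
    V = Z @ G @ Z.T + R
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return G @ Z.T @ Vi @ (y - X @ beta)


def iid_restricted_loglik(y) -> tuple[float, float]:
    """Closed-form REML of an iid normal sample with an intercept:
    sigma^2_hat = sum (y - ybar)^2 / (n - 1), and the restricted likelihood
    evaluated there.  Returns (loglik, sigma2_hat)."""
    y = np.asarray(y, float)
    n = y.size
    s2 = float(((y - y.mean()) ** 2).sum() / (n - 1))
    # log|V| + log|X'V^-1 X| = n log s2 + (log n - log s2), y'Py = n - 1
    ll = -0.5 * ((n - 1) * LOG2PI + (n - 1) * math.log(s2) + math.log(n) + (n - 1))
    return ll, s2


def hwe_exact_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p-value by brute-force enumeration of genotype tables with
    the observed allele counts, probabilities from the multinomial
    permanental formula."""
    n = n_hom_ref + n_het + n_hom_alt
    n_minor = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_minor == 0:
        return 1.0
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        a = (n_minor - h) // 2
        b = n - a - h
        if b < 0:
            continue
        num = (
            math.factorial(n)
            * 2**h
            * math.factorial(n_minor)
            * math.factorial(2 * n - n_minor)
        )
        den = (
            math.factorial(a)
            * math.factorial(h)
            * math.factorial(b)
            * math.factorial(2 * n)
        )
        probs[h] = num / den
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return min(1.0, sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12)))


def dense_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise Kronecker product by explicit loops (oracle)."""
    ra, ca = a.shape
    rb, cb = b.shape
    out = np.empty((ra * rb, ca * cb))
    for i in range(ra):
        for j in range(ca):
            for k in range(rb):
                for l_ in range(cb):
                    out[i * rb + k, j * cb + l_] = a[i, j] * b[k, l_]
    return out
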