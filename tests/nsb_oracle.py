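"""Independent brute-force quadrature oracle for the NSB posterior.

Deliberately coded along a different route from the package estimator:
adaptive scipy quadrature over the concentration parameter beta on
(0, inf) with the prior Jacobian d xi / d beta, rather than a fixed grid
over xi.  Entropy moments under a Dirichlet posterior are evaluated by
their own implementation here.  Used only by tests.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln, polygamma
from scipy.special import psi as digamma

LN2 = np.log(2.0)


def dirichlet_entropy_mean(alpha: np.ndarray) -> float:
    """E[H(p)] in nats for p ~ Dirichlet(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    a0 = alpha.sum()
    return digamma(a0 + 1.0) - float((alpha / a0 * digamma(alpha + 1.0)).sum())


def dirichlet_entropy_second_moment(alpha: np.ndarray) -> float:
    """E[H(p)^2] in nats^2 for p ~ Dirichlet(alpha) (direct double sum)."""
    alpha = np.asarray(alpha, dtype=float)
    a0 = alpha.sum()
    k = alpha.size
    total = 0.0
    psi_a2 = digamma(a0 + 2.0)
    pg_a2 = polygamma(1, a0 + 2.0)
    for i in range(k):
        ai = alpha[i]
        ji = (digamma(ai + 2.0) - psi_a2) ** 2 + polygamma(1, ai + 2.0) - pg_a2
        total += ai * (ai + 1.0) * ji
        for j in range(k):
            if j == i:
                continue
            aj = alpha[j]
            iij = ((digamma(ai + 1.0) - psi_a2) * (digamma(aj + 1.0) - psi_a2)
                   - pg_a2)
            total += ai * aj * iij
    return total / (a0 * (a0 + 1.0))


def _log_evidence(counts: np.ndarray, k: int, beta: float) -> float:
    n = counts.sum()
    return (gammaln(k * beta) - gammaln(n + k * beta)
            + sum(gammaln(c + beta) - gammaln(beta) for c in counts))


def nsb_entropy_quadrature(counts, alphabet_size: int | None = None) -> tuple[float, float]:
    """NSB posterior mean/sd of the entropy in bits by adaptive quadrature.

    Integrates over u = ln(beta) with the flat-in-xi prior weight
    d xi/d beta * beta; suitable for K <= ~30, n <= ~200 oracle checks.
    """
    counts = np.asarray(counts, dtype=int)
    k = alphabet_size if alphabet_size is not None else counts.size
    counts = counts[counts > 0]
    if k == 1:
        return 0.0, 0.0

    def weight_log(u: float) -> float:
        beta = np.exp(u)
        jac = k * polygamma(1, k * beta + 1.0) - polygamma(1, beta + 1.0)
        return _log_evidence(counts, k, beta) + np.log(jac) + u

    # normalize by the peak to stabilize
    us = np.linspace(-25, 25, 400)
    logw = np.array([weight_log(u) for u in us])
    w0 = logw.max()

    def make_alpha(u: float) -> np.ndarray:
        beta = np.exp(u)
        full = np.full(k, beta)
        full[: counts.size] += counts
        return full

    def f_norm(u):
        return np.exp(weight_log(u) - w0)

    def f_s1(u):
        return np.exp(weight_log(u) - w0) * dirichlet_entropy_mean(make_alpha(u))

    def f_s2(u):
        return np.exp(weight_log(u) - w0) * dirichlet_entropy_second_moment(make_alpha(u))

    z, _ = quad(f_norm, -25, 25, limit=300)
    m1, _ = quad(f_s1, -25, 25, limit=300)
    m2, _ = quad(f_s2, -25, 25, limit=300)
    mean = m1 / z
    var = max(m2 / z - mean**2, 0.0)
    return mean / LN2, np.sqrt(var) / LN2
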