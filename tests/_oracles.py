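"""Independent brute-force oracles for the marginal likelihoods.

These enumerate the latent states directly with scipy distributions and
never touch the package's kernel code, so agreement is evidence that the
fast marginalization is correct.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom, poisson


def nmix_loglik_enumeration(
    y: np.ndarray,
    replicate: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    x: np.ndarray,
    n_max: int = 60,
    n_quad: int = 33,
) -> float:
    """Enumerate the latent abundance n = 0..n_max per species.

    The occasion-level overdispersion integral uses the same Gauss-Hermite
    rule as the implementation (so the check isolates the n-marginalization);
    the rule itself is validated separately against adaptive quadrature.
    """
    y = np.atleast_2d(y)
    J, K = y.shape
    if sigma > 0:
        gx, gw = np.polynomial.hermite.hermgauss(n_quad)
        eps = np.sqrt(2.0) * sigma * gx
        w = gw / np.sqrt(np.pi)
    total = 0.0
    n = np.arange(n_max + 1)
    for k in range(K):
        lam = np.exp(float(np.dot(alpha[k], x)))
        prob_n = poisson.pmf(n, lam)
        lik_y = np.ones(n_max + 1)
        for j in range(J):
            b = beta[replicate[j] - 1, k]
            if sigma > 0:
                p = 1.0 / (1.0 + np.exp(-(b + eps)))
                lik_y *= (w[:, None] * binom.pmf(y[j, k], n[None, :], p[:, None])
                          ).sum(axis=0)
            else:
                p = 1.0 / (1.0 + np.exp(-b))
                lik_y *= binom.pmf(y[j, k], n, p)
        total += np.log((prob_n * lik_y).sum())
    return float(total)


def occ_loglik_enumeration(
    y: np.ndarray,
    replicate: np.ndarray,
    phi: np.ndarray,
    beta: np.ndarray,
    g: np.ndarray,
) -> float:
    """Enumerate the latent occupancy z in {0, 1} per species."""
    y = np.atleast_2d(y)
    J, K = y.shape
    total = 0.0
    for k in range(K):
        psi = 1.0 / (1.0 + np.exp(-float(np.dot(phi[k], g))))
        lik = 0.0
        for z in (0, 1):
            pz = psi if z == 1 else 1.0 - psi
            cond = 1.0
            for j in range(J):
                rho = z / (1.0 + np.exp(-beta[replicate[j] - 1, k]))
                cond *= rho if y[j, k] == 1 else 1.0 - rho
            lik += pz * cond
        total += np.log(lik)
    return float(total)


def random_nmix_instance(rng: np.random.Generator):
    """Small random instance in the regime the enumeration bound covers."""
    J = int(rng.integers(1, 4))
    K = int(rng.integers(1, 3))
    P = int(rng.integers(1, 3))
    y = rng.integers(0, 5, size=(J, K))
    replicate = rng.integers(1, 3, size=J)
    alpha = rng.normal(0, 0.5, (K, P))
    alpha[:, 0] = np.log(rng.uniform(0.3, 3.0, K))
    beta = rng.normal(-1.0, 1.0, (2, K))
    sigma = float(rng.choice([0.0, rng.uniform(0.2, 1.0)]))
    x = np.concatenate([[1.0], rng.normal(0, 1, P - 1)])
    return y, replicate, alpha, beta, sigma, x


def random_occ_instance(rng: np.random.Generator):
    J = int(rng.integers(1, 6))
    K = int(rng.integers(1, 4))
    P = int(rng.integers(1, 4))
    y = rng.integers(0, 2, size=(J, K))
    replicate = rng.integers(1, 4, size=J)
    phi = rng.normal(0, 1.2, (K, P))
    beta = rng.normal(-1.0, 1.2, (3, K))
    g = np.concatenate([[1.0], rng.normal(0, 1, P - 1)])
    return y, replicate, phi, beta, g
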