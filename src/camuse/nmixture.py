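"""Multi-species hierarchical N-mixture model.

Latent site abundance n_ik ~ Poisson(lambda_ik) with
log(lambda_ik) = alpha_k . x_i; observed occasion counts
y_ijk ~ Binomial(n_ik, rho_ijk) with
logit(rho_ijk) = beta_{m(i,j),k} + eps_ijk, eps_ijk ~ Normal(0, sigma).
Species-specific alpha_k rows are normal random effects around community
hyper-means with community hyper-sds.

The likelihood is computed with both latent layers integrated out: the
occasion-level overdispersion eps by Gauss-Hermite quadrature and the
latent abundance n by truncated enumeration with log-sum-exp. Because the
detection probability depends on (replicate, species) only, the
per-occasion marginal P(y | n) collapses to a small lookup table over the
distinct (replicate, count) combinations observed, which makes a full-data
likelihood evaluation cheap enough for plain random-walk MCMC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

from ._kernels import detection_table as _detection_table_jit
from ._kernels import nmix_combine as _nmix_combine_jit
from .covariates import SiteCovariateTable
from .events import DetectionArray
from .mcmc import FitConfig, PosteriorDraws, _HierarchicalSpec, run_hierarchical_mcmc

__all__ = [
    "NmixParams",
    "nmix_site_loglik",
    "fit_nmixture",
    "derive_expected_count",
    "derive_detection_prob_nmix",
]

_NEG_BIG = -1e30  # finite stand-in for log(0); safe under 0-weighted sums


@dataclass
class NmixParams:
    """Parameters of the N-mixture model (marginal representation).

    alpha: (n_species, n_covariates) log-scale state effects, intercept first.
    beta: (n_replicates, n_species) logit-scale detection intercepts.
    sigma: occasion-level overdispersion sd (>= 0).
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma: float = 0.0
    hyper_mean: np.ndarray | None = None
    hyper_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.alpha.shape[0] != self.beta.shape[1]:
            raise ValueError("alpha rows (species) must match beta columns")


def _gauss_hermite(n_quad: int, sigma: float):
    """Nodes/log-weights for E_eps[f(eps)], eps ~ Normal(0, sigma)."""
    if sigma == 0 or n_quad <= 1:
        return np.zeros(1), np.zeros(1)
    x, w = np.polynomial.hermite.hermgauss(n_quad)
    return np.sqrt(2.0) * sigma * x, np.log(w) - 0.5 * np.log(np.pi)


class _NmixBucket:
    """One group of sites sharing an enumeration bound."""

    def __init__(self, data: DetectionArray, X: np.ndarray,
                 site_idx: np.ndarray, trunc: int):
        counts = data.counts[site_idx]
        mask = data.mask[site_idx]
        m_idx = data.replicate[site_idx] - 1
        I, J, K = counts.shape
        self.m_of_k: list[np.ndarray] = []
        self.y_of_k: list[np.ndarray] = []
        self.weights_k: list[np.ndarray] = []
        for k in range(K):
            pairs_k: dict[tuple, int] = {}
            for i in range(I):
                for j in range(J):
                    if mask[i, j]:
                        pairs_k.setdefault((m_idx[i, j], counts[i, j, k]),
                                           len(pairs_k))
            W = np.zeros((I, len(pairs_k)))
            for i in range(I):
                for j in range(J):
                    if mask[i, j]:
                        W[i, pairs_k[(m_idx[i, j], counts[i, j, k])]] += 1.0
            combos_k = sorted(pairs_k, key=lambda c: pairs_k[c])
            self.m_of_k.append(np.array([c[0] for c in combos_k], dtype=np.int64))
            self.y_of_k.append(np.array([c[1] for c in combos_k], dtype=np.int64))
            self.weights_k.append(W)
        self.site_idx = site_idx
        self.I, self.K = I, K
        self.trunc = int(trunc)
        self.max_y_k = counts.reshape(-1, K).max(axis=0)
        self.lgamma_n1 = gammaln(np.arange(self.trunc + 1) + 1.0)


class _NmixData:
    """Sufficient statistics of a DetectionArray for the marginal likelihood.

    Sites are grouped into buckets by their enumeration bound so that a
    handful of heavy-count sites (which need latent abundance summed into
    the hundreds) do not slow down the contraction for the ordinary ones.
    ``trunc`` may be a single bound (applied to every site, as the
    reference site-likelihood requires) or a per-site array of bounds.
    """

    _BANDS = (80, 120, 180, 280, 440, 600)  # bucket upper bounds

    def __init__(self, data: DetectionArray, X: np.ndarray,
                 trunc: int | np.ndarray):
        I, J, K = data.counts.shape
        trunc_arr = np.broadcast_to(np.asarray(trunc, dtype=np.int64), (I,))
        self.trunc = int(trunc_arr.max(initial=0))
        self.max_y = int(data.counts.max(initial=0))
        self.y_vals = np.unique(data.counts[data.mask]) if data.mask.any() \
            else np.array([0], dtype=np.int64)
        self.n_rep = max(int(data.replicate.max(initial=1)), 1)
        self.K = K
        self.I = I
        self.X = X
        bands = [b for b in self._BANDS if b < self.trunc] + [self.trunc]
        lower = 0
        self.buckets: list[_NmixBucket] = []
        for upper in bands:
            idx = np.flatnonzero((trunc_arr > lower) & (trunc_arr <= upper))
            if idx.size:
                self.buckets.append(
                    _NmixBucket(data, X, idx, int(trunc_arr[idx].max()))
                )
            lower = upper
        self._cache: dict[tuple, list[np.ndarray]] = {}

    def _summed_tables(self, beta: np.ndarray, sigma: float,
                       n_quad: int) -> list[np.ndarray]:
        """Per bucket: S[i,k,n] = sum_j log P(y_ij | n); cached on (beta, sigma)."""
        key = (beta.tobytes(), float(sigma), n_quad)
        tables = self._cache.get(key)
        if tables is None:
            nodes, logw = _gauss_hermite(n_quad, sigma)
            logtab = _detection_table_jit(
                np.ascontiguousarray(beta, dtype=float), nodes, logw,
                self.y_vals, self.trunc,
            )
            tables = []
            for b in self.buckets:
                S = np.empty((b.I, b.K, b.trunc + 1))
                for k in range(b.K):
                    ypos = np.searchsorted(self.y_vals, b.y_of_k[k])
                    D_k = logtab[b.m_of_k[k], k, ypos, : b.trunc + 1]
                    S[:, k, :] = b.weights_k[k] @ D_k
                tables.append(S)
            if len(self._cache) > 8:
                self._cache.clear()
            self._cache[key] = tables
        return tables

    def loglik(self, alpha: np.ndarray, beta: np.ndarray, sigma: float,
               n_quad: int) -> np.ndarray:
        """Per-species total log-likelihood (K,)."""
        eta = self.X @ alpha.T                            # (I, K)
        lam = np.exp(np.clip(eta, -700, 700))
        tables = self._summed_tables(beta, sigma, n_quad)
        ll = np.zeros(self.K)
        bad = np.zeros(self.K, dtype=bool)
        for b, S in zip(self.buckets, tables):
            lam_b = lam[b.site_idx]
            # enumeration-support guard: Poisson mass beyond the bucket's
            # bound must be negligible
            lam_max = lam_b.max(axis=0)
            bad |= lam_max + 8.0 * np.sqrt(lam_max) > b.trunc - b.max_y_k
            ll += _nmix_combine_jit(S, eta[b.site_idx], lam_b, b.lgamma_n1)
        return np.where(bad, _NEG_BIG, ll)


def nmix_site_loglik(
    y_site: np.ndarray,
    replicate: np.ndarray,
    params: NmixParams,
    x_site: np.ndarray,
    trunc: int,
    mask: np.ndarray | None = None,
    n_quad: int = 33,
) -> float:
    """Marginal log-likelihood of one site's count history.

    ``y_site`` is (n_occasions, n_species), ``replicate`` the 1-based
    replicate index per occasion, ``x_site`` the design row (leading 1).
    The latent abundance is summed out up to ``trunc``; the occasion-level
    overdispersion is integrated by ``n_quad``-node Gauss-Hermite
    quadrature. Species are independent given the parameters, so their
    contributions add.
    """
    y_site = np.atleast_2d(np.asarray(y_site, dtype=np.int64))
    J, K = y_site.shape
    replicate = np.asarray(replicate, dtype=np.int64)
    if mask is None:
        mask = np.ones(J, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if trunc < y_site[mask].max(initial=0):
        raise ValueError("trunc below the maximum observed count")
    eta = params.alpha @ np.asarray(x_site, dtype=float)
    if not np.isfinite(eta).all():
        raise ValueError("non-finite expected count (check alpha / x_site)")
    data = DetectionArray(
        counts=y_site[None] * mask[None, :, None],
        mask=mask[None],
        replicate=np.where(mask, replicate, 0)[None],
        effort=np.where(mask, 7.0, 0.0)[None],
    )
    nd = _NmixData(data, np.asarray(x_site, dtype=float)[None, :], trunc)
    return float(nd.loglik(params.alpha, params.beta, params.sigma, n_quad).sum())


def _check_standardized(X: np.ndarray) -> None:
    if X.shape[1] > 1:
        cols = X[:, 1:]
        if (np.abs(cols.mean(axis=0)) > 0.01).any() or (
            np.abs(cols.std(axis=0, ddof=1) - 1) > 0.01
        ).any():
            warnings.warn(
                "covariates do not look standardized (|mean|>0.01 or |sd-1|>0.01)",
                stacklevel=3,
            )


def _adaptive_trunc(data: DetectionArray, rho_guess: float = 0.12) -> np.ndarray:
    """Per-site enumeration bounds for the latent abundance.

    Scales with both the crude detection-corrected mean rate and each
    site's largest occasion count: a site that produced y individuals in
    one occasion needs headroom for latent n of several times y when
    per-occasion detection is modest. Returns an (n_sites,) integer array.
    """
    mean_y = data.counts[data.mask].mean() if data.mask.any() else 0.0
    lam_hat = max(mean_y / rho_guess, 0.5)
    max_y_site = data.counts.max(axis=(1, 2))
    margin = np.maximum(
        np.maximum(40, int(np.ceil(10 * lam_hat))), 8 * max_y_site
    )
    return np.minimum(max_y_site + margin, 600).astype(np.int64)


def fit_nmixture(
    data: DetectionArray,
    covariates: SiteCovariateTable,
    config: FitConfig | None = None,
) -> PosteriorDraws:
    """Fit the hierarchical multi-species N-mixture model by MCMC.

    Requires count (not binarized) histories and standardized covariates.
    Returns a :class:`PosteriorDraws` store with variables ``alpha``,
    ``beta``, ``sigma``, ``hyper_mean`` and ``hyper_sd``.
    """
    if config is None:
        config = FitConfig()
    if data.binary:
        raise ValueError("N-mixture needs count histories, not binarized data")
    X = covariates.design_matrix
    if X.shape[0] != data.n_sites:
        raise ValueError("covariate table and detection array disagree on sites")
    _check_standardized(X)
    trunc = config.abundance_truncation or _adaptive_trunc(data)
    if np.min(trunc) < data.counts.max(initial=0) and np.ndim(trunc) == 0:
        raise ValueError("abundance truncation below the maximum observed count")
    nd = _NmixData(data, X, trunc)
    K, P, M = data.n_species, X.shape[1], nd.n_rep
    mean_y = np.array(
        [data.counts[:, :, k][data.mask].mean() if data.mask.any() else 0.0
         for k in range(K)]
    )

    def init(rng: np.random.Generator):
        a0 = np.log(np.maximum(mean_y, 0.02) / 0.12)
        alpha = np.zeros((K, P))
        alpha[:, 0] = a0 + 0.3 * rng.standard_normal(K)
        alpha[:, 1:] = 0.1 * rng.standard_normal((K, P - 1))
        beta = -2.0 + 0.3 * rng.standard_normal((M, K))
        sigma = float(0.1 + 0.2 * rng.random())
        return alpha, beta, sigma

    spec = _HierarchicalSpec(
        n_species=K, n_cov=P, n_rep=M, has_sigma=True,
        loglik=lambda a, b, s: nd.loglik(a, b, s, config.n_quad),
        init=init,
    )
    return run_hierarchical_mcmc(
        spec, config, "nmixture", list(data.species),
        ["intercept"] + covariates.names,
    )


def derive_expected_count(
    draws: PosteriorDraws,
    method: str = "intercept",
    design_matrix: np.ndarray | None = None,
):
    """Per-species expected count at a typical site, with 95% CI.

    ``method="intercept"`` back-transforms the intercept, exp(alpha_0k):
    the expected count at a site with every covariate at its mean
    (standardized 0). ``method="site_mean"`` averages lambda over the
    supplied design matrix instead.
    """
    import pandas as pd

    alpha = draws.stacked("alpha")  # (S, K, P)
    if method == "intercept":
        per_draw = np.exp(alpha[:, :, 0])
    elif method == "site_mean":
        if design_matrix is None:
            raise ValueError("site_mean needs the design matrix")
        lam = np.exp(np.einsum("ip,skp->ski", design_matrix, alpha))
        per_draw = lam.mean(axis=2)
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = np.percentile(per_draw, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": per_draw.mean(axis=0), "ci_lo": lo, "ci_hi": hi,
         "method": method},
        index=pd.Index(draws.species, name="species"),
    )


def derive_detection_prob_nmix(draws: PosteriorDraws):
    """Per replicate x species detection probability at eps = 0, with 95% CI."""
    import pandas as pd

    beta = draws.stacked("beta")  # (S, M, K)
    p = expit(beta)
    lo, hi = np.percentile(p, [2.5, 97.5], axis=0)
    M, K = p.shape[1:]
    idx = pd.MultiIndex.from_product(
        [np.arange(1, M + 1), draws.species], names=["replicate", "species"]
    )
    return pd.DataFrame(
        {"mean": p.mean(axis=0).ravel(), "ci_lo": lo.ravel(), "ci_hi": hi.ravel()},
        index=idx,
    )
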