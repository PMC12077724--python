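"""Multi-species hierarchical occupancy (site-use) model.

Latent site use z_ik ~ Bernoulli(psi_ik) with logit(psi_ik) = phi_k . g_i;
detections y_ijk ~ Bernoulli(rho_ijk z_ik) with logit(rho_ijk) =
beta_{m(i,j),k} (no overdispersion term, deliberately mirroring the
N-mixture/occupancy asymmetry of the paired analysis). Species effects
phi_k are normal random effects around community hyper-means.

The latent z is marginalized exactly: an all-zero history mixes the
occupied and unoccupied branches, any detection pins the occupied branch.
The per-site likelihood reduces to sufficient statistics (detections and
trials per replicate class), so evaluations are essentially free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .covariates import SiteCovariateTable
from .events import DetectionArray
from .mcmc import FitConfig, PosteriorDraws, _HierarchicalSpec, run_hierarchical_mcmc
from .nmixture import _check_standardized

__all__ = [
    "OccParams",
    "occ_site_loglik",
    "fit_occupancy",
    "derive_site_use",
    "derive_detection_prob_occ",
]


@dataclass
class OccParams:
    """Parameters of the occupancy model.

    phi: (n_species, n_covariates) logit-scale state effects, intercept first.
    beta: (n_replicates, n_species) logit-scale detection intercepts.
    """

    phi: np.ndarray
    beta: np.ndarray
    hyper_mean: np.ndarray | None = None
    hyper_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.phi.shape[0] != self.beta.shape[1]:
            raise ValueError("phi rows (species) must match beta columns")


class _OccData:
    """Sufficient statistics: detections/trials per site, species, replicate."""

    def __init__(self, data: DetectionArray, X: np.ndarray):
        if data.counts.max(initial=0) > 1:
            raise ValueError("occupancy needs binary histories; binarize() first")
        I, J, K = data.counts.shape
        M = max(int(data.replicate.max(initial=1)), 1)
        self.det = np.zeros((I, K, M))
        self.trials = np.zeros((I, M))
        for m in range(M):
            sel = data.mask & (data.replicate - 1 == m)
            self.trials[:, m] = sel.sum(axis=1)
            self.det[:, :, m] = (data.counts * sel[:, :, None]).sum(axis=1)
        self.nondet = self.trials[:, None, :] - self.det
        self.allzero = self.det.sum(axis=2) == 0  # (I, K)
        self.X = X
        self.n_rep = M
        self.K = K

    def loglik(self, phi: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """Per-species total log-likelihood (K,)."""
        eta = self.X @ phi.T                      # (I, K)
        log_psi = -np.logaddexp(0.0, -eta)
        log_1mpsi = -np.logaddexp(0.0, eta)
        beta = beta[: self.n_rep]                 # data may use fewer replicates
        log_rho = -np.logaddexp(0.0, -beta)       # (M, K)
        log_1mrho = -np.logaddexp(0.0, beta)
        det_part = np.einsum("ikm,mk->ik", self.det, log_rho) + np.einsum(
            "ikm,mk->ik", self.nondet, log_1mrho
        )
        occupied = log_psi + det_part
        site_ll = np.where(
            self.allzero, np.logaddexp(occupied, log_1mpsi), occupied
        )
        return site_ll.sum(axis=0)


def occ_site_loglik(
    y_site: np.ndarray,
    replicate: np.ndarray,
    params: OccParams,
    gamma_site: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Marginal log-likelihood of one site's detection history.

    Per species: log[ psi * prod_j rho_j^y (1-rho_j)^(1-y)
    + (1-psi) * 1{all y = 0} ], summed over species.
    """
    y_site = np.atleast_2d(np.asarray(y_site))
    if not np.isin(y_site, (0, 1)).all():
        raise ValueError("occupancy histories must be binary; got counts > 1")
    J, K = y_site.shape
    replicate = np.asarray(replicate, dtype=np.int64)
    if mask is None:
        mask = np.ones(J, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    data = DetectionArray(
        counts=y_site[None] * mask[None, :, None],
        mask=mask[None],
        replicate=np.where(mask, replicate, 0)[None],
        effort=np.where(mask, 7.0, 0.0)[None],
        binary=True,
    )
    od = _OccData(data, np.asarray(gamma_site, dtype=float)[None, :])
    return float(od.loglik(params.phi, params.beta).sum())


def fit_occupancy(
    data: DetectionArray,
    covariates: SiteCovariateTable,
    config: FitConfig | None = None,
) -> PosteriorDraws:
    """Fit the hierarchical multi-species occupancy model by MCMC.

    Requires binary histories (``DetectionArray.binarize``) and standardized
    covariates. Returns draws with variables ``phi``, ``beta``,
    ``hyper_mean`` and ``hyper_sd``.
    """
    if config is None:
        config = FitConfig()
    X = covariates.design_matrix
    if X.shape[0] != data.n_sites:
        raise ValueError("covariate table and detection array disagree on sites")
    _check_standardized(X)
    od = _OccData(data, X)
    K, P, M = data.n_species, X.shape[1], od.n_rep
    # naive occupancy / detection frequencies for initialization
    naive_occ = np.clip(
        (~od.allzero).mean(axis=0), 0.05, 0.95
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        naive_det = np.clip(
            od.det.sum(axis=(0, 2)) / np.maximum(od.trials.sum(), 1), 0.01, 0.5
        )

    def init(rng: np.random.Generator):
        phi = np.zeros((K, P))
        phi[:, 0] = np.log(naive_occ / (1 - naive_occ)) + 0.3 * rng.standard_normal(K)
        phi[:, 1:] = 0.1 * rng.standard_normal((K, P - 1))
        beta = (
            np.log(naive_det / (1 - naive_det))[None, :]
            + 0.3 * rng.standard_normal((M, K))
        )
        return phi, beta, 0.0

    spec = _HierarchicalSpec(
        n_species=K, n_cov=P, n_rep=M, has_sigma=False,
        loglik=lambda p, b, s: od.loglik(p, b),
        init=init,
    )
    return run_hierarchical_mcmc(
        spec, config, "occupancy", list(data.species),
        ["intercept"] + covariates.names,
    )


def derive_site_use(
    draws: PosteriorDraws,
    method: str = "intercept",
    design_matrix: np.ndarray | None = None,
):
    """Per-species site-use probability with 95% CI.

    ``method="intercept"`` back-transforms the intercept, ilogit(phi_0k):
    site use at a site with all covariates at their mean.
    ``method="site_mean"`` averages psi over the supplied design matrix.
    """
    import pandas as pd

    phi = draws.stacked("phi")  # (S, K, P)
    if method == "intercept":
        per_draw = expit(phi[:, :, 0])
    elif method == "site_mean":
        if design_matrix is None:
            raise ValueError("site_mean needs the design matrix")
        psi = expit(np.einsum("ip,skp->ski", design_matrix, phi))
        per_draw = psi.mean(axis=2)
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = np.percentile(per_draw, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": per_draw.mean(axis=0), "ci_lo": lo, "ci_hi": hi,
         "method": method},
        index=pd.Index(draws.species, name="species"),
    )


def derive_detection_prob_occ(draws: PosteriorDraws):
    """Per replicate x species detection probability with 95% CI."""
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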