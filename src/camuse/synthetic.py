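"""Seeded synthetic camera-trap studies.

Generates everything the downstream pipeline consumes — correlated site
covariates, community-level truth (hyper-parameters and the species
effects drawn from them), latent abundance/occupancy states, detection
histories with exactly the statistical structure the two models assume,
and raw time-stamped event streams (with sub-gap "echo" bursts and
human/vehicle background) that exercise the event-processing chain.

The default scale mirrors the published survey footprint at desk scale:
150 sites, three species at contrasting abundances, 16 seven-day
occasions per site, and 1-4 deployments per site in the proportions the
survey reported (roughly 71/19/7/4%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import SiteCovariateTable, standardize
from .events import DetectionArray, _validate_deployments

__all__ = [
    "StudyDesign",
    "HyperConfig",
    "CommunityTruth",
    "LatentState",
    "BurstSpec",
    "default_design",
    "default_covariate_corr",
    "default_nmixture_hypers",
    "default_occupancy_hypers",
    "gen_site_covariates",
    "gen_community_truth",
    "gen_detection_histories",
    "gen_deployments",
    "gen_event_stream",
    "default_event_rates",
]

SPECIES = ("bear", "wolf", "lynx")
#: independence gaps (minutes) used throughout: bear 10, lynx 1, wolf 30
DEFAULT_GAPS = {"bear": 10.0, "lynx": 1.0, "wolf": 30.0}
#: observed share of sites with 1, 2, 3, 4 deployments in the emulated survey
REPLICATE_SHARES = (107 / 151, 28 / 151, 10 / 151, 6 / 151)

COVARIATE_NAMES = (
    "dist_dump",
    "forest_500m",
    "forest_1km",
    "forest_10km",
    "dist_roads",
    "dist_urban",
    "elevation",
    "roughness",
    "slope",
)


@dataclass
class StudyDesign:
    """Survey layout: sites, deployments per site, occasion structure."""

    n_sites: int
    species_names: list[str]
    replicates_per_site: np.ndarray           # (I,) ints in 1..4
    deployment_durations: list[list[float]]   # days per deployment per site
    occasion_length_days: int = 7
    covariate_corr: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=lambda: list(COVARIATE_NAMES))

    def __post_init__(self) -> None:
        self.replicates_per_site = np.asarray(self.replicates_per_site, dtype=np.int64)
        if ((self.replicates_per_site < 1) | (self.replicates_per_site > 4)).any():
            raise ValueError("replicates_per_site must lie in 1..4")
        if self.occasion_length_days <= 0:
            raise ValueError("occasion_length_days must be positive")
        if self.covariate_corr is not None:
            _validate_corr(self.covariate_corr)
        if len(self.deployment_durations) != self.n_sites:
            raise ValueError("need one duration list per site")

    def occasion_layout(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mask, replicate, effort) arrays of shape (n_sites, max_occasions)."""
        L = self.occasion_length_days
        per_site = []
        for durations in self.deployment_durations:
            occ = []
            for r, d in enumerate(durations, start=1):
                n_full, part = divmod(float(d), L)
                occ.extend((r, float(L)) for _ in range(int(n_full)))
                if part > 0:
                    occ.append((r, part))
            per_site.append(occ)
        J = max(len(o) for o in per_site)
        I = self.n_sites
        mask = np.zeros((I, J), dtype=bool)
        replicate = np.zeros((I, J), dtype=np.int64)
        effort = np.zeros((I, J))
        for i, occ in enumerate(per_site):
            for j, (r, eff) in enumerate(occ):
                mask[i, j], replicate[i, j], effort[i, j] = True, r, eff
        return mask, replicate, effort


def default_design(
    n_sites: int = 150,
    n_occasions: int = 16,
    species: tuple[str, ...] = SPECIES,
    seed: int = 0,
) -> StudyDesign:
    """Desk-scale design: deployments per site drawn in the surveyed
    proportions, each site's ``n_occasions`` occasions split across them."""
    rng = np.random.default_rng(seed)
    reps = rng.choice(np.arange(1, 5), size=n_sites, p=REPLICATE_SHARES)
    durations = []
    for r in reps:
        per_dep = np.full(r, n_occasions // r)
        per_dep[: n_occasions % r] += 1
        durations.append([float(p * 7) for p in per_dep])
    return StudyDesign(
        n_sites=n_sites,
        species_names=list(species),
        replicates_per_site=reps,
        deployment_durations=durations,
        covariate_corr=default_covariate_corr(),
    )


def _validate_corr(corr: np.ndarray) -> None:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")


def default_covariate_corr() -> np.ndarray:
    """Correlation structure echoing the screened covariate set: slope,
    roughness and the 1 km / 10 km forest buffers form one highly
    intercorrelated block (|r| > 0.7); everything else is mildly related.

    Built from a factor loading matrix so it is positive definite by
    construction.
    """
    P = len(COVARIATE_NAMES)
    idx = {n: i for i, n in enumerate(COVARIATE_NAMES)}
    loadings = np.zeros((P, 3))
    # factor 0: terrain (slope, roughness, and the wide forest buffers)
    for name, load in [("slope", 0.92), ("roughness", 0.90),
                       ("forest_1km", 0.82), ("forest_10km", 0.80),
                       ("elevation", 0.35)]:
        loadings[idx[name], 0] = load
    # factor 1: remoteness
    for name, load in [("dist_urban", 0.55), ("dist_roads", 0.5),
                       ("dist_dump", 0.45), ("elevation", 0.3)]:
        loadings[idx[name], 1] = load
    # factor 2: local forest
    for name, load in [("forest_500m", 0.6), ("forest_1km", 0.25)]:
        loadings[idx[name], 2] = load
    corr = loadings @ loadings.T
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# community truth


@dataclass
class HyperConfig:
    """Hyper-parameter settings for generating community truth."""

    state_hyper_mean: np.ndarray   # (P,) incl. intercept, link scale
    state_hyper_sd: np.ndarray     # (P,) >= 0
    detect_hyper_mean: np.ndarray  # (M,) logit scale
    detect_hyper_sd: float
    overdispersion_sd: float = 0.0

    def __post_init__(self) -> None:
        self.state_hyper_mean = np.asarray(self.state_hyper_mean, dtype=float)
        self.state_hyper_sd = np.asarray(self.state_hyper_sd, dtype=float)
        self.detect_hyper_mean = np.asarray(self.detect_hyper_mean, dtype=float)
        if (self.state_hyper_sd < 0).any() or self.detect_hyper_sd < 0:
            raise ValueError("hyper sds must be >= 0")
        if self.overdispersion_sd < 0:
            raise ValueError("overdispersion sd must be >= 0")


def default_nmixture_hypers(n_covariates: int = 8) -> HyperConfig:
    """Counts-side defaults: expected counts of order 1-3 per site and
    per-individual, per-occasion detection of a few percent, replicate
    intercepts echoing the published detection rows."""
    slopes = np.resize([0.24, 0.34, -0.35, 0.2, -0.2, 0.15, -0.15, 0.1],
                       n_covariates)
    return HyperConfig(
        state_hyper_mean=np.concatenate([[np.log(2.0)], slopes]),
        state_hyper_sd=np.concatenate([[0.4], np.full(n_covariates, 0.25)]),
        detect_hyper_mean=np.array([-3.89, -3.89, -4.60, -3.18]),
        detect_hyper_sd=0.3,
        overdispersion_sd=0.5,
    )


def default_occupancy_hypers(n_covariates: int = 8) -> HyperConfig:
    """Occupancy-side defaults: community site use around 0.8 and
    per-occasion detection around 0.1-0.18."""
    slopes = np.resize([0.47, -0.35, 0.3, -0.3, 0.25, -0.2, 0.2, -0.15],
                       n_covariates)
    return HyperConfig(
        state_hyper_mean=np.concatenate([[1.4], slopes]),
        state_hyper_sd=np.concatenate([[0.8], np.full(n_covariates, 0.3)]),
        detect_hyper_mean=np.array([-1.8, -2.1, -2.3, -1.5]),
        detect_hyper_sd=0.3,
        overdispersion_sd=0.0,
    )


@dataclass
class CommunityTruth:
    """Recorded generating truth of one synthetic study."""

    state_hyper_mean: np.ndarray
    state_hyper_sd: np.ndarray
    detect_hyper_mean: np.ndarray
    detect_hyper_sd: float
    species_effects: np.ndarray    # (K, P): alpha_k or phi_k rows
    detect_intercepts: np.ndarray  # (M, K): beta_{m,k}
    overdispersion_sd: float
    seed: int
    species_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (np.asarray(self.state_hyper_sd) < 0).any():
            raise ValueError("hyper sds must be >= 0")
        if self.overdispersion_sd < 0:
            raise ValueError("overdispersion sd must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "state_hyper_mean": self.state_hyper_mean.tolist(),
                "state_hyper_sd": self.state_hyper_sd.tolist(),
                "detect_hyper_mean": self.detect_hyper_mean.tolist(),
                "detect_hyper_sd": self.detect_hyper_sd,
                "species_effects": self.species_effects.tolist(),
                "detect_intercepts": self.detect_intercepts.tolist(),
                "overdispersion_sd": self.overdispersion_sd,
                "seed": self.seed,
                "species_names": self.species_names,
                "covariate_names": self.covariate_names,
            },
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "CommunityTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            state_hyper_mean=np.array(d["state_hyper_mean"]),
            state_hyper_sd=np.array(d["state_hyper_sd"]),
            detect_hyper_mean=np.array(d["detect_hyper_mean"]),
            detect_hyper_sd=d["detect_hyper_sd"],
            species_effects=np.array(d["species_effects"]),
            detect_intercepts=np.array(d["detect_intercepts"]),
            overdispersion_sd=d["overdispersion_sd"],
            seed=d["seed"],
            species_names=d["species_names"],
            covariate_names=d["covariate_names"],
        )


def gen_community_truth(
    config: HyperConfig,
    n_species: int,
    n_replicates: int,
    seed: int,
    species_names: list[str] | None = None,
    covariate_names: list[str] | None = None,
) -> CommunityTruth:
    """Draw species effects and detection intercepts from the community
    hyper-distributions (normal random effects)."""
    rng = np.random.default_rng(seed)
    P = len(config.state_hyper_mean)
    M = min(n_replicates, len(config.detect_hyper_mean))
    effects = config.state_hyper_mean + config.state_hyper_sd * rng.standard_normal(
        (n_species, P)
    )
    detect = (
        config.detect_hyper_mean[:M, None]
        + config.detect_hyper_sd * rng.standard_normal((M, n_species))
    )
    return CommunityTruth(
        state_hyper_mean=config.state_hyper_mean.copy(),
        state_hyper_sd=config.state_hyper_sd.copy(),
        detect_hyper_mean=config.detect_hyper_mean[:M].copy(),
        detect_hyper_sd=config.detect_hyper_sd,
        species_effects=effects,
        detect_intercepts=detect,
        overdispersion_sd=config.overdispersion_sd,
        seed=seed,
        species_names=list(species_names or [f"sp{k}" for k in range(n_species)]),
        covariate_names=list(covariate_names or []),
    )


# ---------------------------------------------------------------------------
# covariates


def gen_site_covariates(
    n_sites: int,
    corr_spec: np.ndarray,
    seed: int,
    names: list[str] | None = None,
) -> SiteCovariateTable:
    """Multivariate-normal site covariates with the requested correlation."""
    corr_spec = np.asarray(corr_spec, dtype=float)
    _validate_corr(corr_spec)
    P = corr_spec.shape[0]
    names = list(names) if names is not None else list(COVARIATE_NAMES[:P])
    if len(names) != P:
        raise ValueError("covariate names must match the correlation matrix")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr_spec + 1e-10 * np.eye(P))
    vals = rng.standard_normal((n_sites, P)) @ L.T
    raw = pd.DataFrame(
        vals, columns=names,
        index=pd.Index([f"s{i:03d}" for i in range(n_sites)], name="site_id"),
    )
    return SiteCovariateTable(raw=raw)


# ---------------------------------------------------------------------------
# latent states and detection histories


@dataclass
class LatentState:
    """Latent quantities behind one synthetic detection history."""

    abundance: np.ndarray | None          # (I, K) n_ik
    occupancy: np.ndarray                 # (I, K) z_ik
    site_rate: np.ndarray | None          # (I, K) lambda_ik
    site_use_prob: np.ndarray             # (I, K) psi_ik
    overdispersion_draws: np.ndarray | None  # (I, J, K) eps_ijk

    def __post_init__(self) -> None:
        if self.abundance is not None and (self.abundance < 0).any():
            raise ValueError("abundance must be non-negative")
        if not np.isin(self.occupancy, (0, 1)).all():
            raise ValueError("occupancy must be binary")
        if ((self.site_use_prob < 0) | (self.site_use_prob > 1)).any():
            raise ValueError("site-use probabilities must lie in [0, 1]")


def gen_detection_histories(
    truth: CommunityTruth,
    covariates: SiteCovariateTable,
    design: StudyDesign,
    model_kind: str,
    seed: int,
) -> tuple[DetectionArray, LatentState]:
    """Simulate detection histories from the exact model structure.

    N-mixture: n ~ Poisson(exp(alpha.x)), y ~ Binomial(n, ilogit(beta + eps)),
    eps ~ Normal(0, sigma). Occupancy: z ~ Bernoulli(ilogit(phi.g)),
    y ~ Bernoulli(ilogit(beta) * z). The occasion layout (mask, replicate
    index, effort) comes from the design.
    """
    if model_kind not in ("nmixture", "occupancy"):
        raise ValueError(f"unknown model_kind: {model_kind!r}")
    if covariates.standardized is None:
        covariates = standardize(covariates)
    X = covariates.design_matrix
    if X.shape[1] != truth.species_effects.shape[1]:
        raise ValueError("covariate count does not match truth effect dimensions")
    if X.shape[0] != design.n_sites:
        raise ValueError("covariate table and design disagree on sites")
    rng = np.random.default_rng(seed)
    mask, replicate, effort = design.occasion_layout()
    I, J = mask.shape
    K = truth.species_effects.shape[0]
    M = truth.detect_intercepts.shape[0]
    if int(replicate.max()) > M:
        raise ValueError("design needs more replicate detection intercepts")
    m_idx = np.where(mask, replicate - 1, 0)
    beta_occ = truth.detect_intercepts[m_idx]          # (I, J, K)

    if model_kind == "nmixture":
        lam = np.exp(X @ truth.species_effects.T)      # (I, K)
        n_lat = rng.poisson(lam)
        sigma = truth.overdispersion_sd
        eps = sigma * rng.standard_normal((I, J, K))
        p = expit(beta_occ + eps)
        y = rng.binomial(n_lat[:, None, :], p)
        y *= mask[:, :, None]
        latent = LatentState(
            abundance=n_lat,
            occupancy=(n_lat > 0).astype(np.int64),
            site_rate=lam,
            site_use_prob=1.0 - np.exp(-lam),
            overdispersion_draws=eps,
        )
        binary = False
    else:
        psi = expit(X @ truth.species_effects.T)
        z = (rng.random((I, K)) < psi).astype(np.int64)
        p = expit(beta_occ)
        y = ((rng.random((I, J, K)) < p) & (z[:, None, :] > 0)).astype(np.int64)
        y *= mask[:, :, None]
        latent = LatentState(
            abundance=None,
            occupancy=z,
            site_rate=None,
            site_use_prob=psi,
            overdispersion_draws=None,
        )
        binary = True
    data = DetectionArray(
        counts=y,
        mask=mask,
        replicate=replicate,
        effort=effort,
        site_ids=list(covariates.site_ids),
        species=list(truth.species_names or design.species_names),
        binary=binary,
    )
    return data, latent


# ---------------------------------------------------------------------------
# deployments and raw event streams


def gen_deployments(design: StudyDesign, seed: int = 0,
                    start_year: int = 2010) -> pd.DataFrame:
    """Deployment table for the design: distinct projected locations
    (>= 500 m between sites), one deployment per site per year."""
    rng = np.random.default_rng(seed)
    rows = []
    n_cols = int(np.ceil(np.sqrt(design.n_sites)))
    for i in range(design.n_sites):
        east0 = 500_000.0 + (i % n_cols) * 800.0
        north0 = 4_450_000.0 + (i // n_cols) * 800.0
        for r, dur in enumerate(design.deployment_durations[i], start=1):
            start = pd.Timestamp(year=start_year + r - 1, month=6, day=1) + \
                pd.Timedelta(days=int(rng.integers(0, 60)))
            rows.append(
                {
                    "deployment_id": f"d{i:03d}_{r}",
                    "site_id": f"s{i:03d}",
                    # small within-site placement scatter, well under 15 m
                    "easting": east0 + rng.uniform(-5, 5),
                    "northing": north0 + rng.uniform(-5, 5),
                    "start": start,
                    "end": start + pd.Timedelta(days=float(dur)),
                }
            )
    df = pd.DataFrame(rows)
    _validate_deployments(df)
    return df


@dataclass
class BurstSpec:
    """Within-gap burst behaviour of the raw event stream.

    Each independent arrival spawns, with probability ``echo_prob``, a
    short train of echo records within ``echo_window_minutes`` — the
    repeated triggers the independence filter is meant to remove.
    """

    echo_prob: float = 0.3
    echo_mean: float = 1.5
    echo_window_minutes: float = 5.0


def gen_event_stream(
    rates: pd.DataFrame,
    deployments: pd.DataFrame,
    cluster_spec: BurstSpec | None = None,
    seed: int = 0,
    focal_species: tuple[str, ...] = SPECIES,
) -> pd.DataFrame:
    """Time-stamped event records from per-site daily intensities.

    ``rates`` is indexed by site id with one column per category (focal
    species plus human/vehicle). Independent arrivals are homogeneous
    Poisson within each deployment window; focal-species arrivals spawn
    sub-gap echo bursts per ``cluster_spec``. Human/vehicle streams get no
    echoes (they are never independence-filtered).
    """
    if (rates.to_numpy() < 0).any():
        raise ValueError("event rates must be >= 0")
    _validate_deployments(deployments)
    cluster_spec = cluster_spec or BurstSpec()
    rng = np.random.default_rng(seed)
    rows = []
    deps = deployments.sort_values(["site_id", "deployment_id"])
    for _, dep in deps.iterrows():
        site = dep["site_id"]
        if site not in rates.index:
            continue
        days = (dep["end"] - dep["start"]) / pd.Timedelta(days=1)
        for cat in sorted(rates.columns):
            lam = float(rates.loc[site, cat]) * days
            n = rng.poisson(lam) if lam > 0 else 0
            offsets = np.sort(rng.uniform(0, days, size=n))
            for off in offsets:
                t = dep["start"] + pd.Timedelta(days=float(off))
                rows.append((site, dep["deployment_id"], t, cat))
                if cat in focal_species and rng.random() < cluster_spec.echo_prob:
                    n_echo = 1 + rng.poisson(max(cluster_spec.echo_mean - 1, 0))
                    lags = rng.uniform(
                        0.1, cluster_spec.echo_window_minutes, size=n_echo
                    )
                    for lag in np.sort(lags):
                        te = t + pd.Timedelta(minutes=float(lag))
                        if te < dep["end"]:
                            rows.append((site, dep["deployment_id"], te, cat))
    df = pd.DataFrame(rows, columns=["site_id", "deployment_id", "timestamp", "species"])
    return df.sort_values(["site_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def default_event_rates(
    latent: LatentState,
    site_ids: list,
    species_names: list[str],
    per_individual_daily_rate: float = 0.02,
    human_rate_mean: float = 1.0,
    vehicle_rate_mean: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site daily event intensities from a latent abundance state.

    Focal-species intensity is latent abundance times a per-individual
    daily encounter rate (the survey-wide average is about one carnivore
    record per 50 camera-days); human/vehicle backgrounds are lognormal
    around their means.
    """
    rng = np.random.default_rng(seed)
    n = latent.abundance if latent.abundance is not None else latent.occupancy
    rates = pd.DataFrame(
        n * per_individual_daily_rate,
        index=pd.Index(site_ids, name="site_id"),
        columns=species_names,
    )
    rates["human"] = human_rate_mean * rng.lognormal(0, 0.75, size=len(site_ids))
    rates["vehicle"] = vehicle_rate_mean * rng.lognormal(0, 0.75, size=len(site_ids))
    return rates
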