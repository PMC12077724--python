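"""Site-covariate preparation.

Covariates arrive as a per-site table of continuous values (terrain,
land-cover and trap-rate covariates). Before modelling they are
standardized to mean 0 / sd 1, screened for collinearity with Pearson
correlation, and each group of mutually correlated covariates is resolved
by a univariate model comparison that keeps the covariate with the largest
community-level effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SiteCovariateTable",
    "standardize",
    "correlation_screen",
    "ScreenReport",
    "univariate_compare",
    "UnivariateComparison",
]


@dataclass
class SiteCovariateTable:
    """Per-site covariate vectors, raw and standardized.

    ``raw`` is indexed by site id with one column per covariate. After
    :func:`standardize`, ``standardized`` holds the scaled columns and
    ``scaler`` the per-covariate (mean, sd) used, enabling
    back-transformation of predictions. ``design_matrix`` prepends the
    intercept column of ones expected by both models.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame | None = None
    scaler: pd.DataFrame | None = None

    @property
    def names(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def site_ids(self) -> list:
        return list(self.raw.index)

    @property
    def n_sites(self) -> int:
        return len(self.raw)

    @property
    def design_matrix(self) -> np.ndarray:
        """(n_sites, 1 + n_covariates) array: leading 1, then standardized values."""
        if self.standardized is None:
            raise ValueError("covariates are not standardized; call standardize() first")
        vals = self.standardized.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(vals)), vals])

    def subset(self, names: Sequence[str]) -> "SiteCovariateTable":
        names = list(names)
        return SiteCovariateTable(
            raw=self.raw[names].copy(),
            standardized=None if self.standardized is None
            else self.standardized[names].copy(),
            scaler=None if self.scaler is None else self.scaler[names].copy(),
        )

    def to_csv(self, path: str | Path) -> None:
        self.raw.rename_axis("site_id").to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteCovariateTable":
        return cls(raw=pd.read_csv(path, index_col="site_id"))


def standardize(table: SiteCovariateTable) -> SiteCovariateTable:
    """Scale every covariate to mean 0, sd 1 (sample sd, denominator n-1).

    Raises if a column is constant (sd 0) or fewer than two sites are
    present. Idempotent: standardizing an already-standardized table leaves
    the values unchanged.
    """
    raw = table.raw
    if len(raw) < 2:
        raise ValueError("standardize requires at least 2 sites")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant covariate column(s): {constant}")
    standardized = (raw - mean) / sd
    scaler = pd.DataFrame({"mean": mean, "sd": sd}).T
    return SiteCovariateTable(raw=raw.copy(), standardized=standardized, scaler=scaler)


@dataclass
class ScreenReport:
    """Pairwise Pearson correlations and the conflict groups they imply."""

    pairs: pd.DataFrame           # columns: cov_a, cov_b, r
    threshold: float
    groups: list[list[str]]       # connected components with >= 2 members

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "threshold": self.threshold,
                "pairs": self.pairs.to_dict(orient="records"),
                "groups": self.groups,
            },
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def correlation_screen(
    table: SiteCovariateTable, threshold: float = 0.7
) -> ScreenReport:
    """Find groups of covariates with pairwise Pearson ``|r| > threshold``.

    The inequality is strict (``|r|`` exactly at the threshold is not
    flagged). Covariates joined by above-threshold edges are closed into
    connected components; components with at least two members are the
    conflict groups to be resolved by :func:`univariate_compare`.
    """
    raw = table.raw
    if len(raw) < 3:
        raise ValueError("correlation_screen requires at least 3 sites")
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValueError(f"missing values in covariates: {bad}")
    names = list(raw.columns)
    corr = raw.corr(method="pearson").to_numpy()
    iu, ju = np.triu_indices(len(names), k=1)
    pairs = pd.DataFrame(
        {
            "cov_a": [names[i] for i in iu],
            "cov_b": [names[j] for j in ju],
            "r": corr[iu, ju],
        }
    )
    above = np.abs(pairs["r"].to_numpy()) > threshold
    n = len(names)
    adj = coo_matrix(
        (np.ones(above.sum()), (iu[above], ju[above])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    groups = []
    for lab in np.unique(labels):
        members = sorted(np.asarray(names)[labels == lab].tolist())
        if len(members) >= 2:
            groups.append(members)
    groups.sort()
    return ScreenReport(pairs=pairs, threshold=threshold, groups=groups)


@dataclass
class UnivariateComparison:
    """Outcome of a one-covariate-at-a-time model comparison."""

    selected: str
    effects: pd.DataFrame  # index covariate; columns: hyper_effect, abs_effect, rhat
    status: str            # "ok", "tie" or "warning" (non-convergent fit)
    model_kind: str
    group: list[str] = field(default_factory=list)


def univariate_compare(
    group: Sequence[str],
    data,
    covariates: SiteCovariateTable,
    model_kind: str,
    fit_config=None,
    rhat_threshold: float = 1.1,
) -> UnivariateComparison:
    """Resolve a correlated covariate group by single-covariate model fits.

    Each candidate is fitted alone (same hierarchical model class, short
    chains) and the candidate with the largest absolute posterior-mean
    community (hyper-level) effect is selected. Exact ties fall back to
    name order and are flagged; a candidate whose hyper-effect R-hat exceeds
    ``rhat_threshold`` flags the whole comparison as a warning while still
    reporting a selection.
    """
    from .mcmc import FitConfig
    from .nmixture import fit_nmixture
    from .occupancy import fit_occupancy

    group = sorted(group)
    if len(group) < 2:
        raise ValueError("univariate_compare needs a group of >= 2 covariates")
    if model_kind not in ("nmixture", "occupancy"):
        raise ValueError(f"unknown model_kind: {model_kind!r}")
    if fit_config is None:
        fit_config = FitConfig(n_chains=2, n_iter=1200, n_burnin=600, seed=0)
    fit = fit_nmixture if model_kind == "nmixture" else fit_occupancy

    rows = []
    for name in group:
        sub = covariates.subset([name])
        sub = standardize(sub) if sub.standardized is None else sub
        fit_data = data if model_kind == "nmixture" else (
            data if data.binary else data.binarize()
        )
        draws = fit(fit_data, sub, replace(fit_config, seed=fit_config.seed))
        slope = draws.get("hyper_mean")[..., 1]  # (chain, draw); index 0 = intercept
        rhat = gelman_rubin_from_chains(slope)
        rows.append({"covariate": name,
                     "hyper_effect": float(slope.mean()),
                     "abs_effect": float(abs(slope.mean())),
                     "rhat": rhat})
    effects = pd.DataFrame(rows).set_index("covariate")

    best = effects["abs_effect"].max()
    winners = effects.index[np.isclose(effects["abs_effect"], best, atol=1e-9)]
    selected = sorted(winners)[0]
    if len(winners) > 1:
        status = "tie"
    elif (effects["rhat"] >= rhat_threshold).any():
        status = "warning"
    else:
        status = "ok"
    return UnivariateComparison(selected=selected, effects=effects, status=status,
                                model_kind=model_kind, group=list(group))


def gelman_rubin_from_chains(chains: np.ndarray) -> float:
    """Split-chain R-hat straight from a (chain, draw) array."""
    from .diagnostics import split_rhat

    return split_rhat(np.asarray(chains))
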