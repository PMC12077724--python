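"""Pipeline orchestration and cross-model comparison.

``run_pipeline`` drives the full analysis — simulate (or load) raw data,
process events into histories, prepare covariates, fit both models,
diagnose, and compare — writing every artefact plus a reproducibility
manifest to an output directory. ``compare_models`` implements the
bookkeeping behind the headline comparison: which species x covariate
associations are significant under each model, which are shared, and
whether any shared ones conflict in sign.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as covmod
from . import events as evmod
from . import synthetic as synth
from .diagnostics import posterior_predictive_check, significance_table
from .mcmc import FitConfig, PriorConfig
from .nmixture import derive_detection_prob_nmix, derive_expected_count, fit_nmixture
from .occupancy import derive_detection_prob_occ, derive_site_use, fit_occupancy

__all__ = ["ComparisonReport", "compare_models", "PipelineConfig", "run_pipeline"]

log = logging.getLogger("camuse.pipeline")

AGREEMENTS = ("shared-same-sign", "shared-conflict", "nmix-only", "occ-only", "neither")


@dataclass
class ComparisonReport:
    """Cell-wise and tallied agreement between the two models."""

    table: pd.DataFrame        # species, covariate, nmix/occ category, agreement
    tallies: dict[str, dict[str, int]]
    shared_fraction: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "table": self.table.to_dict(orient="records"),
                "tallies": self.tallies,
                "shared_fraction": round(self.shared_fraction, 6),
            },
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _agreement(cat_n: str, cat_o: str) -> str:
    sig_n, sig_o = cat_n != "none", cat_o != "none"
    if sig_n and sig_o:
        return "shared-same-sign" if cat_n[-1] == cat_o[-1] else "shared-conflict"
    if sig_n:
        return "nmix-only"
    if sig_o:
        return "occ-only"
    return "neither"


def compare_models(
    sig_nmix: pd.DataFrame, sig_occ: pd.DataFrame
) -> ComparisonReport:
    """Merge two significance tables on the species x covariate grid.

    Both inputs come from :func:`camuse.diagnostics.significance_table`.
    "Significant" includes both tiers (strong and moderate). The shared
    fraction is ``2 * n_shared / (n_sig_nmix + n_sig_occ)`` — the fraction
    of all significant findings that the models agree on — and 1.0 when
    neither model finds anything significant.
    """
    key = ["species", "covariate"]
    a = sig_nmix.set_index(key)
    b = sig_occ.set_index(key)
    if set(a.index) != set(b.index):
        missing = sorted(set(a.index) ^ set(b.index))
        raise ValueError(f"species x covariate grids differ on cells: {missing}")
    merged = a[["category", "mean_effect"]].join(
        b[["category", "mean_effect"]], lsuffix="_nmix", rsuffix="_occ"
    ).reset_index()
    merged["agreement"] = [
        _agreement(cn, co)
        for cn, co in zip(merged["category_nmix"], merged["category_occ"])
    ]
    tallies = {}
    for model, col in (("nmix", "category_nmix"), ("occ", "category_occ")):
        cats = merged[col]
        tallies[model] = {
            "significant": int((cats != "none").sum()),
            "strong": int(cats.str.startswith("strong").sum()),
            "moderate": int(cats.str.startswith("moderate").sum()),
        }
    n_shared = int(merged["agreement"].str.startswith("shared").sum())
    tallies["shared"] = {
        "total": n_shared,
        "conflict": int((merged["agreement"] == "shared-conflict").sum()),
    }
    denom = tallies["nmix"]["significant"] + tallies["occ"]["significant"]
    shared_fraction = 2.0 * n_shared / denom if denom else 1.0
    return ComparisonReport(table=merged, tallies=tallies,
                            shared_fraction=shared_fraction)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    outdir: str = "camuse_run"
    seed: int = 0
    mode: str = "synthetic"                  # or "files"
    # synthetic-mode scale
    n_sites: int = 150
    n_occasions: int = 16
    species: tuple[str, ...] = synth.SPECIES
    # file-mode inputs
    events_file: str | None = None
    deployments_file: str | None = None
    covariates_file: str | None = None
    # processing
    gap_minutes: dict = field(default_factory=lambda: dict(synth.DEFAULT_GAPS))
    merge_radius_m: float = 15.0
    deployment_cap: int = 4
    occasion_length_days: int = 7
    # covariate prep
    screen_threshold: float = 0.7
    resolve_groups: bool = True
    resolve_model: str = "occupancy"
    # fitting
    n_chains: int = 3
    n_iter: int = 6000
    n_burnin: int = 2000
    ppc_draws: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species"] = list(d["species"])
        return d


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    comparison: ComparisonReport


class PipelineError(RuntimeError):
    """Raised with the failing stage's name for quick triage."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"[stage {name}] {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full paired-model analysis and write all artefacts.

    Stages: simulate (synthetic mode) or load (file mode) -> process
    events into count/binary histories -> covariate standardization,
    collinearity screen and group resolution -> both model fits ->
    diagnostics and significance -> cross-model comparison -> manifest.
    Outputs are deterministic given the config (including its seed):
    re-running with an identical config reproduces byte-identical tables.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    warnings_: list[str] = []
    seed = int(config.seed)
    species = list(config.species)

    with _stage("simulate" if config.mode == "synthetic" else "load"):
        if config.mode == "synthetic":
            design = synth.default_design(
                config.n_sites, config.n_occasions, tuple(species), seed=seed
            )
            cov_table = synth.gen_site_covariates(
                config.n_sites, design.covariate_corr, seed=seed + 1
            )
            truth = synth.gen_community_truth(
                synth.default_nmixture_hypers(len(design.covariate_names)),
                n_species=len(species), n_replicates=4, seed=seed + 2,
                species_names=species,
                covariate_names=design.covariate_names,
            )
            X = covmod.standardize(cov_table).design_matrix
            rng = np.random.default_rng(seed + 3)
            lam = np.exp(X @ truth.species_effects.T)
            abundance = rng.poisson(lam)
            deployments = synth.gen_deployments(design, seed=seed + 4)
            rates = pd.DataFrame(
                abundance * 0.02,
                index=pd.Index(cov_table.site_ids, name="site_id"),
                columns=species,
            )
            bg = np.random.default_rng(seed + 5)
            rates["human"] = bg.lognormal(0, 0.75, size=len(rates))
            rates["vehicle"] = 0.5 * bg.lognormal(0, 0.75, size=len(rates))
            events = synth.gen_event_stream(
                rates, deployments, seed=seed + 6, focal_species=tuple(species)
            )
            events.to_csv(out / "events.csv", index=False)
            deployments.to_csv(out / "deployments.csv", index=False)
            cov_table.to_csv(out / "covariates.csv")
            truth.to_json(out / "truth.json")
        else:
            for name in ("events_file", "deployments_file", "covariates_file"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input {name}: {p}")
            events = evmod.read_events(config.events_file)
            deployments = evmod.read_deployments(config.deployments_file)
            cov_table = covmod.SiteCovariateTable.from_csv(config.covariates_file)
        counters["raw_events"] = len(events)
        counters["deployments"] = len(deployments)

    with _stage("process"):
        merged = evmod.merge_sites(deployments, config.merge_radius_m)
        counters["sites_after_merge"] = merged["site_id"].nunique()
        selected = evmod.select_deployments(merged, config.deployment_cap)
        counters["deployments_selected"] = len(selected)
        # events inherit the canonical site ids of their deployment
        dep_site = merged.set_index("deployment_id")["site_id"]
        events = events.assign(site_id=events["deployment_id"].map(dep_site))
        filtered = evmod.filter_independent_events(events, config.gap_minutes)
        counters["independent_events"] = int(
            filtered["species"].isin(species).sum()
        )
        histories = evmod.build_count_histories(
            filtered, selected, species,
            occasion_length_days=config.occasion_length_days,
        )
        counters["survey_days"] = int(round(histories.effort[histories.mask].sum()))
        counters["detections"] = int(histories.counts.sum())
        histories.write(out / "histories_counts.csv")
        binary = histories.binarize()
        binary.write(out / "histories_binary.csv")
        trap_rates = evmod.compute_trap_rates(filtered, selected)

    with _stage("covariates"):
        raw = cov_table.raw.loc[[str(s) for s in histories.site_ids]]
        raw = raw.join(trap_rates)
        full = covmod.standardize(covmod.SiteCovariateTable(raw=raw))
        screen = covmod.correlation_screen(full, config.screen_threshold)
        screen.to_json(out / "covariate_screen.json")
        counters["covariate_groups"] = len(screen.groups)
        drop: list[str] = []
        resolutions = {}
        if config.resolve_groups and screen.groups:
            short = FitConfig(
                n_chains=2, n_iter=1500, n_burnin=700, seed=seed + 10
            )
            for group in screen.groups:
                data = histories if config.resolve_model == "nmixture" else binary
                res = covmod.univariate_compare(
                    group, data, full, config.resolve_model, short
                )
                resolutions[",".join(group)] = {
                    "selected": res.selected,
                    "status": res.status,
                }
                drop.extend(c for c in group if c != res.selected)
        else:
            # unresolved: keep the alphabetically first member of each group
            for group in screen.groups:
                drop.extend(sorted(group)[1:])
        survivors = [c for c in full.names if c not in drop]
        final_cov = full.subset(survivors)
        final_cov.to_csv(out / "covariates_final.csv")
        (out / "covariate_resolution.json").write_text(
            json.dumps({"dropped": sorted(drop), "survivors": survivors,
                        "resolutions": resolutions}, indent=1, sort_keys=True)
        )

    fit_cfg = FitConfig(
        n_chains=config.n_chains, n_iter=config.n_iter,
        n_burnin=config.n_burnin, priors=PriorConfig(),
        seed=seed + 20,
    )
    with _stage("fit-nmix"):
        draws_n = fit_nmixture(histories, final_cov, fit_cfg)
        draws_n.to_netcdf(out / "draws_nmix.nc")
        summary_n = pd.concat(
            [
                derive_expected_count(draws_n).assign(parameter="expected_count"),
                derive_detection_prob_nmix(draws_n)
                .reset_index()
                .set_index("species")
                .assign(parameter="detection_prob"),
            ]
        )
        summary_n.to_csv(out / "summary_nmix.csv", float_format="%.6g")
    with _stage("fit-occ"):
        draws_o = fit_occupancy(binary, final_cov, replace(fit_cfg, seed=seed + 21))
        draws_o.to_netcdf(out / "draws_occ.nc")
        summary_o = pd.concat(
            [
                derive_site_use(draws_o).assign(parameter="site_use"),
                derive_detection_prob_occ(draws_o)
                .reset_index()
                .set_index("species")
                .assign(parameter="detection_prob"),
            ]
        )
        summary_o.to_csv(out / "summary_occ.csv", float_format="%.6g")

    with _stage("diagnose"):
        diag_n = posterior_predictive_check(
            draws_n, histories, final_cov, seed=seed + 30, n_rep=config.ppc_draws
        )
        diag_o = posterior_predictive_check(
            draws_o, binary, final_cov, seed=seed + 31, n_rep=config.ppc_draws
        )
        diag_n.to_json(out / "diagnostics_nmix.json")
        diag_o.to_json(out / "diagnostics_occ.json")
        for label, diag in (("nmix", diag_n), ("occ", diag_o)):
            if not diag.converged:
                warnings_.append(f"{label}: max R-hat {diag.max_rhat:.3f} >= 1.1")
                log.warning("%s fit not converged (max R-hat %.3f)",
                            label, diag.max_rhat)
        sig_n = significance_table(draws_n)
        sig_o = significance_table(draws_o)
        sig_n.to_csv(out / "significance_nmix.csv", index=False,
                     float_format="%.6g")
        sig_o.to_csv(out / "significance_occ.csv", index=False,
                     float_format="%.6g")

    with _stage("compare"):
        comparison = compare_models(sig_n, sig_o)
        comparison.to_json(out / "comparison.json")

    cfg_dict = config.to_dict()
    cfg_dict.pop("outdir")  # identical runs into different directories hash alike
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "counters": counters,
        "warnings": warnings_,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(outdir=out, manifest=manifest, comparison=comparison)


def _versions() -> dict[str, str]:
    import scipy
    import xarray

    from . import __version__

    return {
        "camuse": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "xarray": xarray.__version__,
    }
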