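import numpy as np
import pandas as pd
import pytest

from camuse import FitConfig
from camuse.calibration import run_calibration_study
from camuse.covariates import SiteCovariateTable, standardize
from camuse.mcmc import calibration_priors
from camuse.synthetic import (
    HyperConfig,
    default_design,
    gen_community_truth,
    gen_detection_histories,
    gen_site_covariates,
)


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic N-mixture study shared by the fitting unit tests.

    60 sites, 3 species, 12 occasions, moderate detection so the data are
    informative enough for short-chain fits.
    """
    cfg = HyperConfig(
        state_hyper_mean=[0.5, 0.2, -0.3],
        state_hyper_sd=[0.3, 0.2, 0.2],
        detect_hyper_mean=[-1.8, -2.0, -2.2, -1.6],
        detect_hyper_sd=0.2,
        overdispersion_sd=0.4,
    )
    design = default_design(60, 12, seed=10)
    cov = standardize(
        gen_site_covariates(60, np.eye(2), seed=11, names=["u", "v"])
    )
    truth = gen_community_truth(cfg, 3, 4, seed=12)
    data, latent = gen_detection_histories(truth, cov, design, "nmixture", seed=13)
    return {"design": design, "cov": cov, "truth": truth, "data": data,
            "latent": latent, "hypers": cfg}


@pytest.fixture(scope="session")
def short_fit_config():
    return FitConfig(
        n_chains=2, n_iter=1600, n_burnin=800, seed=5,
        priors=calibration_priors(3), n_quad=9,
    )


@pytest.fixture(scope="session")
def nmix_calibration():
    """20-replicate simulation-based calibration of the N-mixture fit at the
    survey footprint, with posterior predictive checks."""
    return run_calibration_study(
        "nmixture", n_replicates=20, seed=0, with_ppc=True
    )


@pytest.fixture(scope="session")
def occ_calibration():
    """20-replicate simulation-based calibration of the occupancy fit."""
    return run_calibration_study("occupancy", n_replicates=20, seed=0)


@pytest.fixture()
def event_frame():
    """Hand-built raw events at one site: a bear stream at known minute
    offsets plus a human passthrough record."""
    t0 = pd.Timestamp("2015-06-01 08:00:00")
    rows = [
        ("s1", "d1", t0 + pd.Timedelta(minutes=m), "bear") for m in (0, 5, 12, 30)
    ] + [("s1", "d1", t0 + pd.Timedelta(minutes=2), "human")]
    return pd.DataFrame(rows, columns=["site_id", "deployment_id", "timestamp",
                                       "species"])


def make_deployments(rows):
    df = pd.DataFrame(
        rows, columns=["deployment_id", "site_id", "easting", "northing",
                       "start", "end"]
    )
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


@pytest.fixture()
def covariate_table():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(200)
    raw = pd.DataFrame(
        {
            "a": x,
            "b": 2.0 * x + 0.1 * rng.standard_normal(200),  # |r| ~ 1 with a
            "c": rng.standard_normal(200),
        },
        index=pd.Index([f"s{i}" for i in range(200)], name="site_id"),
    )
    return SiteCovariateTable(raw=raw)
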