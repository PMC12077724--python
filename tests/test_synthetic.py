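"""Synthetic-study generator: covariate correlation, community truth,
detection-history structure, event streams, and generative consistency."""

import numpy as np
import pandas as pd
import pytest

from camuse.covariates import standardize
from camuse.synthetic import (
    BurstSpec,
    HyperConfig,
    default_covariate_corr,
    default_design,
    gen_community_truth,
    gen_deployments,
    gen_detection_histories,
    gen_event_stream,
    gen_site_covariates,
)
from camuse.events import filter_independent_events


class TestSiteCovariates:
    def test_identity_corr_uncorrelated(self):
        tab = gen_site_covariates(10000, np.eye(3), seed=0, names=list("abc"))
        corr = tab.raw.corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_requested_correlation_reproduced(self):
        corr = np.array([[1.0, 0.95], [0.95, 1.0]])
        tab = gen_site_covariates(10000, corr, seed=1, names=["a", "b"])
        assert tab.raw.corr().loc["a", "b"] > 0.9

    def test_empty_table(self):
        tab = gen_site_covariates(0, np.eye(2), seed=0, names=["a", "b"])
        assert tab.n_sites == 0
        assert tab.names == ["a", "b"]

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            gen_site_covariates(10, bad, seed=0, names=list("abc"))

    def test_default_corr_matches_screened_structure(self):
        # slope/roughness/1km/10km block is mutually |r|>0.7-linked; the
        # 500 m buffer stays outside it
        corr = pd.DataFrame(default_covariate_corr())
        from camuse.synthetic import COVARIATE_NAMES

        corr.index = corr.columns = list(COVARIATE_NAMES)
        assert corr.loc["slope", "roughness"] > 0.7
        assert corr.loc["slope", "forest_1km"] > 0.7
        assert abs(corr.loc["forest_500m", "forest_10km"]) < 0.7
        assert np.linalg.eigvalsh(corr.to_numpy()).min() > 0


class TestCommunityTruth:
    CFG = HyperConfig(
        state_hyper_mean=[0.5, 0.2], state_hyper_sd=[0.3, 0.1],
        detect_hyper_mean=[-2.0, -2.2], detect_hyper_sd=0.2,
        overdispersion_sd=0.3,
    )

    def test_zero_variance_collapses_to_mean(self):
        cfg = HyperConfig(
            state_hyper_mean=[0.5, 0.2], state_hyper_sd=[0.0, 0.0],
            detect_hyper_mean=[-2.0], detect_hyper_sd=0.0,
        )
        truth = gen_community_truth(cfg, 5, 1, seed=0)
        assert np.allclose(truth.species_effects, [0.5, 0.2])
        assert np.allclose(truth.detect_intercepts, -2.0)

    def test_same_seed_identical(self):
        a = gen_community_truth(self.CFG, 3, 2, seed=7)
        b = gen_community_truth(self.CFG, 3, 2, seed=7)
        assert np.array_equal(a.species_effects, b.species_effects)
        assert np.array_equal(a.detect_intercepts, b.detect_intercepts)

    def test_law_of_large_numbers(self):
        cfg = HyperConfig(
            state_hyper_mean=[0.0], state_hyper_sd=[1.0],
            detect_hyper_mean=[-2.0], detect_hyper_sd=0.1,
        )
        truth = gen_community_truth(cfg, 1000, 1, seed=3)
        assert abs(truth.species_effects[:, 0].mean()) < 0.1

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="hyper sds"):
            HyperConfig(
                state_hyper_mean=[0.0], state_hyper_sd=[-0.1],
                detect_hyper_mean=[-2.0], detect_hyper_sd=0.2,
            )

    def test_json_roundtrip(self, tmp_path):
        from camuse.synthetic import CommunityTruth

        truth = gen_community_truth(self.CFG, 3, 2, seed=9)
        truth.to_json(tmp_path / "t.json")
        back = CommunityTruth.from_json(tmp_path / "t.json")
        assert np.array_equal(truth.species_effects, back.species_effects)


class TestDetectionHistories:
    def _setup(self, overdispersion=0.0, detect=-2.0, n_sites=40, occ=8):
        cfg = HyperConfig(
            state_hyper_mean=[0.4, 0.2], state_hyper_sd=[0.2, 0.1],
            detect_hyper_mean=[detect] * 4, detect_hyper_sd=0.0,
            overdispersion_sd=overdispersion,
        )
        design = default_design(n_sites, occ, seed=1)
        cov = standardize(gen_site_covariates(n_sites, np.eye(1), seed=2,
                                              names=["x"]))
        truth = gen_community_truth(cfg, 2, 4, seed=3)
        return truth, cov, design

    def test_zero_detection_limit(self):
        truth, cov, design = self._setup()
        truth.detect_intercepts[:] = -np.inf
        data, _ = gen_detection_histories(truth, cov, design, "nmixture", seed=4)
        assert data.counts.sum() == 0

    def test_unoccupied_sites_yield_no_detections(self):
        truth, cov, design = self._setup(detect=2.0)
        data, latent = gen_detection_histories(truth, cov, design, "occupancy",
                                               seed=5)
        empty = latent.occupancy == 0
        per_site = data.counts.sum(axis=1)
        assert (per_site[empty] == 0).all()

    def test_unknown_model_kind(self):
        truth, cov, design = self._setup()
        with pytest.raises(ValueError, match="model_kind"):
            gen_detection_histories(truth, cov, design, "royle", seed=0)

    def test_determinism(self):
        truth, cov, design = self._setup()
        a, _ = gen_detection_histories(truth, cov, design, "nmixture", seed=6)
        b, _ = gen_detection_histories(truth, cov, design, "nmixture", seed=6)
        assert np.array_equal(a.counts, b.counts)

    def test_generative_mean_matches_thinned_poisson(self):
        # E[y] = lambda * rho for the binomial thinning of a Poisson count
        truth, cov, design = self._setup(detect=-1.0, n_sites=400, occ=16)
        data, latent = gen_detection_histories(truth, cov, design, "nmixture",
                                               seed=7)
        rho = 1 / (1 + np.exp(1.0))
        expected = (latent.site_rate[:, None, :] * rho * data.mask[:, :, None])
        obs = data.counts[data.mask].mean()
        assert obs == pytest.approx(expected[data.mask].mean(), rel=0.05)

    def test_occupancy_detection_marginal(self):
        # P(>=1 detection over J occasions) = psi (1 - (1-rho)^J)
        truth, cov, design = self._setup(detect=-1.5, n_sites=3000, occ=8)
        data, latent = gen_detection_histories(truth, cov, design, "occupancy",
                                               seed=8)
        rho = 1 / (1 + np.exp(1.5))
        J = data.mask.sum(axis=1)
        p_detected = latent.site_use_prob * (1 - (1 - rho) ** J[:, None])
        frac = (data.counts.sum(axis=1) > 0).mean()
        assert frac == pytest.approx(p_detected.mean(), abs=0.02)

    def test_binarized_counts_dominate_shared_latent_occupancy(self):
        # where n > 0 the count history, binarized, marks site use
        truth, cov, design = self._setup(detect=0.0)
        data, latent = gen_detection_histories(truth, cov, design, "nmixture",
                                               seed=9)
        detected = data.counts.sum(axis=1) > 0
        assert (latent.occupancy[detected] == 1).all()


class TestEventStream:
    def _deployments(self, n_sites=5):
        design = default_design(n_sites, 8, seed=0)
        return design, gen_deployments(design, seed=1)

    def test_zero_rates_empty(self):
        design, deps = self._deployments()
        rates = pd.DataFrame(
            0.0, index=pd.Index([f"s{i:03d}" for i in range(5)], name="site_id"),
            columns=["bear", "human"],
        )
        ev = gen_event_stream(rates, deps, seed=2)
        assert ev.empty

    def test_same_seed_identical(self):
        design, deps = self._deployments()
        rates = pd.DataFrame(
            0.5, index=pd.Index([f"s{i:03d}" for i in range(5)], name="site_id"),
            columns=["bear", "human"],
        )
        a = gen_event_stream(rates, deps, seed=3)
        b = gen_event_stream(rates, deps, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_rates_rejected(self):
        design, deps = self._deployments()
        rates = pd.DataFrame(
            -0.1, index=pd.Index(["s000"], name="site_id"), columns=["bear"]
        )
        with pytest.raises(ValueError, match="rates"):
            gen_event_stream(rates, deps, seed=0)

    def test_burst_collapses_to_one_independent_event(self):
        # 5 records within 2 minutes for a 10-minute-gap species -> 1 kept
        t0 = pd.Timestamp("2015-06-01 12:00:00")
        ev = pd.DataFrame(
            [("s1", "d1", t0 + pd.Timedelta(seconds=s), "bear")
             for s in (0, 20, 50, 80, 110)],
            columns=["site_id", "deployment_id", "timestamp", "species"],
        )
        kept = filter_independent_events(ev, {"bear": 10.0})
        assert len(kept) == 1

    def test_echoes_removed_by_filter(self):
        design, deps = self._deployments()
        rates = pd.DataFrame(
            1.0, index=pd.Index([f"s{i:03d}" for i in range(5)], name="site_id"),
            columns=["bear"],
        )
        spec = BurstSpec(echo_prob=1.0, echo_mean=3.0, echo_window_minutes=2.0)
        ev = gen_event_stream(rates, deps, cluster_spec=spec, seed=4)
        kept = filter_independent_events(ev, {"bear": 10.0})
        assert len(kept) < len(ev)

    def test_events_fall_inside_deployment_windows(self):
        design, deps = self._deployments()
        rates = pd.DataFrame(
            1.0, index=pd.Index([f"s{i:03d}" for i in range(5)], name="site_id"),
            columns=["bear", "vehicle"],
        )
        ev = gen_event_stream(rates, deps, seed=5)
        merged = ev.merge(deps, on=["site_id", "deployment_id"])
        assert (merged["timestamp"] >= merged["start"]).all()
        assert (merged["timestamp"] < merged["end"]).all()
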