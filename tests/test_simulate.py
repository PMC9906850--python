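"""Generator correctness: known-truth draws, determinism, planted artifacts."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from owlmove import simulate
from owlmove.simulate import SimConfig


def _cohort(**kw):
    cfg = SimConfig(**kw)
    meta, truth = simulate.simulate_cohort(cfg)
    return cfg, meta, truth


class TestCohort:
    def test_degenerate_variances_collapse_individuals(self):
        cfg, _, truth = _cohort(n_individuals=12, tau_u=0.0, tau_v=0.0, lambda_age=0.0, seed=1)
        ind = truth.individuals
        assert np.allclose(ind["u"], 0.0)
        assert np.allclose(ind["v"], 0.0)
        assert np.allclose(ind["riiv_true_km"], np.exp(cfg.lambda0))

    def test_random_effect_correlation_at_large_n(self):
        _, _, truth = _cohort(
            n_individuals=10_000, nights_per_individual=1, tau_u=0.5, rho=0.3, seed=2
        )
        r = np.corrcoef(truth.individuals["u"], truth.individuals["v"])[0, 1]
        assert abs(r - 0.3) < 0.02

    def test_same_seed_identical_outputs(self):
        _, meta1, t1 = _cohort(n_individuals=8, seed=5)
        _, meta2, t2 = _cohort(n_individuals=8, seed=5)
        pd.testing.assert_frame_equal(meta1, meta2)
        pd.testing.assert_frame_equal(t1.individuals, t2.individuals)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            SimConfig(rho=1.5)


class TestNightIndices:
    def test_noiseless_limit_recovers_individual_means(self):
        cfg = SimConfig(
            n_individuals=6, nights_per_individual=50, lambda0=np.log(1e-4),
            lambda_age=0.0, tau_v=0.0, beta_age=0.0, beta_sex=0.0, seed=3,
        )
        _, truth = simulate.simulate_cohort(cfg)
        nights = simulate.simulate_night_indices(cfg, truth)
        g = nights.groupby("individual")["d_true_km"]
        ind = truth.individuals.set_index("individual")
        assert (g.std() < 1e-3).all()
        expected = cfg.mu + ind["u"]
        assert np.allclose(g.mean(), expected.loc[g.mean().index], atol=1e-3)

    def test_age_specific_dispersion_preset(self):
        # adult sigma 1.23 km vs juvenile 2.25 km at the group-mean level
        cfg = SimConfig(
            n_individuals=200, nights_per_individual=200, tau_v=0.0,
            juvenile_fraction=0.5, transition_fraction=0.0, mu=6.0, seed=4,
        )
        _, truth = simulate.simulate_cohort(cfg)
        nights = simulate.simulate_night_indices(cfg, truth)
        sds = nights.groupby(["individual", "age_class"])["d_true_km"].std().reset_index()
        adult = sds[sds["age_class"] == "adult"]["d_true_km"].mean()
        juv = sds[sds["age_class"] == "juvenile"]["d_true_km"].mean()
        assert adult == pytest.approx(1.23, abs=0.1)
        assert juv == pytest.approx(2.25, abs=0.15)

    def test_variance_algebra_of_individual_means(self):
        cfg = SimConfig(
            n_individuals=100, nights_per_individual=100, tau_u=0.5, tau_v=0.0,
            lambda_age=0.0, beta_age=0.0, beta_sex=0.0, mu=5.0, seed=5,
        )
        _, truth = simulate.simulate_cohort(cfg)
        nights = simulate.simulate_night_indices(cfg, truth)
        means = nights.groupby("individual")["d_true_km"].mean()
        sigma = np.exp(cfg.lambda0)
        expected = np.sqrt(0.5**2 + sigma**2 / 100)
        assert means.std() == pytest.approx(expected, abs=0.1)

    def test_truncation_rare_at_unit_sigma(self):
        cfg = SimConfig(
            n_individuals=100, nights_per_individual=1000, mu=2.45, tau_u=0.0,
            tau_v=0.0, lambda0=0.0, lambda_age=0.0, beta_age=0.0, beta_sex=0.0,
            seed=6,
        )
        _, truth = simulate.simulate_cohort(cfg)
        simulate.simulate_night_indices(cfg, truth)
        assert truth.truncated_fraction < 0.01

    def test_empirical_sd_converges_to_true_riiv(self):
        # lambda_age off: over 10^4 nights every individual crosses the
        # age boundary, which would change sigma mid-series
        cfg = SimConfig(
            n_individuals=8, nights_per_individual=10_000, mu=6.0,
            beta_age=0.0, beta_sex=0.0, lambda_age=0.0, seed=7,
        )
        _, truth = simulate.simulate_cohort(cfg)
        nights = simulate.simulate_night_indices(cfg, truth)
        emp = nights.groupby("individual")["d_true_km"].std()
        ind = truth.individuals.set_index("individual")
        rel = np.abs(emp / ind.loc[emp.index, "riiv_true_km"] - 1)
        assert (rel < 0.05).all()


class TestNightTrack:
    def test_max_displacement_matches_target(self, small_track):
        d = np.hypot(small_track["x_m"] - small_track["x_m"][0],
                     small_track["y_m"] - small_track["y_m"][0]).max() / 1000
        step = 8.0 * 8.0 / 1000
        assert 2.6 - step <= d <= 2.6 + 1e-9

    def test_fix_count_is_window_over_interval(self, small_track):
        assert len(small_track) == 13 * 3600 // 8  # 5850

    def test_planted_stops_recovered_by_detector(self, small_track):
        from owlmove import indices

        t = small_track["time_utc_ms"].to_numpy() / 1000.0
        x = small_track["x_m"].to_numpy()
        y = small_track["y_m"].to_numpy()
        segs = indices.segment_moves_stops(t, x, y)
        lab = indices.stop_labels(segs, len(t))
        # truth: a fix is a planted stop when the noiseless position repeats
        true_stop = np.zeros(len(t), bool)
        same_next = (np.diff(small_track["x_true_m"]) == 0) & (np.diff(small_track["y_true_m"]) == 0)
        true_stop[:-1] |= same_next
        true_stop[1:] |= same_next
        recall = lab[true_stop].mean()
        assert recall >= 0.90

    def test_rejects_nonpositive_target(self):
        cfg = SimConfig(seed=0)
        with pytest.raises(ValueError):
            simulate.simulate_night_track(
                {"tag_id": 1, "nest_x_m": 0, "nest_y_m": 0}, date(2021, 1, 1), -1.0, cfg
            )


class TestArtifacts:
    def test_zero_rates_leave_track_unchanged(self, small_track):
        cfg = SimConfig(artifact_rate_std=0.0, artifact_rate_speed=0.0, seed=0)
        out = simulate.inject_artifacts(small_track, cfg)
        pd.testing.assert_frame_equal(out, small_track)

    def test_injection_reproducible_and_marked(self, small_track):
        cfg = SimConfig(artifact_rate_std=0.01, artifact_rate_speed=0.005, seed=9)
        a = simulate.inject_artifacts(small_track, cfg)
        b = simulate.inject_artifacts(small_track, cfg)
        pd.testing.assert_frame_equal(a, b)
        assert a["artifact_std"].sum() > 0
        assert (a.loc[a["artifact_std"], "std_m"] > 50).all()


class TestSurvival:
    def test_null_hazard_gives_equal_groups(self):
        cfg = SimConfig(
            n_individuals=2000, nights_per_individual=300, gamma_riiv=0.0,
            gamma_age=0.0, censor_day=300.0, seed=10,
        )
        _, truth = simulate.simulate_cohort(cfg)
        surv = simulate.simulate_survival(truth, cfg)
        ind = truth.individuals
        hi = ind["riiv_true_km"] > ind["riiv_true_km"].median()
        frac_hi = surv.loc[hi.to_numpy(), "event"].mean()
        frac_lo = surv.loc[~hi.to_numpy(), "event"].mean()
        assert abs(frac_hi - frac_lo) < 0.05

    def test_zero_censor_day_means_no_events(self):
        cfg = SimConfig(n_individuals=20, censor_day=0.0, seed=11)
        _, truth = simulate.simulate_cohort(cfg)
        surv = simulate.simulate_survival(truth, cfg)
        assert surv["event"].sum() == 0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(hazard_baseline=0.0)
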