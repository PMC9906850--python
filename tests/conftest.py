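"""Shared fixtures.

The expensive DHGLM recovery fit (60 individuals x 120 nights) is
session-scoped so the parameter-recovery assertions and the acceptance
checks share one MCMC run.
"""

import numpy as np
import pandas as pd
import pytest

from owlmove import dhglm, simulate


@pytest.fixture(scope="session")
def recovery_setup():
    """Pure variance-components cohort: tau_u=0.5, tau_v=0.4, rho=0.3."""
    cfg = simulate.SimConfig(
        n_individuals=60,
        nights_per_individual=120,
        tau_u=0.5,
        tau_v=0.4,
        rho=0.3,
        beta_age=0.0,
        beta_sex=0.0,
        lambda_age=0.0,
        seed=11,
    )
    _, truth = simulate.simulate_cohort(cfg)
    nights = simulate.simulate_night_indices(cfg, truth).rename(
        columns={"d_true_km": "max_disp_km"}
    )
    return cfg, truth, nights


@pytest.fixture(scope="session")
def recovery_fit(recovery_setup):
    cfg, truth, nights = recovery_setup
    spec = dhglm.DHGLMSpec(
        chains=4, iterations=4000, seed=11,
        response_floor=cfg.displacement_floor_km,
    )
    return dhglm.fit_dhglm(nights, spec)


@pytest.fixture()
def small_track():
    """A simple noiseless out-and-back track for index tests."""
    rng = np.random.default_rng(0)
    cfg = simulate.SimConfig(noise_sd_m=0.0, artifact_rate_std=0, artifact_rate_speed=0, seed=0)
    ind = {"tag_id": 1, "nest_x_m": 0.0, "nest_y_m": 0.0}
    from datetime import date

    return simulate.simulate_night_track(ind, date(2021, 3, 1), 2.6, cfg, rng)
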