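"""Shared fixtures: one synthetic study bundle plus the calibrated posteriors
and scenario ensembles computed from it, reused across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from soxplus import (
    SoxParams,
    SynthConfig,
    calibrate,
    make_bundle,
    run_scenario,
)

SEED = 1


@pytest.fixture(scope="session")
def base_params() -> SoxParams:
    return SoxParams()


@pytest.fixture(scope="session")
def bundle(base_params):
    """Full synthetic input bundle at the reference seed."""
    return make_bundle(SynthConfig(seed=SEED, truth=base_params))


@pytest.fixture(scope="session")
def posteriors(bundle, base_params):
    """Both model configurations calibrated at the reduced (10k x 3) scale."""
    out = {}
    for i, conf in enumerate(("Hydraulic", "Hydraulic+NSL")):
        out[conf] = calibrate(
            conf,
            bundle["transpiration"],
            bundle["drivers"],
            base_params,
            n_iterations=10_000,
            n_burn=6_667,
            n_chains=3,
            seed=SEED * 100 + 21 + i,
        )
    return out


@pytest.fixture(scope="session")
def scenario_ensembles(bundle, posteriors, base_params):
    """The three dry-down scenarios as 500-member posterior ensembles."""
    drivers = bundle["drivers"]
    la_obs = bundle["observed_la"]
    s1 = run_scenario(
        "Hydraulic", posteriors["Hydraulic"], drivers, base_params,
        ("observed", la_obs), n_runs=500, seed=SEED * 100 + 31,
    )
    s2 = run_scenario(
        "Hydraulic+NSL", posteriors["Hydraulic+NSL"], drivers, base_params,
        ("constant", None), n_runs=500, seed=SEED * 100 + 32,
    )
    s3 = run_scenario(
        "Hydraulic+NSL+shedding", posteriors["Hydraulic+NSL"], drivers, base_params,
        ("observed", la_obs), n_runs=500, seed=SEED * 100 + 33,
    )
    return {"Hydraulic": s1, "Hydraulic+NSL": s2, "Hydraulic+NSL+shedding": s3}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
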