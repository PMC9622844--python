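"""Shared fixtures: small synthetic networks generated once per session."""

import pytest

from arcticseb import harmonize as hz
from arcticseb import solar_norm as sol
from arcticseb import synthetic_data as syn


@pytest.fixture(scope="session")
def small_network():
    """Noisy 7-class network: 2 sites/class, 2 years, hourly, with gaps,
    outliers and gap-filled flags."""
    config = syn.SimConfig(
        n_sites_per_vegtype=2,
        years=(2004, 2005),
        timestep=60,
        gap_fraction=0.05,
        outlier_rate=0.001,
        gapfilled_fraction=0.01,
        seed=7,
    )
    records, metadata, snow, climate, truth = syn.generate_network(config)
    return {
        "config": config,
        "records": records,
        "metadata": metadata,
        "snow": snow,
        "climate": climate,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def clean_network():
    """Noise-free 1-site-per-class network: exact analytic oracles apply."""
    config = syn.SimConfig(
        n_sites_per_vegtype=1,
        years=(2010, 2010),
        timestep=60,
        noise_sd={v: 0.0 for v in syn.DEFAULT_NOISE_SD},
        gap_fraction=0.0,
        outlier_rate=0.0,
        gapfilled_fraction=0.0,
        replicate_probability=0.0,
        network_overlap_probability=0.0,
        seed=3,
    )
    records, metadata, snow, climate, truth = syn.generate_network(config)
    return {
        "config": config,
        "records": records,
        "metadata": metadata,
        "snow": snow,
        "climate": climate,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_daily(small_network):
    daily, report = hz.harmonize_pipeline(small_network["records"], 60)
    daily = sol.normalize_fluxes(daily, small_network["metadata"])
    return {"daily": daily, "report": report, **small_network}


@pytest.fixture(scope="session")
def clean_daily(clean_network):
    daily, report = hz.harmonize_pipeline(clean_network["records"], 60)
    daily = sol.normalize_fluxes(daily, clean_network["metadata"])
    return {"daily": daily, "report": report, **clean_network}
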