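"""Shared fixtures: small simulated datasets and a medium fitted model."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import seedbed as sb
from seedbed.covariates import TERM_NAMES


def make_series(temps, psis, start="2005-03-01", site_id="SX"):
    """Hourly microclimate frame from parallel temperature/potential arrays."""
    temps = np.asarray(temps, dtype=float)
    psis = np.asarray(psis, dtype=float)
    ts = pd.date_range(start, periods=len(temps), freq="h")
    return pd.DataFrame(
        {"site_id": site_id, "timestamp": ts, "soil_temp_c": temps, "soil_wp_mpa": psis}
    )


def random_series(rng, n_hours=8760, start="2005-01-01"):
    temps = rng.uniform(-10.0, 45.0, n_hours)
    psis = rng.uniform(-8.0, 0.0, n_hours)
    return make_series(temps, psis, start=start)


def normal_covariates(n, seed, sites=None):
    """Covariate rows with independent standard-normal term values."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list(TERM_NAMES))
    df.insert(0, "site_id", [f"S{i % (sites or n):04d}" for i in range(n)])
    df.insert(1, "obs_year", 2000 + np.arange(n) % 15)
    return df


@pytest.fixture(scope="session")
def small_sites():
    return sb.generate_sites(12, 3, seed=11)


@pytest.fixture(scope="session")
def seasonal_small():
    """Seasonal rate sums for 20 simulated sites over 6 observation years."""
    sites = sb.generate_sites(20, 4, seed=31)
    ss = np.random.SeedSequence(32).spawn(len(sites))
    monthly = []
    for i, (_, site) in enumerate(sites.iterrows()):
        series = sb.simulate_microclimate(
            site, 2004, 2010, int(ss[i].generate_state(1)[0] % 2**31)
        )
        monthly.append(sb.monthly_rate_sums(series))
    monthly = pd.concat(monthly, ignore_index=True)
    seasonal = sb.seasonal_rate_sums(monthly, range(2005, 2011))
    return sites, seasonal


@pytest.fixture(scope="session")
def presence_fit():
    """Presence model fitted to n=1500 synthetic rows with the default truth."""
    cov = normal_covariates(1500, seed=41, sites=150)
    truth = sb.SynthTruth()
    obs = sb.simulate_observations(cov, truth, seed=42)
    model = sb.fit_presence(cov, obs["presence"])
    return cov, truth, obs, model
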