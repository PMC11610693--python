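"""Synthetic sites, soil microclimate, and presence/cover observations.

The field pipeline this package serves consumes (a) hourly soil temperature
and water potential at 2 cm depth from a physical soil model and (b) field
observations of percent cover.  This module emulates both with known
statistical structure so the full chain — rate sums, covariates, additive
models, blocked validation, hindcast — can be exercised and verified without
external data.

The microclimate emulator is deliberately *statistical*, not physical: it
reproduces the features the rate-sum method is sensitive to — an elevation
lapse in mean soil temperature, annual and diurnal temperature cycles, a
south-facing warm bias scaled by slope, and episodic wetting with
exponential dry-down concentrated in an October–May wet season — and nothing
else (no snowpack, no canopy, no energy balance).

Observations are generated from four known smooth functions of the rate-sum
covariates (a concave-down response to mean fall favorability, a saturating
increase with mean spring favorability, a concave-down increase with the
fall anomaly, and a linear decrease with the spring anomaly), so that model
fits can be checked against the generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit
from scipy.stats import truncnorm
from sklearn.cluster import KMeans

from .covariates import TERM_NAMES

SITE_COLUMNS = [
    "site_id",
    "x_km",
    "y_km",
    "elevation_m",
    "aspect_deg",
    "slope_deg",
    "watershed_id",
    "sand_frac",
    "silt_frac",
    "clay_frac",
]

#: Cover above which an observation counts as a presence (percent).
PRESENCE_COVER_THRESHOLD = 2.0


@dataclass(frozen=True)
class SiteGenConfig:
    """Ranges for the random site generator."""

    x_range_km: tuple[float, float] = (0.0, 100.0)
    y_range_km: tuple[float, float] = (0.0, 100.0)
    elevation_range_m: tuple[float, float] = (800.0, 2500.0)
    slope_range_deg: tuple[float, float] = (0.0, 35.0)
    texture_alpha: tuple[float, float, float] = (2.0, 2.0, 2.0)


@dataclass(frozen=True)
class MicroclimateConfig:
    """Parameters of the statistical soil-microclimate emulator.

    Temperature (°C at 2 cm) is an annual mean declining with elevation at
    ``lapse_rate_c_per_km``, plus an annual cosine peaking on day-of-year
    ``seasonal_peak_doy`` (late July), a diurnal cosine peaking at
    ``diurnal_peak_hour`` local time, a south-facing warm bias proportional
    to sin(slope), AR(1) noise, and an optional linear warming trend applied
    to ``warming_months`` below a configurable elevation band (used to
    emulate climate-change scenarios).

    Water potential (MPa, <= 0) jumps to ``wet_value_mpa`` at Poisson wetting
    events — more frequent during the October–May wet season — then decays
    exponentially toward ``dry_floor_mpa`` with a shorter time constant in
    the warm months (faster summer dry-down).
    """

    ref_temp_c: float = 9.0
    ref_elevation_m: float = 1500.0
    lapse_rate_c_per_km: float = 6.5
    seasonal_amplitude_c: float = 10.0
    seasonal_peak_doy: float = 205.0
    diurnal_amplitude_c: float = 5.0
    diurnal_peak_hour: float = 14.0
    aspect_amplitude_c: float = 2.0
    noise_sd_c: float = 1.5
    noise_ar1: float = 0.95
    wet_value_mpa: float = -0.03
    dry_floor_mpa: float = -8.0
    wet_season_months: tuple = (10, 11, 12, 1, 2, 3, 4, 5)
    wet_event_rate_per_hour: float = 1.0 / 120.0
    dry_event_rate_per_hour: float = 1.0 / 720.0
    warm_months: tuple = (6, 7, 8, 9)
    dry_down_tau_hours_cool: float = 240.0
    dry_down_tau_hours_warm: float = 72.0
    fall_warming_c_per_year: float = 0.0
    warming_months: tuple = (10, 11, 12)
    warming_full_below_m: float = 1200.0
    warming_zero_above_m: float = 1800.0

    def __post_init__(self) -> None:
        if self.wet_value_mpa > 0 or self.dry_floor_mpa >= self.wet_value_mpa:
            raise ValueError("require dry_floor_mpa < wet_value_mpa <= 0")
        if min(self.wet_event_rate_per_hour, self.dry_event_rate_per_hour) < 0:
            raise ValueError("event rates must be >= 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class SynthTruth:
    """Generative truth for presence/cover observations.

    Presence is Bernoulli with logit ``beta0 + f1(fall_spatial) +
    f2(spring_spatial) + f3(fall_temporal) + f4(spring_temporal)`` where

    * ``f1(x) = fall_spatial_height − fall_spatial_curvature·(x − fall_spatial_peak)²``
      (concave-down: best at moderately favorable sites),
    * ``f2(x) = spring_spatial_amp·tanh(x)`` (increasing, saturating),
    * ``f3(x) = fall_temporal_amp·(1 − exp(−(x + 3)/fall_temporal_scale))``
      (increasing, concave-down),
    * ``f4(x) = spring_temporal_slope·x`` (decreasing linear for the default
      negative slope).

    Cover (percent) at presence sites is Gaussian around
    ``cover_intercept + cover_gain·Σ f_j``, truncated to (2, 100] so that a
    generated presence always exceeds the 2 % presence threshold; absences
    have cover 0.
    """

    beta0: float = -1.5
    fall_spatial_height: float = 1.5
    fall_spatial_peak: float = 0.5
    fall_spatial_curvature: float = 1.0
    spring_spatial_amp: float = 1.2
    fall_temporal_amp: float = 2.0
    fall_temporal_scale: float = 3.0
    spring_temporal_slope: float = -0.7
    cover_intercept: float = 12.0
    cover_gain: float = 3.0
    cover_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.cover_noise_sd <= 0:
            raise ValueError("cover_noise_sd must be > 0")

    def partial_effect(self, term: str, x) -> np.ndarray:
        """Evaluate one true (uncentered) partial-effect function."""
        x = np.asarray(x, dtype=float)
        if term == "fall_spatial":
            return self.fall_spatial_height - self.fall_spatial_curvature * (
                x - self.fall_spatial_peak
            ) ** 2
        if term == "spring_spatial":
            return self.spring_spatial_amp * np.tanh(x)
        if term == "fall_temporal":
            return self.fall_temporal_amp * (
                1.0 - np.exp(-(x + 3.0) / self.fall_temporal_scale)
            )
        if term == "spring_temporal":
            return self.spring_temporal_slope * x
        raise KeyError(f"unknown term: {term}")

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(covariates), self.beta0)
        for term in TERM_NAMES:
            eta += self.partial_effect(term, covariates[term].to_numpy(dtype=float))
        return eta

    @classmethod
    def null(cls, beta0: float = 0.0) -> "SynthTruth":
        """Truth with all four effect functions identically zero."""
        return cls(
            beta0=beta0,
            fall_spatial_height=0.0,
            fall_spatial_curvature=0.0,
            spring_spatial_amp=0.0,
            fall_temporal_amp=0.0,
            spring_temporal_slope=0.0,
        )


def generate_sites(
    n_sites: int,
    n_watersheds: int,
    seed: int,
    config: SiteGenConfig = SiteGenConfig(),
) -> pd.DataFrame:
    """Random sites with contiguous watershed groupings.

    Coordinates are uniform on the configured planar extent; watershed ids
    come from k-means clustering of (x, y), which yields spatially contiguous
    (Voronoi) groups.  Elevation, aspect and slope are uniform on their
    ranges; soil texture fractions are Dirichlet and sum to 1.
    """
    if n_sites <= 0 or n_watersheds <= 0:
        raise ValueError("n_sites and n_watersheds must be positive")
    if n_sites < n_watersheds:
        raise ValueError("need n_sites >= n_watersheds")
    if n_watersheds < 2:
        raise ValueError("need at least 2 watersheds for blocked validation")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*config.x_range_km, n_sites)
    y = rng.uniform(*config.y_range_km, n_sites)
    elevation = rng.uniform(*config.elevation_range_m, n_sites)
    aspect = rng.uniform(0.0, 360.0, n_sites)
    slope = rng.uniform(*config.slope_range_deg, n_sites)
    texture = rng.dirichlet(config.texture_alpha, n_sites)
    texture /= texture.sum(axis=1, keepdims=True)

    km = KMeans(
        n_clusters=n_watersheds,
        n_init=10,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    labels = km.fit_predict(np.column_stack([x, y]))
    # Relabel clusters in order of first appearance for stable ids.
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    width = len(str(n_watersheds))
    watershed = [f"W{remap[lab]:0{width}d}" for lab in labels]

    return pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(n_sites)],
            "x_km": x,
            "y_km": y,
            "elevation_m": elevation,
            "aspect_deg": aspect,
            "slope_deg": slope,
            "watershed_id": watershed,
            "sand_frac": texture[:, 0],
            "silt_frac": texture[:, 1],
            "clay_frac": texture[:, 2],
        }
    )


def simulate_microclimate(
    site,
    start_year: int,
    end_year: int,
    seed: int,
    config: MicroclimateConfig = MicroclimateConfig(),
) -> pd.DataFrame:
    """Hourly soil temperature and water potential for one site.

    ``site`` is a mapping (or dataframe row) with at least ``site_id``,
    ``elevation_m``, ``aspect_deg`` and ``slope_deg``.  Returns one row per
    hour over all full calendar years from ``start_year`` to ``end_year``
    inclusive, with columns (site_id, timestamp, soil_temp_c, soil_wp_mpa).
    """
    if start_year > end_year:
        raise ValueError("start_year must be <= end_year")
    rng = np.random.default_rng(seed)
    idx = pd.date_range(
        start=f"{start_year}-01-01", end=f"{end_year}-12-31 23:00", freq="h"
    )
    n = len(idx)
    month = idx.month.to_numpy()
    hour = idx.hour.to_numpy()
    doy = idx.dayofyear.to_numpy() + hour / 24.0
    year = idx.year.to_numpy()

    elev_km = float(site["elevation_m"]) / 1000.0
    mean_t = config.ref_temp_c - config.lapse_rate_c_per_km * (
        elev_km - config.ref_elevation_m / 1000.0
    )
    aspect_eff = (
        config.aspect_amplitude_c
        * np.cos(np.radians(float(site["aspect_deg"]) - 180.0))
        * np.sin(np.radians(float(site["slope_deg"])))
    )
    seasonal = config.seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - config.seasonal_peak_doy) / 365.25
    )
    diurnal = config.diurnal_amplitude_c * np.cos(
        2 * np.pi * (hour - config.diurnal_peak_hour) / 24.0
    )
    trend = np.zeros(n)
    if config.fall_warming_c_per_year != 0.0:
        lo, hi = config.warming_full_below_m, config.warming_zero_above_m
        w_elev = float(np.clip((hi - float(site["elevation_m"])) / (hi - lo), 0.0, 1.0))
        in_season = np.isin(month, config.warming_months)
        trend = (
            config.fall_warming_c_per_year * (year - start_year) * in_season * w_elev
        )
    phi = config.noise_ar1
    innovations = rng.standard_normal(n) * config.noise_sd_c * np.sqrt(1 - phi**2)
    noise = lfilter([1.0], [1.0, -phi], innovations)
    temp = mean_t + aspect_eff + seasonal + diurnal + trend + noise

    wet_season = np.isin(month, config.wet_season_months)
    event_rate = np.where(
        wet_season, config.wet_event_rate_per_hour, config.dry_event_rate_per_hour
    )
    events = rng.random(n) < event_rate
    events[0] = True  # initialize wet; with zero rates psi then decays monotonically
    tau = np.where(
        np.isin(month, config.warm_months),
        config.dry_down_tau_hours_warm,
        config.dry_down_tau_hours_cool,
    )
    decay = np.cumsum(1.0 / tau)
    last_event_decay = np.maximum.accumulate(np.where(events, decay, -np.inf))
    psi = config.dry_floor_mpa + (config.wet_value_mpa - config.dry_floor_mpa) * np.exp(
        -(decay - last_event_decay)
    )

    return pd.DataFrame(
        {
            "site_id": site["site_id"],
            "timestamp": idx,
            "soil_temp_c": temp,
            "soil_wp_mpa": psi,
        }
    )


def simulate_observations(
    covariates: pd.DataFrame, truth: SynthTruth, seed: int
) -> pd.DataFrame:
    """Draw presence/cover observations for the given covariate rows.

    Presence is Bernoulli(logistic(eta)) with ``eta`` from
    :meth:`SynthTruth.linear_predictor`.  Cover at presence sites is drawn
    from a normal truncated to (2, 100], so the recomputed presence flag
    (cover > 2 %) agrees with the Bernoulli draw; absences have cover 0.
    """
    missing = [t for t in TERM_NAMES if t not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing fields: {missing}")
    vals = covariates[list(TERM_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("covariate values must be finite")
    rng = np.random.default_rng(seed)
    eta = truth.linear_predictor(covariates)
    p = expit(eta)
    present = rng.random(len(p)) < p

    cover = np.zeros(len(p))
    if present.any():
        mean = truth.cover_intercept + truth.cover_gain * (eta[present] - truth.beta0)
        sd = truth.cover_noise_sd
        lo = (PRESENCE_COVER_THRESHOLD - mean) / sd
        hi = (100.0 - mean) / sd
        cover[present] = truncnorm.rvs(
            lo, hi, loc=mean, scale=sd, size=int(present.sum()), random_state=rng
        )
    out = pd.DataFrame(
        {
            "site_id": covariates["site_id"].to_numpy()
            if "site_id" in covariates.columns
            else np.arange(len(p)),
            "obs_year": covariates["obs_year"].to_numpy()
            if "obs_year" in covariates.columns
            else 0,
            "cover_percent": cover,
            "presence": cover > PRESENCE_COVER_THRESHOLD,
        }
    )
    return out


def truth_partial_effects(truth: SynthTruth, grid) -> dict[str, np.ndarray]:
    """True effect curves on ``grid``, each centered to mean zero over the grid.

    Centering matches the identifiability convention of fitted additive-model
    smooths, so these curves are directly comparable to
    :func:`seedbed.sdm.partial_effects` output.
    """
    grid = np.asarray(grid, dtype=float)
    out = {}
    for term in TERM_NAMES:
        f = truth.partial_effect(term, grid)
        out[term] = f - f.mean()
    return out


def write_sites_csv(sites: pd.DataFrame, path) -> None:
    sites[SITE_COLUMNS].to_csv(path, index=False)


def read_sites_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sites CSV missing columns: {missing}")
    return df
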