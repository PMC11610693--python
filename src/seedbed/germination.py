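"""Wet-thermal germination rates and rate-sum accumulation.

Germination progress of an annual-grass seed population is modeled as a
function of shallow-soil temperature that accrues only while the seedbed is
wet.  During any hour in which soil temperature ``T`` exceeds a base
temperature (0 °C) *and* soil water potential ``psi`` exceeds a wetness
threshold (−1.25 MPa), the hourly germination rate of the 35 % subpopulation
is a quadratic in temperature::

    rate(T) = c0 + c1*T + c2*T**2        (c0, c1, c2) = (1.29e-4, 6.16e-4, -1.25e-5)

Outside those conditions the rate is exactly zero.  Summing hourly rates over
a calendar window (a month, or a season such as October–December) yields a
dimensionless *rate sum*: the number of times the window's microclimate would
have carried the 35 % subpopulation through germination.  Rate sums are the
seedbed-favorability covariates consumed by the distribution models in
:mod:`seedbed.sdm`.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MICROCLIMATE_COLUMNS = ["site_id", "timestamp", "soil_temp_c", "soil_wp_mpa"]

#: Fall season months (accumulated in the year before the observation year).
FALL_MONTHS = (10, 11, 12)
#: Spring month (accumulated in the observation year itself).
SPRING_MONTH = 3


@dataclass(frozen=True)
class RateCurveParams:
    """Parameters of the hourly wet-thermal germination-rate curve.

    Attributes
    ----------
    poly_coeffs
        ``(c0, c1, c2)`` of the temperature response, in per-hour units.
        Defaults are the mean curve of the 35 % subpopulation across eight
        sagebrush-steppe seed lots.
    wet_threshold_mpa
        Water potential above which (i.e. wetter than) the seedbed counts as
        wet.  Strict inequality; an hour at exactly the threshold is dry.
    base_temp_c
        Temperature above which germination can progress.  Strict inequality.
    subpopulation_frac
        Fraction of the seed lot the curve describes (metadata only).
    form
        ``"quadratic"`` evaluates ``c0 + c1*T + c2*T**2`` (default);
        ``"linear"`` evaluates ``c0 + T*(c1 + c2)``, an alternative reading
        of the published coefficient list.  Both agree in the T -> 0+ limit.
    """

    poly_coeffs: tuple[float, float, float] = (1.29e-4, 6.16e-4, -1.25e-5)
    wet_threshold_mpa: float = -1.25
    base_temp_c: float = 0.0
    subpopulation_frac: float = 0.35
    form: str = "quadratic"

    def __post_init__(self) -> None:
        if len(self.poly_coeffs) != 3:
            raise ValueError("poly_coeffs must contain exactly three coefficients")
        if not self.wet_threshold_mpa < 0:
            raise ValueError("wet_threshold_mpa must be negative (wet means psi near 0)")
        if self.form not in ("quadratic", "linear"):
            raise ValueError(f"unknown rate-curve form: {self.form!r}")
        if not 0 < self.subpopulation_frac <= 1:
            raise ValueError("subpopulation_frac must lie in (0, 1]")


DEFAULT_PARAMS = RateCurveParams()


def germination_rate(soil_temp_c, soil_wp_mpa, params: RateCurveParams = DEFAULT_PARAMS):
    """Hourly germination rate at temperature ``soil_temp_c`` and potential ``soil_wp_mpa``.

    Vectorized over array inputs; scalars in, scalar out.  The rate is the
    temperature polynomial clipped at zero when ``T > base_temp_c`` and
    ``psi > wet_threshold_mpa`` (both strict), and exactly 0 otherwise.
    """
    T = np.asarray(soil_temp_c, dtype=float)
    psi = np.asarray(soil_wp_mpa, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(psi))):
        raise ValueError("soil temperature and water potential must be finite")
    c0, c1, c2 = params.poly_coeffs
    if params.form == "quadratic":
        poly = c0 + c1 * T + c2 * T * T
    else:
        poly = c0 + T * (c1 + c2)
    active = (T > params.base_temp_c) & (psi > params.wet_threshold_mpa)
    rate = np.where(active, np.clip(poly, 0.0, None), 0.0)
    if np.isscalar(soil_temp_c) and np.isscalar(soil_wp_mpa):
        return float(rate)
    return rate


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    """Check the hourly-microclimate invariants for a single-site series."""
    missing = [c for c in ("timestamp", "soil_temp_c", "soil_wp_mpa") if c not in series.columns]
    if missing:
        raise ValueError(f"microclimate series missing columns: {missing}")
    ts = pd.DatetimeIndex(series["timestamp"])
    if len(ts) == 0:
        raise ValueError("empty microclimate series")
    deltas = np.diff(ts.asi8)
    hour_ns = 3_600_000_000_000
    bad = np.nonzero(deltas != hour_ns)[0]
    if bad.size:
        i = bad[0]
        raise ValueError(
            f"non-hourly spacing in microclimate series: gap after {ts[i]} (next is {ts[i + 1]})"
        )
    psi = series["soil_wp_mpa"].to_numpy(dtype=float)
    if np.any(psi > 0):
        raise ValueError("soil water potential must be <= 0 MPa")
    return series


def hourly_rates(series: pd.DataFrame, params: RateCurveParams = DEFAULT_PARAMS) -> pd.Series:
    """Elementwise germination rate for every hour of a validated series."""
    _validate_series(series)
    rate = germination_rate(
        series["soil_temp_c"].to_numpy(dtype=float),
        series["soil_wp_mpa"].to_numpy(dtype=float),
        params,
    )
    return pd.Series(rate, index=series.index, name="rate")


def rate_sum(
    series: pd.DataFrame,
    window: tuple,
    params: RateCurveParams = DEFAULT_PARAMS,
) -> float:
    """Sum of hourly rates for timestamps in the half-open window ``[start, end)``.

    A window wholly disjoint from the series is an empty sum (0.0); a window
    that only partially overlaps the series raises, because silently
    truncating a seasonal sum would bias it low.
    """
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if not start < end:
        raise ValueError("window must be non-empty with start < end")
    _validate_series(series)
    ts = pd.DatetimeIndex(series["timestamp"])
    coverage_start, coverage_end = ts[0], ts[-1] + pd.Timedelta(hours=1)
    if end <= coverage_start or start >= coverage_end:
        return 0.0
    if start < coverage_start or end > coverage_end:
        raise ValueError(
            f"window [{start}, {end}) extends outside series coverage "
            f"[{coverage_start}, {coverage_end})"
        )
    mask = (ts >= start) & (ts < end)
    rates = hourly_rates(series, params)
    return float(rates.to_numpy()[mask].sum())


def _complete_month_mask(year: np.ndarray, month: np.ndarray) -> tuple:
    """Codes and completeness flags for (year, month) groups of an hourly index."""
    code = year * 12 + (month - 1)
    uniq, counts = np.unique(code, return_counts=True)
    expected = np.array(
        [calendar.monthrange(c // 12, c % 12 + 1)[1] * 24 for c in uniq], dtype=int
    )
    return code, uniq, counts == expected


def monthly_rate_sums(
    series: pd.DataFrame, params: RateCurveParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Germination rate sums per complete calendar month.

    Returns a frame with columns (site_id, year, month, rate_sum); partial
    boundary months are dropped with a logged warning.  Accepts a series
    containing one or more sites (validated per site).
    """
    if "site_id" in series.columns and series["site_id"].nunique() > 1:
        parts = [
            monthly_rate_sums(g, params) for _, g in series.groupby("site_id", sort=True)
        ]
        return pd.concat(parts, ignore_index=True)

    _validate_series(series)
    site_id = series["site_id"].iloc[0] if "site_id" in series.columns else ""
    ts = pd.DatetimeIndex(series["timestamp"])
    rates = hourly_rates(series, params).to_numpy()
    code, uniq, complete = _complete_month_mask(ts.year.to_numpy(), ts.month.to_numpy())
    sums = np.zeros(uniq.size)
    pos = np.searchsorted(uniq, code)
    np.add.at(sums, pos, rates)
    if not complete.all():
        dropped = [(int(c // 12), int(c % 12 + 1)) for c in uniq[~complete]]
        logger.warning("dropping partial boundary months for site %s: %s", site_id, dropped)
    out = pd.DataFrame(
        {
            "site_id": site_id,
            "year": (uniq[complete] // 12).astype(int),
            "month": (uniq[complete] % 12 + 1).astype(int),
            "rate_sum": sums[complete],
        }
    )
    return out


def seasonal_rate_sums(monthly: pd.DataFrame, obs_years) -> pd.DataFrame:
    """Fall (Oct–Dec of the prior year) and spring (March) sums per site and year.

    The fall sum for observation year ``y`` is the total over October,
    November and December of ``y - 1`` — the fall immediately preceding a
    growing-season observation in ``y``.  Site-years missing any constituent
    month are omitted with a logged warning.
    """
    obs_years = sorted(int(y) for y in obs_years)
    key = monthly.set_index(["site_id", "year", "month"])["rate_sum"]
    rows = []
    for site_id in sorted(monthly["site_id"].unique()):
        for y in obs_years:
            try:
                fall = sum(key[(site_id, y - 1, m)] for m in FALL_MONTHS)
                spring = key[(site_id, y, SPRING_MONTH)]
            except KeyError:
                logger.warning(
                    "incomplete monthly records for site %s, obs_year %d; row omitted",
                    site_id,
                    y,
                )
                continue
            rows.append((site_id, y, float(fall), float(spring)))
    return pd.DataFrame(
        rows, columns=["site_id", "obs_year", "fall_rate_sum", "spring_rate_sum"]
    )


def read_microclimate_csv(path) -> pd.DataFrame:
    """Read a long-format hourly microclimate CSV (the SHAW-output contract)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in MICROCLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"microclimate CSV missing columns: {missing}")
    return df[MICROCLIMATE_COLUMNS]
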