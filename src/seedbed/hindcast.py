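"""Multi-decade occupancy hindcast by elevation tercile and aspect class.

Applying the fitted presence model to covariates for every site and year of
a historical window (default 1990–2019) gives, per year, the fraction of
sites predicted occupied.  Sites are stratified into elevation terciles
(bottom/middle/top third of the dataset) and four aspect classes (N/E/S/W
azimuth quarters); trends are summarized per stratum by the ordinary
least-squares slope of occupied fraction on year and the relative change
between the fitted line's endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sdm import FittedGAM, predict

logger = logging.getLogger(__name__)

TERCILES = ("low", "mid", "high")
ASPECT_CLASSES = ("N", "E", "S", "W")


def aspect_class(aspect_deg: float) -> str:
    """N = [315,360) ∪ [0,45), E = [45,135), S = [135,225), W = [225,315)."""
    a = float(aspect_deg) % 360.0
    if a < 45.0 or a >= 315.0:
        return "N"
    if a < 135.0:
        return "E"
    if a < 225.0:
        return "S"
    return "W"


def stratify_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Elevation terciles (ties broken by site_id) and aspect classes per site.

    Terciles partition the sites into groups whose sizes differ by at most
    one, ranked by elevation; the lowest-ranked third is ``low``.
    """
    if len(sites) < 3:
        raise ValueError("need >= 3 sites to form elevation terciles")
    order = np.lexsort(
        (sites["site_id"].to_numpy(), sites["elevation_m"].to_numpy(dtype=float))
    )
    tercile = np.empty(len(sites), dtype=object)
    for label, chunk in zip(TERCILES, np.array_split(order, 3)):
        tercile[chunk] = label
    return pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy(),
            "elevation_tercile": tercile,
            "aspect_class": [aspect_class(a) for a in sites["aspect_deg"]],
        }
    )


def _stratum_column(strata: pd.DataFrame, by: str) -> pd.Series:
    if by == "tercile":
        return strata["elevation_tercile"].astype(str)
    if by == "tercile_aspect":
        return strata["elevation_tercile"].astype(str) + "/" + strata["aspect_class"].astype(str)
    raise ValueError(f"unknown stratification: {by!r}")


def annual_occupancy(
    model: FittedGAM,
    covariates: pd.DataFrame,
    strata: pd.DataFrame,
    threshold: float = 0.5,
    by: str = "tercile",
) -> pd.DataFrame:
    """Fraction of stratum sites predicted occupied, per year.

    ``covariates`` must contain one row for every (site, year) of the
    hindcast window; missing site-years raise, listing the offenders.
    Occupied means predicted probability strictly above ``threshold``.
    """
    if model.family != "binomial":
        raise ValueError("annual_occupancy requires the presence (binomial) model")
    sites = sorted(strata["site_id"].unique())
    years = sorted(covariates["obs_year"].unique())
    have = set(zip(covariates["site_id"], covariates["obs_year"]))
    missing = [(s, y) for s in sites for y in years if (s, y) not in have]
    if missing:
        raise KeyError(f"covariates missing site-years: {missing[:10]}")

    preds = predict(model, covariates, threshold=threshold)
    merged = preds.merge(strata, on="site_id", how="inner")
    merged["stratum"] = _stratum_column(merged, by)
    occ = (
        merged.groupby(["stratum", "obs_year"], sort=True)["label"]
        .mean()
        .rename("fraction_occupied")
        .reset_index()
        .rename(columns={"obs_year": "year"})
    )
    return occ


@dataclass
class TrendSummary:
    stratum: str
    slope_per_year: float
    relative_change_pct: float  # NaN when the fitted start value is <= 0


def trend_estimate(series: pd.DataFrame) -> pd.DataFrame:
    """OLS trend of occupied fraction on year, per stratum.

    The relative change over the window is ``100 * (fit_end − fit_start) /
    fit_start`` computed from the fitted line's endpoints (robust to
    single-year noise); it is undefined (NaN) when the fitted start is <= 0.
    Requires >= 3 years per stratum.
    """
    rows = []
    for stratum, g in series.groupby("stratum", sort=True):
        years = g["year"].to_numpy(dtype=float)
        frac = g["fraction_occupied"].to_numpy(dtype=float)
        if len(years) < 3:
            raise ValueError(f"stratum {stratum!r} has < 3 years; trend undefined")
        slope, intercept = np.polyfit(years, frac, 1)
        fit_start = intercept + slope * years.min()
        fit_end = intercept + slope * years.max()
        if fit_start > 0:
            rel = 100.0 * (fit_end - fit_start) / fit_start
        else:
            rel = float("nan")
            logger.info("stratum %s: fitted start <= 0; relative change undefined", stratum)
        rows.append(TrendSummary(str(stratum), float(slope), float(rel)))
    return pd.DataFrame([r.__dict__ for r in rows])


def plot_occupancy(series: pd.DataFrame, path) -> None:
    """Line plot of occupied fraction vs year, one line per stratum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for stratum, g in series.groupby("stratum", sort=True):
        ax.plot(g["year"], g["fraction_occupied"], marker="o", ms=3, label=str(stratum))
    ax.set_xlabel("year")
    ax.set_ylabel("fraction of sites predicted occupied")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
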