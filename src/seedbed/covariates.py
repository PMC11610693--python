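"""Spatial and temporal scaling of seasonal rate sums into model covariates.

The distribution and abundance models use four covariates derived from the
fall (Oct–Dec) and spring (March) germination rate sums:

* ``fall_spatial`` / ``spring_spatial`` — each site's long-term mean seasonal
  rate sum, z-scored *across sites* (between-site climate differences; 0
  means an average site).
* ``fall_temporal`` / ``spring_temporal`` — each site-year's seasonal rate
  sum, z-scored *within the site* across years (weather anomaly; 0 means an
  average year for that site).

Scaling constants are computed once (conventionally on the training site
set, to keep held-out watersheds untouched) and can be frozen to a file for
reuse on test data and in hindcasts.  Sample (n−1) standard deviations are
used throughout.  A site whose rate sums never vary across years — e.g. a
site too cold or dry to ever accumulate germination progress — gets temporal
anomalies of 0, encoding "an average year for this site".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

#: Covariate/term names, in canonical order.
TERM_NAMES = ("fall_spatial", "spring_spatial", "fall_temporal", "spring_temporal")

SEASONS = ("fall", "spring")

COVARIATE_COLUMNS = ["site_id", "obs_year"] + list(TERM_NAMES)


@dataclass
class ScalingConstants:
    """Frozen scaling constants for covariate construction.

    ``spatial[season]`` holds the across-site (mean, sd) of site-mean rate
    sums; ``temporal[(site_id, season)]`` holds the per-site (mean, sd) of
    that site's yearly rate sums.  ``provenance`` records which site set
    defined the spatial constants.
    """

    spatial: dict = field(default_factory=dict)
    temporal: dict = field(default_factory=dict)
    provenance: str = ""

    def to_yaml(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "spatial": {s: [float(m), float(sd)] for s, (m, sd) in self.spatial.items()},
            "temporal": {
                f"{site}|{season}": [float(m), float(sd)]
                for (site, season), (m, sd) in self.temporal.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScalingConstants":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        spatial = {s: tuple(v) for s, v in payload["spatial"].items()}
        temporal = {}
        for key, v in payload["temporal"].items():
            site, season = key.rsplit("|", 1)
            temporal[(site, season)] = tuple(v)
        return cls(spatial=spatial, temporal=temporal, provenance=payload["provenance"])


def spatial_scale(site_means: dict, constants: tuple | None = None):
    """Across-site z-scores of per-site mean rate sums.

    Returns ``(zscores, (mean, sd))``.  When ``constants`` is given it is
    applied unchanged (frozen training constants); otherwise the sample mean
    and sample SD of ``site_means`` define the scale and require >= 2 sites.
    """
    sites = sorted(site_means)
    values = np.array([site_means[s] for s in sites], dtype=float)
    if constants is None:
        if len(values) < 2:
            raise ValueError("spatial scaling needs >= 2 sites")
        mean, sd = float(values.mean()), float(values.std(ddof=1))
    else:
        mean, sd = float(constants[0]), float(constants[1])
    if sd == 0:
        raise ValueError("across-site SD is zero: degenerate spatial covariate")
    z = (values - mean) / sd
    return dict(zip(sites, z)), (mean, sd)


def temporal_scale(site_year_values: dict) -> dict:
    """Within-site z-scores across years.

    ``site_year_values`` maps ``(site, year) -> value``.  Sites with a single
    year or zero across-year SD get anomaly 0 for all their years (logged).
    """
    by_site: dict = {}
    for (site, year), v in site_year_values.items():
        by_site.setdefault(site, []).append((year, float(v)))
    out = {}
    for site, pairs in sorted(by_site.items()):
        vals = np.array([v for _, v in pairs])
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            logger.info("site %s has degenerate across-year variance; anomalies set to 0", site)
            for year, _ in pairs:
                out[(site, year)] = 0.0
        else:
            mean, sd = vals.mean(), vals.std(ddof=1)
            for year, v in pairs:
                out[(site, year)] = (v - mean) / sd
    return out


def _seasonal_column(season: str) -> str:
    return f"{season}_rate_sum"


def compute_constants(
    seasonal: pd.DataFrame, spatial_sites=None, provenance: str = "all sites"
) -> ScalingConstants:
    """Scaling constants from a seasonal rate-sum table.

    Site means are taken over every year present in ``seasonal`` (the full
    reference period — climatology, not just observed years).  The across-site
    spatial constants are computed over ``spatial_sites`` when given (e.g. the
    training sites only), while per-site temporal constants are computed for
    every site present.
    """
    constants = ScalingConstants(provenance=provenance)
    for season in SEASONS:
        col = _seasonal_column(season)
        site_means = seasonal.groupby("site_id")[col].mean()
        if spatial_sites is not None:
            subset = site_means.loc[site_means.index.intersection(list(spatial_sites))]
        else:
            subset = site_means
        if len(subset) < 2:
            raise ValueError("spatial scaling needs >= 2 sites")
        mean, sd = float(subset.mean()), float(subset.std(ddof=1))
        if sd == 0:
            raise ValueError(f"across-site SD of {col} is zero: degenerate covariate")
        constants.spatial[season] = (mean, sd)
        grouped = seasonal.groupby("site_id")[col]
        for site, (m, s, k) in grouped.agg(["mean", "std", "count"]).iterrows():
            sd_site = 0.0 if (k < 2 or not np.isfinite(s)) else float(s)
            constants.temporal[(site, season)] = (float(m), sd_site)
    return constants


def build_covariates(
    seasonal: pd.DataFrame,
    site_years=None,
    constants: ScalingConstants | None = None,
) -> tuple[pd.DataFrame, ScalingConstants]:
    """Covariate rows for the requested site-years.

    ``site_years`` is an iterable of ``(site_id, obs_year)``; by default every
    site-year present in ``seasonal`` gets a row.  When ``constants`` is None
    they are computed from ``seasonal`` itself (all sites).  Requested
    site-years absent from the seasonal table raise, listing the offenders.
    """
    if constants is None:
        constants = compute_constants(seasonal)
    indexed = seasonal.set_index(["site_id", "obs_year"]).sort_index()
    if site_years is None:
        requested = list(indexed.index)
    else:
        requested = [(s, int(y)) for s, y in site_years]
        missing = [sy for sy in requested if sy not in indexed.index]
        if missing:
            raise KeyError(f"site-years missing from seasonal table: {missing[:10]}")

    site_means = {
        season: seasonal.groupby("site_id")[_seasonal_column(season)].mean()
        for season in SEASONS
    }
    rows = []
    for site, year in requested:
        row = {"site_id": site, "obs_year": year}
        for season in SEASONS:
            value = float(indexed.loc[(site, year), _seasonal_column(season)])
            sp_mean, sp_sd = constants.spatial[season]
            row[f"{season}_spatial"] = (float(site_means[season][site]) - sp_mean) / sp_sd
            if (site, season) in constants.temporal:
                t_mean, t_sd = constants.temporal[(site, season)]
            else:  # site outside the constants' provenance: use its own record
                t_mean, t_sd = float(site_means[season][site]), float(
                    seasonal.loc[seasonal["site_id"] == site, _seasonal_column(season)].std(
                        ddof=1
                    )
                )
            row[f"{season}_temporal"] = 0.0 if (t_sd == 0 or not np.isfinite(t_sd)) else (
                value - t_mean
            ) / t_sd
        rows.append(row)
    return pd.DataFrame(rows, columns=COVARIATE_COLUMNS), constants


def screen_covariates(cover: dict, candidates: dict) -> pd.DataFrame:
    """Rank candidate rate-sum metrics by |Pearson r| with percent cover.

    ``cover`` maps ``(site, year) -> percent``; each candidate maps the same
    keys to its values.  Candidates are ranked by absolute correlation with
    ties broken alphabetically; constant candidates (undefined r) rank last.
    Requires >= 3 complete pairs per candidate.
    """
    rows = []
    any_pairs = False
    for name in sorted(candidates):
        keys = [k for k in cover if k in candidates[name]]
        if len(keys) >= 3:
            any_pairs = True
        x = np.array([cover[k] for k in keys], dtype=float)
        y = np.array([candidates[name][k] for k in keys], dtype=float)
        if len(keys) < 3 or x.std() == 0 or y.std() == 0:
            rows.append((name, np.nan, len(keys)))
        else:
            r = pearsonr(y, x).statistic
            rows.append((name, float(r), len(keys)))
    if not any_pairs:
        raise ValueError("no candidate has >= 3 complete pairs with cover")
    table = pd.DataFrame(rows, columns=["name", "r", "n_pairs"])
    defined = table["r"].notna()
    table["abs_r"] = table["r"].abs()
    table = pd.concat(
        [
            table[defined].sort_values(["abs_r", "name"], ascending=[False, True]),
            table[~defined].sort_values("name"),
        ]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[["rank", "name", "r", "abs_r", "n_pairs"]]


def write_covariates_csv(cov: pd.DataFrame, path) -> None:
    cov[COVARIATE_COLUMNS].to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate CSV missing columns: {missing}")
    return df
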