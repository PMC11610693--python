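"""Additive presence and cover models on the four rate-sum covariates.

Two generalized additive models relate seedbed favorability to the species:

* a binomial (logit) *presence* model,
  ``logit P(presence) = b0 + s1(fall_spatial) + s2(spring_spatial) +
  s3(fall_temporal) + s4(spring_temporal)``, and
* a Gaussian (identity) *cover* model with the same four smooth terms and
  raw percent cover as response (zeros included).

Each smooth is a penalized cubic B-spline with basis dimension ``k``
(default 10) and knots placed at quantiles of the training covariate values
(evenly through the data; equal spacing is configurable).  Smoothing
parameters are chosen per term by a deterministic coordinate-descent grid
search over the penalized fits from
:class:`statsmodels.gam.generalized_additive_model.GLMGam`, minimizing a
BIC on effective degrees of freedom by default — a conservative criterion
that, like REML, shrinks uninformative smooths to (near-)linear rather than
chasing noise the way AIC and GCV tend to (AIC and GCV remain configurable).

Fitted models serialize to JSON, storing the training covariate matrix so the
spline bases (whose knots are a deterministic function of the training
values) can be reconstructed exactly at load time.  Predictions for covariate
values outside the training range use the boundary value of each smooth
(constant extrapolation) and are flagged per row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.gam.api import GLMGam, BSplines
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .covariates import TERM_NAMES

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class GamConfig:
    """Settings for the additive-model fits.

    ``alpha_grid_log10`` spans the smoothing-parameter search grid (powers of
    ten); ``n_sweeps`` coordinate-descent passes over the four terms are
    made.  ``threshold`` is the presence classification cut on predicted
    probability (strict >).
    """

    k: int = 10
    degree: int = 3
    criterion: str = "bic"  # "bic" | "aic" | "gcv"
    knot_spacing: str = "quantile"  # "quantile" | "equal"
    alpha_grid_log10: tuple[float, float, int] = (-3.0, 5.0, 9)
    n_sweeps: int = 2
    threshold: float = 0.5
    maxiter: int = 200

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("basis dimension k must be >= 4 for cubic splines")
        if self.criterion not in ("aic", "bic", "gcv"):
            raise ValueError(f"unknown smoothing criterion: {self.criterion!r}")
        if self.knot_spacing not in ("quantile", "equal"):
            raise ValueError(f"unknown knot spacing: {self.knot_spacing!r}")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class PartialEffectCurve:
    """One centered smooth-term curve on the linear-predictor scale."""

    term: str
    grid: np.ndarray
    effect: np.ndarray
    se: np.ndarray


@dataclass
class FittedGAM:
    """A fitted additive model (presence or cover).

    Coefficients are ordered intercept first, then the basis coefficients of
    the four smooths in :data:`seedbed.covariates.TERM_NAMES` order.
    ``train_x`` (n × 4) is retained because the spline knots are a
    deterministic function of the training covariate values; rebuilding the
    basis from it reproduces the design exactly.
    """

    family: str  # "binomial" | "gaussian"
    config: GamConfig
    alpha: list
    params: np.ndarray
    cov_params: np.ndarray
    scale: float
    train_x: np.ndarray
    edf_per_term: dict
    edf_intercept: float
    n_train: int
    deviance: float
    llf: float

    # -- construction helpers -------------------------------------------------

    def smoother(self) -> BSplines:
        return _make_smoother(self.train_x, self.config)

    @property
    def term_names(self) -> tuple:
        return TERM_NAMES

    @property
    def train_ranges(self) -> dict:
        return {
            t: (float(self.train_x[:, i].min()), float(self.train_x[:, i].max()))
            for i, t in enumerate(TERM_NAMES)
        }

    def _coef_slices(self, smoother: BSplines) -> dict:
        out = {}
        start = 1  # intercept first
        for i, t in enumerate(TERM_NAMES):
            dim = smoother.smoothers[i].dim_basis
            out[t] = slice(start, start + dim)
            start += dim
        return out

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """Intercept plus smooth contributions; X values clipped to the training range."""
        smoother = self.smoother()
        Xc = np.column_stack(
            [
                np.clip(X[:, i], self.train_x[:, i].min(), self.train_x[:, i].max())
                for i in range(X.shape[1])
            ]
        )
        basis = np.column_stack(
            [smoother.smoothers[i].transform(Xc[:, i]) for i in range(Xc.shape[1])]
        )
        return self.params[0] + basis @ self.params[1:]

    # -- serialization --------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "version": SERIALIZATION_VERSION,
            "family": self.family,
            "config": asdict(self.config),
            "term_names": list(TERM_NAMES),
            "alpha": [float(a) for a in self.alpha],
            "params": self.params.tolist(),
            "cov_params": self.cov_params.tolist(),
            "scale": float(self.scale),
            "train_x": self.train_x.tolist(),
            "edf_per_term": {t: float(v) for t, v in self.edf_per_term.items()},
            "edf_intercept": float(self.edf_intercept),
            "n_train": int(self.n_train),
            "deviance": float(self.deviance),
            "llf": float(self.llf),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FittedGAM":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported model file version: {payload.get('version')}")
        cfg_fields = dict(payload["config"])
        for key in ("alpha_grid_log10",):
            cfg_fields[key] = tuple(cfg_fields[key])
        return cls(
            family=payload["family"],
            config=GamConfig(**cfg_fields),
            alpha=payload["alpha"],
            params=np.asarray(payload["params"]),
            cov_params=np.asarray(payload["cov_params"]),
            scale=payload["scale"],
            train_x=np.asarray(payload["train_x"]),
            edf_per_term=payload["edf_per_term"],
            edf_intercept=payload["edf_intercept"],
            n_train=payload["n_train"],
            deviance=payload["deviance"],
            llf=payload["llf"],
        )


def _make_smoother(X: np.ndarray, config: GamConfig) -> BSplines:
    return BSplines(
        X,
        df=[config.k] * X.shape[1],
        degree=[config.degree] * X.shape[1],
        variable_names=list(TERM_NAMES),
        knot_kwds=[{"spacing": config.knot_spacing}] * X.shape[1],
    )


def _covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    missing = [t for t in TERM_NAMES if t not in covariates.columns]
    if missing:
        raise KeyError(f"covariates missing terms: {missing}")
    X = covariates[list(TERM_NAMES)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariate values must be finite")
    return X


def _criterion_value(res, criterion: str, n: int) -> float:
    if criterion == "aic":
        return float(res.aic)
    if criterion == "bic":
        return float(res.bic_llf if hasattr(res, "bic_llf") else res.bic)
    edf = float(np.sum(res.edf))
    return float(n * res.deviance / (n - edf) ** 2)  # GCV


def _fit_once(y, exog, smoother, alpha, family, maxiter):
    model = GLMGam(y, exog=exog, smoother=smoother, alpha=list(alpha), family=family)
    try:
        res = model.fit(maxiter=maxiter)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise RuntimeError(f"additive-model fit failed: {err}") from err
    if not getattr(res, "converged", True):
        raise RuntimeError("additive-model fit did not converge")
    return res


def _select_alpha(y, exog, smoother, family, config: GamConfig):
    """Deterministic coordinate-descent over a log-spaced alpha grid."""
    lo, hi, npts = config.alpha_grid_log10
    grid = np.logspace(lo, hi, int(npts))
    alpha = np.ones(len(smoother.smoothers))
    n = len(y)
    for _ in range(config.n_sweeps):
        for j in range(len(alpha)):
            best = (np.inf, alpha[j])
            for a in grid:
                trial = alpha.copy()
                trial[j] = a
                res = _fit_once(y, exog, smoother, trial, family, config.maxiter)
                crit = _criterion_value(res, config.criterion, n)
                if crit < best[0]:
                    best = (crit, a)
            alpha[j] = best[1]
    return alpha


def _fit(X: np.ndarray, y: np.ndarray, family_name: str, config: GamConfig) -> FittedGAM:
    n = len(y)
    exog = np.ones((n, 1))
    smoother = _make_smoother(X, config)
    family = sm.families.Binomial() if family_name == "binomial" else sm.families.Gaussian()
    alpha = _select_alpha(y, exog, smoother, family, config)
    res = _fit_once(y, exog, smoother, alpha, family, config.maxiter)
    logger.info(
        "fitted %s additive model: n=%d, alpha=%s, edf=%.2f, criterion=%s",
        family_name,
        n,
        np.round(alpha, 4).tolist(),
        float(np.sum(res.edf)),
        config.criterion,
    )
    edf = np.asarray(res.edf)
    edf_per_term = {}
    start = 1
    for i, t in enumerate(TERM_NAMES):
        dim = smoother.smoothers[i].dim_basis
        edf_per_term[t] = float(edf[start : start + dim].sum())
        start += dim
    return FittedGAM(
        family=family_name,
        config=config,
        alpha=list(alpha),
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        scale=float(res.scale),
        train_x=X.copy(),
        edf_per_term=edf_per_term,
        edf_intercept=float(edf[0]),
        n_train=n,
        deviance=float(res.deviance),
        llf=float(res.llf),
    )


def fit_presence(
    covariates: pd.DataFrame, presence, config: GamConfig = GamConfig()
) -> FittedGAM:
    """Fit the binomial presence model.

    Requires at least 20 rows of each class; raises on single-class labels,
    complete separation, or non-convergence.
    """
    X = _covariate_matrix(covariates)
    y = np.asarray(presence, dtype=bool)
    if len(y) != len(X):
        raise ValueError("labels and covariates must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("presence labels contain a single class; cannot fit")
    if min(n_pos, n_neg) < 20:
        raise ValueError(
            f"need >= 20 rows per class (got {n_pos} presences, {n_neg} absences)"
        )
    return _fit(X, y.astype(float), "binomial", config)


def fit_abundance(
    covariates: pd.DataFrame, cover_percent, config: GamConfig = GamConfig()
) -> FittedGAM:
    """Fit the Gaussian cover model on raw percent cover (absences included)."""
    X = _covariate_matrix(covariates)
    y = np.asarray(cover_percent, dtype=float)
    if len(y) != len(X):
        raise ValueError("cover values and covariates must have equal length")
    if len(y) < 50:
        raise ValueError(f"need >= 50 rows to fit the cover model (got {len(y)})")
    if np.any(~np.isfinite(y)) or np.any(y < 0) or np.any(y > 100):
        raise ValueError("cover_percent must be finite and within [0, 100]")
    return _fit(X, y, "gaussian", config)


def predict(
    model: FittedGAM, covariates: pd.DataFrame, threshold: float | None = None
) -> pd.DataFrame:
    """Model predictions for covariate rows.

    For the presence model: ``probability`` in [0, 1] and ``label`` =
    (probability > threshold, strict).  For the cover model: ``cover_pred``
    (unclamped) and ``cover_pred_clamped`` in [0, 100].  Rows with any
    covariate outside the training range are flagged ``extrapolated`` (their
    smooth contributions use the boundary value).
    """
    X = _covariate_matrix(covariates)
    if threshold is None:
        threshold = model.config.threshold
    ranges = model.train_ranges
    extrapolated = np.zeros(len(X), dtype=bool)
    for i, t in enumerate(TERM_NAMES):
        lo, hi = ranges[t]
        extrapolated |= (X[:, i] < lo) | (X[:, i] > hi)
    eta = model.linear_predictor(X)
    out = pd.DataFrame(index=covariates.index)
    for col in ("site_id", "obs_year"):
        if col in covariates.columns:
            out[col] = covariates[col].to_numpy()
    if model.family == "binomial":
        prob = expit(eta)
        out["probability"] = prob
        out["label"] = prob > threshold
    else:
        out["cover_pred"] = eta
        out["cover_pred_clamped"] = np.clip(eta, 0.0, 100.0)
    out["extrapolated"] = extrapolated
    return out


def partial_effects(model: FittedGAM, n_grid: int = 100) -> list[PartialEffectCurve]:
    """Centered partial-effect curves with pointwise standard errors.

    Each curve spans its covariate's training range on an even grid and is
    centered by subtracting the mean smooth contribution over the training
    rows, matching the identifiability convention of centered smooths; the
    other terms contribute nothing (they are likewise centered).
    """
    smoother = model.smoother()
    slices = model._coef_slices(smoother)
    curves = []
    for i, t in enumerate(TERM_NAMES):
        lo, hi = model.train_x[:, i].min(), model.train_x[:, i].max()
        grid = np.linspace(lo, hi, n_grid)
        sm_i = smoother.smoothers[i]
        basis_grid = sm_i.transform(grid)
        basis_train_mean = sm_i.transform(model.train_x[:, i]).mean(axis=0)
        centered = basis_grid - basis_train_mean
        sl = slices[t]
        coef = model.params[sl]
        effect = centered @ coef
        cov = model.cov_params[sl, sl.start : sl.stop]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", centered, cov, centered), 0.0))
        curves.append(PartialEffectCurve(term=t, grid=grid, effect=effect, se=se))
    return curves


def model_diagnostics(
    model: FittedGAM, covariates: pd.DataFrame, response, seed: int = 0
) -> dict:
    """Goodness-of-fit report: basis-dimension adequacy, dispersion, residuals.

    Per term, the effective degrees of freedom are compared with the basis
    dimension and flagged when EDF > 0.9 (k − 1) — a sign the basis may be
    forcing over-smoothing.  Dispersion is the Pearson statistic over
    residual degrees of freedom (scaled by the fitted variance for the
    Gaussian family).  Randomized-quantile residuals (uniform jitter for the
    binomial family, seeded) are summarized by mean, SD and extreme count.
    """
    X = _covariate_matrix(covariates)
    y = np.asarray(response, dtype=float)
    eta = model.linear_predictor(X)
    k = model.config.k
    terms = {}
    for t in TERM_NAMES:
        edf = model.edf_per_term[t]
        terms[t] = {
            "edf": edf,
            "k": k,
            "basis_dim_flag": bool(edf > 0.9 * (k - 1)),
        }
    edf_total = model.edf_intercept + sum(model.edf_per_term.values())
    rng = np.random.default_rng(seed)
    if model.family == "binomial":
        mu = expit(eta)
        pearson = np.sum((y - mu) ** 2 / np.clip(mu * (1 - mu), 1e-12, None))
        dispersion = float(pearson / (len(y) - edf_total))
        # randomized-quantile residuals for 0/1 outcomes
        u = np.where(y > 0.5, (1 - mu) + rng.random(len(y)) * mu, rng.random(len(y)) * (1 - mu))
        rqr = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    else:
        mu = eta
        pearson = np.sum((y - mu) ** 2)
        dispersion = float(pearson / (len(y) - edf_total) / model.scale)
        rqr = (y - mu) / np.sqrt(model.scale)
    return {
        "family": model.family,
        "n": int(len(y)),
        "edf_total": float(edf_total),
        "terms": terms,
        "dispersion": dispersion,
        "rqr_mean": float(np.mean(rqr)),
        "rqr_sd": float(np.std(rqr, ddof=1)),
        "rqr_frac_beyond_3": float(np.mean(np.abs(rqr) > 3)),
    }
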