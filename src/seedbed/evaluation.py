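"""Watershed-blocked validation and accuracy metrics.

Field observations are spatially clustered, so random row-wise splits leak
information between train and test.  Following standard spatial-blocking
practice, whole watershed units are the sampling unit: a fraction of
watersheds (default 1/3) is drawn into the test set, so no site ever appears
on both sides and the realized observation fraction varies from run to run.

Metrics are the class-wise presence/absence accuracies (sensitivity and
specificity), their unweighted mean (balanced accuracy), overall accuracy,
and — for cover predictions — the squared Pearson correlation between
observed and predicted cover.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import confusion_matrix

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    """A watershed-blocked train/test partition."""

    train_watersheds: list
    test_watersheds: list
    seed: int
    test_fraction_watersheds: float
    test_fraction_observations: float

    def to_frame(self) -> pd.DataFrame:
        rows = [(w, "train") for w in self.train_watersheds] + [
            (w, "test") for w in self.test_watersheds
        ]
        return pd.DataFrame(rows, columns=["watershed_id", "partition"])


@dataclass
class MetricsReport:
    """Classification and cover-prediction accuracy on a test set."""

    n_test: int
    tp: int
    fp: int
    tn: int
    fn: int
    presence_accuracy: float
    absence_accuracy: float
    balanced_accuracy: float
    overall_accuracy: float
    r_squared: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        lines = [
            f"n test observations : {self.n_test}",
            f"confusion (TP FP TN FN): {self.tp} {self.fp} {self.tn} {self.fn}",
            f"presence accuracy (sensitivity): {self.presence_accuracy:.3f}",
            f"absence accuracy (specificity) : {self.absence_accuracy:.3f}",
            f"balanced accuracy              : {self.balanced_accuracy:.3f}",
            f"overall accuracy               : {self.overall_accuracy:.3f}",
        ]
        if self.r_squared is not None:
            lines.append(f"cover R^2 (obs vs pred)        : {self.r_squared:.3f}")
        return "\n".join(lines)


def split_by_watershed(
    observations: pd.DataFrame,
    watershed_map: dict,
    test_fraction: float = 1.0 / 3.0,
    seed: int = 0,
) -> SplitSpec:
    """Sample watersheds without replacement into a test block.

    ``round(test_fraction * n_watersheds)`` units (at least 1, at most
    n − 1) are drawn uniformly; deterministic under ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    watersheds = sorted(set(watershed_map.values()))
    n_ws = len(watersheds)
    if n_ws < 3:
        raise ValueError("need >= 3 watersheds for a blocked split")
    n_test = int(round(test_fraction * n_ws))
    n_test = min(max(n_test, 1), n_ws - 1)
    rng = np.random.default_rng(seed)
    test = sorted(rng.choice(watersheds, size=n_test, replace=False).tolist())
    train = sorted(set(watersheds) - set(test))
    obs_ws = observations["site_id"].map(watershed_map)
    frac_obs = float(obs_ws.isin(test).mean()) if len(observations) else float("nan")
    logger.info(
        "blocked split: %d/%d watersheds (%.1f%% of observations) held out",
        n_test,
        n_ws,
        100 * frac_obs,
    )
    return SplitSpec(
        train_watersheds=train,
        test_watersheds=test,
        seed=seed,
        test_fraction_watersheds=n_test / n_ws,
        test_fraction_observations=frac_obs,
    )


def classification_metrics(true_presence, predicted_labels) -> MetricsReport:
    """Sensitivity, specificity, balanced and overall accuracy from labels.

    If one class is absent from ``true_presence``, its class-wise rate and
    the balanced accuracy are reported as NaN (undefined).
    """
    y = np.asarray(true_presence, dtype=bool)
    yhat = np.asarray(predicted_labels, dtype=bool)
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError("label vectors must be nonempty and of equal length")
    tn, fp, fn, tp = confusion_matrix(y, yhat, labels=[False, True]).ravel()
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    balanced = (sens + spec) / 2.0
    overall = (tp + tn) / len(y)
    return MetricsReport(
        n_test=len(y),
        tp=int(tp),
        fp=int(fp),
        tn=int(tn),
        fn=int(fn),
        presence_accuracy=float(sens),
        absence_accuracy=float(spec),
        balanced_accuracy=float(balanced),
        overall_accuracy=float(overall),
    )


def r_squared(observed_cover, predicted_cover, method: str = "pearson") -> float:
    """Observed-vs-predicted cover R².

    Default is the squared Pearson correlation (sign-blind: a perfectly
    anti-correlated prediction also scores 1, which is logged);
    ``method="ss"`` gives the 1 − SSE/SST variant instead.
    """
    obs = np.asarray(observed_cover, dtype=float)
    pred = np.asarray(predicted_cover, dtype=float)
    if len(obs) < 3 or len(obs) != len(pred):
        raise ValueError("need >= 3 observed/predicted pairs of equal length")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("constant observed or predicted cover: R^2 undefined")
    if method == "ss":
        sse = np.sum((obs - pred) ** 2)
        sst = np.sum((obs - obs.mean()) ** 2)
        return float(1.0 - sse / sst)
    r = pearsonr(obs, pred).statistic
    if r < 0:
        logger.info("observed and predicted cover are negatively correlated (r=%.3f)", r)
    return float(r * r)


def write_metrics(report: MetricsReport, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(report.to_text() + "\n")
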