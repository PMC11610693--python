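"""Additive model fitting, prediction, partial effects, and diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import spearmanr
from statsmodels.gam.api import GLMGam

import seedbed as sb
from seedbed.covariates import TERM_NAMES
from seedbed.sdm import GamConfig, _make_smoother

from conftest import normal_covariates


def central_mask(values, grid):
    lo, hi = np.quantile(values, [0.05, 0.95])
    return (grid >= lo) & (grid <= hi)


class TestFitPresence:
    def test_refit_is_deterministic(self):
        cov = normal_covariates(300, seed=50)
        obs = sb.simulate_observations(cov, sb.SynthTruth(), seed=51)
        m1 = sb.fit_presence(cov, obs["presence"])
        m2 = sb.fit_presence(cov, obs["presence"])
        np.testing.assert_allclose(m1.params, m2.params, atol=1e-8)

    def test_single_class_labels_rejected(self):
        cov = normal_covariates(100, seed=52)
        with pytest.raises(ValueError, match="single class"):
            sb.fit_presence(cov, np.ones(100, dtype=bool))

    def test_too_few_rows_per_class_rejected(self):
        cov = normal_covariates(100, seed=53)
        labels = np.zeros(100, dtype=bool)
        labels[:5] = True
        with pytest.raises(ValueError, match="20 rows per class"):
            sb.fit_presence(cov, labels)

    def test_null_truth_smooths_shrink_toward_flat(self):
        cov = normal_covariates(2000, seed=54)
        obs = sb.simulate_observations(cov, sb.SynthTruth.null(beta0=0.2), seed=55)
        model = sb.fit_presence(cov, obs["presence"])
        for term, edf in model.edf_per_term.items():
            assert edf <= 1.5, f"{term} EDF {edf} not shrunk"

    def test_recovers_generative_shapes(self, presence_fit):
        cov, truth, _, model = presence_fit
        curves = {c.term: c for c in sb.partial_effects(model)}
        # spring temporal: decreasing over the central 90% of its range
        c = curves["spring_temporal"]
        mask = central_mask(cov["spring_temporal"], c.grid)
        rho = spearmanr(c.grid[mask], c.effect[mask]).statistic
        assert rho < -0.8
        # fall spatial: concave-down with peak near the generative optimum
        c = curves["fall_spatial"]
        mask = central_mask(cov["fall_spatial"], c.grid)
        peak = c.grid[mask][np.argmax(c.effect[mask])]
        assert abs(peak - truth.fall_spatial_peak) <= 0.5


class TestFitAbundance:
    def test_pure_noise_gives_flat_smooths_around_the_mean(self):
        cov = normal_covariates(800, seed=60)
        rng = np.random.default_rng(61)
        cover = np.clip(rng.normal(15.0, 4.0, 800), 0, 100)
        model = sb.fit_abundance(cov, cover)
        for term, edf in model.edf_per_term.items():
            assert edf <= 1.5, f"{term} EDF {edf} not shrunk"
        preds = sb.predict(model, cov)["cover_pred"]
        assert preds.mean() == pytest.approx(cover.mean(), abs=0.5)
        assert preds.std() < 1.0  # essentially a constant model

    def test_recovers_concave_down_cover_response(self):
        cov = normal_covariates(1200, seed=62)
        rng = np.random.default_rng(63)
        x = cov["fall_spatial"].to_numpy()
        cover = np.clip(20.0 + 6.0 * (1.0 - (x - 0.5) ** 2) + rng.normal(0, 3, len(x)), 0, 100)
        model = sb.fit_abundance(cov, cover)
        curve = {c.term: c for c in sb.partial_effects(model)}["fall_spatial"]
        mask = central_mask(x, curve.grid)
        peak = curve.grid[mask][np.argmax(curve.effect[mask])]
        assert abs(peak - 0.5) <= 0.5

    def test_too_few_rows_rejected(self):
        cov = normal_covariates(30, seed=64)
        with pytest.raises(ValueError, match=">= 50 rows"):
            sb.fit_abundance(cov, np.full(30, 10.0))


class TestPredict:
    def test_probabilities_bounded_and_threshold_strict(self, presence_fit):
        cov, _, _, model = presence_fit
        preds = sb.predict(model, cov)
        assert preds["probability"].between(0, 1).all()
        p0 = preds["probability"].iloc[0]
        at_tie = sb.predict(model, cov.iloc[[0]], threshold=p0)
        assert not at_tie["label"].iloc[0]  # probability == threshold -> negative

    def test_matches_direct_statsmodels_fit_on_training_data(self, presence_fit):
        cov, _, obs, model = presence_fit
        X = cov[list(TERM_NAMES)].to_numpy(dtype=float)
        smoother = _make_smoother(X, model.config)
        res = GLMGam(
            obs["presence"].to_numpy(dtype=float),
            exog=np.ones((len(X), 1)),
            smoother=smoother,
            alpha=list(model.alpha),
            family=sm.families.Binomial(),
        ).fit()
        preds = sb.predict(model, cov)
        np.testing.assert_allclose(
            preds["probability"].to_numpy(), res.fittedvalues, atol=1e-6
        )

    def test_extrapolation_flagged_and_clipped(self, presence_fit):
        cov, _, _, model = presence_fit
        row = cov.iloc[[0]].copy()
        row["fall_spatial"] = model.train_x[:, 0].max() + 5.0
        pred = sb.predict(model, row)
        assert pred["extrapolated"].iloc[0]
        edge = cov.iloc[[0]].copy()
        edge["fall_spatial"] = model.train_x[:, 0].max()
        np.testing.assert_allclose(
            pred["probability"], sb.predict(model, edge)["probability"], atol=1e-12
        )

    def test_missing_term_rejected(self, presence_fit):
        cov, _, _, model = presence_fit
        with pytest.raises(KeyError, match="spring_spatial"):
            sb.predict(model, cov.drop(columns=["spring_spatial"]))

    def test_abundance_predictions_clamped(self):
        cov = normal_covariates(300, seed=66)
        rng = np.random.default_rng(67)
        cover = np.clip(rng.normal(10, 5, 300), 0, 100)
        model = sb.fit_abundance(cov, cover)
        preds = sb.predict(model, cov)
        assert preds["cover_pred_clamped"].between(0, 100).all()


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, presence_fit, tmp_path):
        cov, _, _, model = presence_fit
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = sb.FittedGAM.from_json(path)
        np.testing.assert_allclose(loaded.params, model.params, atol=0)
        np.testing.assert_allclose(
            sb.predict(loaded, cov)["probability"],
            sb.predict(model, cov)["probability"],
            atol=1e-8,
        )

    def test_version_mismatch_rejected(self, presence_fit, tmp_path):
        import json

        _, _, _, model = presence_fit
        path = tmp_path / "model.json"
        model.to_json(path)
        payload = json.loads(path.read_text())
        payload["version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            sb.FittedGAM.from_json(path)


class TestPartialEffects:
    def test_grids_span_training_ranges(self, presence_fit):
        cov, _, _, model = presence_fit
        for curve in sb.partial_effects(model, n_grid=50):
            x = cov[curve.term]
            assert curve.grid[0] == pytest.approx(x.min())
            assert curve.grid[-1] == pytest.approx(x.max())
            assert (np.diff(curve.grid) > 0).all()
            assert np.all(np.isfinite(curve.se))

    def test_flat_model_curves_are_near_zero(self):
        cov = normal_covariates(800, seed=70)
        rng = np.random.default_rng(71)
        cover = np.clip(rng.normal(15.0, 4.0, 800), 0, 100)
        model = sb.fit_abundance(cov, cover)
        for curve in sb.partial_effects(model):
            assert np.max(np.abs(curve.effect)) < 1.0


class TestDiagnostics:
    def test_report_fields_complete_for_both_families(self, presence_fit):
        cov, _, obs, model = presence_fit
        report = sb.model_diagnostics(model, cov, obs["presence"].astype(float))
        assert set(report["terms"]) == set(TERM_NAMES)
        for key in ("dispersion", "rqr_mean", "rqr_sd", "edf_total"):
            assert key in report

    def test_small_basis_on_wiggly_truth_raises_flag(self):
        cov = normal_covariates(900, seed=72)
        rng = np.random.default_rng(73)
        x = cov["fall_spatial"].to_numpy()
        cover = np.clip(20 + 6 * np.sin(1.5 * x) + rng.normal(0, 0.5, len(x)), 0, 100)
        model = sb.fit_abundance(cov, cover, GamConfig(k=4))
        report = sb.model_diagnostics(model, cov, cover)
        assert report["terms"]["fall_spatial"]["basis_dim_flag"]

    def test_well_specified_gaussian_dispersion_near_one(self):
        cov = normal_covariates(1000, seed=74)
        rng = np.random.default_rng(75)
        cover = np.clip(30 + 3 * cov["spring_spatial"] + rng.normal(0, 4, 1000), 0, 100)
        model = sb.fit_abundance(cov, cover)
        report = sb.model_diagnostics(model, cov, cover)
        assert 0.8 <= report["dispersion"] <= 1.2
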