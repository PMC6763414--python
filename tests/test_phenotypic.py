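"""Spatial stage-one fits, AIC selection, heritability, stage two."""

import numpy as np
import pandas as pd
import pytest

from wheatgs import (
    across_trial_analysis, fit_spatial_models, filter_trials,
    preprocess_softening, select_model_aic, trial_heritability,
)
from wheatgs.phenotypic import SpatialModelSpec, TrialFit, all_spatial_specs
from wheatgs.synthetic import _ar1_field


def _toy_trial(n_rows, n_cols, n_lines, seed, rho_row=0.0, spatial_sd=0.0,
               error_sd=0.5, reps_balanced=False, checks=0):
    """Grid trial with known genetic values; returns (plots, gv)."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i:03d}" for i in range(n_lines)]
    n_plots = n_rows * n_cols
    if reps_balanced:
        assert n_plots % n_lines == 0
        plot_lines = lines * (n_plots // n_lines)
    else:
        plot_lines = (lines * (n_plots // n_lines + 1))[:n_plots]
    plot_lines = list(rng.permutation(plot_lines))
    gv = dict(zip(lines, rng.normal(0.0, 1.0, n_lines)))
    field = spatial_sd * _ar1_field(n_rows, n_cols, rho_row, 0.0, rng)
    recs = []
    for i, line in enumerate(plot_lines):
        r, c = divmod(i, n_cols)
        recs.append({
            "line": line, "trial": "T1", "year": 2015, "row": r + 1,
            "col": c + 1, "is_check": line in lines[:checks],
            "Y": gv[line] + field[r, c] + rng.normal(0.0, error_sd)})
    return pd.DataFrame(recs), gv


class TestSofteningPreprocess:
    def test_inversion_and_idempotency_guard(self, small_plots):
        out = preprocess_softening(small_plots)
        mask = small_plots["SOFT"].notna()
        np.testing.assert_allclose(out.loc[mask, "SOFT"],
                                   -small_plots.loc[mask, "SOFT"])
        assert out["SOFT"].isna().equals(small_plots["SOFT"].isna())
        assert (out["GY"].dropna() == small_plots["GY"].dropna()).all()
        with pytest.raises(ValueError, match="twice"):
            preprocess_softening(out)


class TestSpatialFits:
    def test_sixteen_distinct_specs_baseline_first(self):
        specs = all_spatial_specs()
        assert len(specs) == len(set(specs)) == 16
        assert specs[0] == SpatialModelSpec(False, False, "IID")

    def test_blues_and_aic_invariant_to_plot_order(self):
        plots, _ = _toy_trial(6, 8, 16, seed=1)
        shuffled = plots.sample(frac=1.0, random_state=2).reset_index(drop=True)
        spec = [SpatialModelSpec(False, False, "AR1_ROW")]
        f1 = fit_spatial_models(plots, "Y", specs=spec)[0]
        f2 = fit_spatial_models(shuffled, "Y", specs=spec)[0]
        assert f1.aic == pytest.approx(f2.aic, abs=1e-5)
        pd.testing.assert_series_equal(f1.blues, f2.blues, atol=1e-6)

    def test_noise_free_blues_recover_genetic_values(self):
        plots, gv = _toy_trial(6, 8, 16, seed=3, error_sd=0.0)
        fit = fit_spatial_models(plots, "Y",
                                 specs=[SpatialModelSpec(False, False, "IID")])[0]
        truth = pd.Series(gv)[fit.blues.index]
        shift = (fit.blues - truth).std()
        assert shift == pytest.approx(0.0, abs=1e-6)

    def test_single_row_trial_pins_row_correlation(self):
        plots, _ = _toy_trial(1, 24, 8, seed=4)
        fit = fit_spatial_models(
            plots, "Y", specs=[SpatialModelSpec(False, False, "AR1_ROW")])[0]
        assert fit.variance_components["rho_row"] == 0.0

    def test_ar1_row_signal_beats_baseline_aic(self):
        plots, _ = _toy_trial(10, 20, 50, seed=5, rho_row=0.8,
                              spatial_sd=1.0, error_sd=0.4)
        fits = fit_spatial_models(plots, "Y")
        best = select_model_aic(fits)
        assert best.spec.residual in ("AR1_ROW", "AR1_BOTH")


class TestModelSelection:
    def _fit(self, aic, nvp, label="x"):
        return TrialFit("T", "Y", SpatialModelSpec(False, False, "IID"),
                        reml_loglik=0.0, aic=aic, n_var_params=nvp,
                        variance_components={}, blues=pd.Series(dtype=float),
                        mvd=np.nan)

    def test_argmin_tiebreak_and_identity(self):
        fits = [self._fit(100, 1), self._fit(98, 3), self._fit(99, 2)]
        assert select_model_aic(fits) is fits[1]
        tie = [self._fit(98, 1), self._fit(98, 5)]
        assert select_model_aic(tie) is tie[0]  # parsimony, baseline first
        assert select_model_aic([fits[0]]) is fits[0]
        with pytest.raises(ValueError):
            select_model_aic([])


class TestHeritability:
    def test_closed_form_from_stored_components(self):
        f = TrialFit("T", "Y", SpatialModelSpec(False, False, "IID"),
                     0.0, 0.0, 1, {"genotype": 1.0}, pd.Series(dtype=float),
                     mvd=2.0)
        assert f.h2_from_components() == pytest.approx(0.5)
        f.variance_components["genotype"] = 0.0
        assert f.h2_from_components() == 0.0

    def test_balanced_design_matches_classic_formula(self):
        # r replicates, iid error: MVD = 2 s2e / r exactly
        r = 3
        plots, _ = _toy_trial(6, 8, 16, seed=7, error_sd=0.7,
                              reps_balanced=True)
        fit = fit_spatial_models(
            plots, "Y", specs=[SpatialModelSpec(False, False, "IID")])[0]
        s2e = fit.variance_components["residual"]
        assert fit.mvd == pytest.approx(2.0 * s2e / r, rel=1e-5)
        h2 = trial_heritability(fit, "all_lines")
        s2g = fit.variance_components["genotype"]
        assert h2 == pytest.approx(s2g / (s2g + s2e / r), rel=1e-6)

    def test_unreplicated_trial_is_unassessable(self):
        plots, _ = _toy_trial(4, 4, 16, seed=8)
        fit = fit_spatial_models(
            plots, "Y", specs=[SpatialModelSpec(False, False, "IID")])[0]
        assert trial_heritability(fit, "all_lines") is None
        assert fit.unassessable

    def test_checks_only_error_source(self):
        plots, _ = _toy_trial(6, 8, 40, seed=9, error_sd=0.5, checks=3)
        fit = fit_spatial_models(
            plots, "Y", specs=[SpatialModelSpec(False, False, "IID")])[0]
        h2 = trial_heritability(fit, "checks_only")
        assert h2 is not None and 0.0 <= h2 <= 1.0
        assert "residual_checks" in fit.variance_components


class TestTrialFilter:
    def _fit_with_h2(self, trial, h2, unassessable=False):
        f = TrialFit(trial, "Y", SpatialModelSpec(False, False, "IID"),
                     0.0, 0.0, 1, {}, pd.Series(dtype=float), np.nan,
                     h2=h2, unassessable=unassessable)
        return f

    def test_thresholds_are_strict_and_class_specific(self):
        fits = [self._fit_with_h2("A", 0.30), self._fit_with_h2("B", 0.31),
                self._fit_with_h2("C", 0.05), self._fit_with_h2("D", 0.10),
                self._fit_with_h2("E", None, unassessable=True)]
        assert filter_trials(fits, "agronomic") == ["B"]
        assert filter_trials(fits, "rheology") == ["A", "B", "D", "E"]
        with pytest.raises(ValueError):
            filter_trials(fits, "quality")


class TestAcrossTrial:
    def test_single_trial_passthrough_up_to_shift(self):
        rng = np.random.default_rng(10)
        blues = pd.DataFrame({
            "line": [f"L{i}" for i in range(10)], "trial": "T1",
            "blue": rng.normal(size=10)})
        res = across_trial_analysis(blues, "Y")
        diff = res.blues - blues.set_index("line")["blue"]
        assert diff.std() == pytest.approx(0.0, abs=1e-10)

    def test_balanced_two_trial_matches_anova_oracle(self):
        rng = np.random.default_rng(11)
        lines = [f"L{i}" for i in range(6)]
        g = dict(zip(lines, rng.normal(size=6)))
        t_eff = {"T1": 1.0, "T2": -1.0}
        rows = [{"line": l, "trial": t, "blue": g[l] + t_eff[t]}
                for l in lines for t in t_eff]
        res = across_trial_analysis(pd.DataFrame(rows), "Y")
        means = pd.Series({l: np.mean([g[l] + v for v in t_eff.values()])
                           for l in lines})
        # sum-to-zero trial coding: BLUE_i = line mean - mean trial effect
        np.testing.assert_allclose(res.blues[lines], means[lines], atol=1e-8)

    def test_unbalanced_matches_direct_ls_oracle(self):
        df = pd.DataFrame({
            "line": ["A", "B", "C", "A", "B", "D", "E"],
            "trial": ["T1", "T1", "T1", "T2", "T2", "T2", "T2"],
            "blue": [3.0, 1.0, 2.0, 4.0, 2.5, 0.5, 1.5]})
        res = across_trial_analysis(df, "Y")
        lines = sorted(df["line"].unique())
        X = np.zeros((len(df), len(lines) + 1))
        for i, (_, r) in enumerate(df.iterrows()):
            X[i, lines.index(r["line"])] = 1.0
            X[i, -1] = 1.0 if r["trial"] == "T1" else -1.0
        beta = np.linalg.lstsq(X, df["blue"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.blues[lines], beta[:len(lines)],
                                   atol=1e-8)

    def test_disconnected_trials_raise(self):
        df = pd.DataFrame({
            "line": ["A", "B", "C", "D"],
            "trial": ["T1", "T1", "T2", "T2"],
            "blue": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="disconnected"):
            across_trial_analysis(df, "Y")
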