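"""Beta mixed model, LRT ladder and marginal trends."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from dyadsync.coherence import CoherenceTable
from dyadsync.behavior import DyadScores
from dyadsync.montage_io import ValidationError, build_default_montage
from dyadsync.stats import (
    FormulaSpec,
    build_model_frame,
    compress_boundary,
    fit_beta_mixed,
    lrt,
    model_ladder,
    pairing_comparison,
    pairing_frame,
    simulate_beta_mixed,
    trend_contrast,
)
from dyadsync.surrogates import SurrogateSet


def fake_tables_and_scores(rng, n_dyads=5, n_epochs=8):
    montage = build_default_montage()
    tables, scores = [], []
    for d in range(n_dyads):
        vals = rng.uniform(0.15, 0.6, size=(16, n_epochs))
        tables.append(CoherenceTable(
            dyad_id=f"d{d:02d}", chromophore="HbO", values=vals,
            montage=montage, channel_mask=np.ones(16, bool)))
        scores.append(DyadScores(
            dyad_id=f"d{d:02d}", turn_taking=rng.uniform(20, 90),
            relevance=rng.uniform(0, 30), contingency=rng.uniform(0, 20),
            intrusiveness=rng.uniform(0, 10),
            mean_turn_duration_ms=rng.uniform(800, 2500),
            total_overlap_ms=rng.uniform(0, 5000)))
    return tables, scores


class TestModelFrame:
    def test_boundary_compression_formula(self):
        y = np.array([1.0] + [0.5] * 99)
        out = compress_boundary(y)
        assert out[0] == pytest.approx(0.995)
        assert np.all(out[1:] == 0.5)
        assert compress_boundary(np.array([0.0, 0.5]), n=100)[0] \
            == pytest.approx(0.005)

    def test_standardized_predictors(self, rng):
        tables, scores = fake_tables_and_scores(rng)
        frame = build_model_frame(tables, scores)
        for col in ("turn_taking_z", "time_z", "turn_duration_z"):
            assert abs(frame[col].mean()) < 1e-10
            assert abs(frame[col].std(ddof=0) - 1) < 1e-10

    def test_row_count_is_product(self, rng):
        tables, scores = fake_tables_and_scores(rng, n_dyads=5)
        frame = build_model_frame(tables, scores)
        assert len(frame) == 5 * 16 * 8

    def test_missing_rows_dropped_and_counted(self, rng):
        tables, scores = fake_tables_and_scores(rng, n_dyads=3)
        tables[0].values[2, :] = np.nan
        frame = build_model_frame(tables, scores)
        assert len(frame) == 3 * 16 * 8 - 8
        assert frame.attrs["n_dropped_missing"] == 8

    def test_response_strictly_inside_unit_interval(self, rng):
        tables, scores = fake_tables_and_scores(rng, n_dyads=2)
        tables[0].values[0, 0] = 1.0
        frame = build_model_frame(tables, scores)
        assert frame["wtc"].max() < 1.0 and frame["wtc"].min() > 0.0

    def test_empty_join_rejected(self, rng):
        tables, _ = fake_tables_and_scores(rng, n_dyads=2)
        with pytest.raises(ValidationError):
            build_model_frame(tables, [])

    def test_roi_filter(self, rng):
        tables, scores = fake_tables_and_scores(rng, n_dyads=2)
        frame = build_model_frame(tables, scores, roi="TPJ-L")
        assert set(frame["roi"]) == {"TPJ-L"}
        assert len(frame) == 2 * 4 * 8


class TestBetaMixedFit:
    def test_constant_half_response_gives_zero_intercept(self):
        frame = pd.DataFrame({"dyad_id": np.repeat([f"g{i}" for i in range(8)],
                                                   10),
                              "wtc": np.full(80, 0.5),
                              "epoch": np.tile(np.arange(1, 11), 8)})
        fit = fit_beta_mixed(frame, FormulaSpec(), compute_se=False)
        assert abs(fit.beta[0]) < 1e-4

    def test_zero_variance_matches_plain_beta_mle(self):
        """With no group variance the fit must agree with an independent
        fixed-effects beta-regression MLE (statsmodels)."""
        from statsmodels.othermod.betareg import BetaModel

        frame = simulate_beta_mixed(20, 50,
                                    beta={"intercept": 0.3, "x_z": 0.4},
                                    sigma={"intercept": 1e-8}, phi=25, seed=2)
        fit = fit_beta_mixed(frame, FormulaSpec(fixed=("x_z",),
                                                random=("x_z",)),
                             method="laplace", compute_se=False)
        X = np.column_stack([np.ones(len(frame)), frame["x_z"]])
        oracle = BetaModel(frame["wtc"], X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, oracle.params[:2], atol=1e-3)
        assert fit.loglik == pytest.approx(oracle.llf, abs=0.05)

    def test_laplace_agrees_with_adaptive_quadrature(self):
        frame = simulate_beta_mixed(30, 32, beta={"intercept": 0.4},
                                    sigma={"intercept": 0.3}, phi=30, seed=5)
        lap = fit_beta_mixed(frame, FormulaSpec(), method="laplace",
                             compute_se=False)
        agq = fit_beta_mixed(frame, FormulaSpec(), method="agq",
                             compute_se=False)
        assert lap.beta[0] == pytest.approx(agq.beta[0], abs=1e-2)
        assert lap.phi == pytest.approx(agq.phi, rel=1e-2)
        assert lap.sigma["intercept"] == pytest.approx(agq.sigma["intercept"],
                                                       abs=1e-2)

    def test_single_seed_parameter_recovery(self):
        frame = simulate_beta_mixed(40, 128, beta={"intercept": 0.5},
                                    sigma={"intercept": 0.3}, phi=30, seed=1)
        fit = fit_beta_mixed(frame, FormulaSpec(), method="agq")
        assert abs(fit.beta[0] - 0.5) < 3 * fit.se[0]
        assert fit.phi == pytest.approx(30, rel=0.15)
        assert fit.sigma["intercept"] == pytest.approx(0.3, abs=0.1)

    def test_response_outside_interval_rejected(self):
        frame = pd.DataFrame({"dyad_id": ["a", "a", "b", "b"],
                              "wtc": [0.2, 1.0, 0.4, 0.5],
                              "epoch": [1, 2, 1, 2]})
        with pytest.raises(ValidationError, match="inside"):
            fit_beta_mixed(frame, FormulaSpec(), compute_se=False)

    def test_rank_deficiency_named(self):
        frame = simulate_beta_mixed(10, 8, beta={"intercept": 0.3, "x_z": 0.1},
                                    sigma={"intercept": 0.2}, phi=20, seed=0)
        frame["x2_z"] = frame["x_z"]
        with pytest.raises(ValidationError, match="rank-deficient"):
            fit_beta_mixed(frame, FormulaSpec(fixed=("x_z", "x2_z")),
                           compute_se=False)


class TestLRT:
    def test_identical_models_give_null_result(self):
        frame = simulate_beta_mixed(10, 16, seed=3)
        fit = fit_beta_mixed(frame, FormulaSpec(), compute_se=False)
        fit2 = fit_beta_mixed(frame, FormulaSpec(fixed=("time_z",)),
                              compute_se=False)
        chi2, df, p = lrt(fit, fit2)
        assert df == 1 and chi2 >= 0
        with pytest.raises(ValidationError):
            lrt(fit, fit)  # no added parameters

    def test_chi_square_tail_arithmetic(self):
        # chi2 = 19.54 on 2 df is far in the tail
        assert chi2_dist.sf(19.54, 2) < 0.001

    def test_different_data_rejected(self):
        f1 = simulate_beta_mixed(6, 8, seed=0)
        f2 = simulate_beta_mixed(6, 10, seed=0)
        a = fit_beta_mixed(f1, FormulaSpec(), compute_se=False)
        b = fit_beta_mixed(f2, FormulaSpec(fixed=("time_z",)),
                           compute_se=False)
        with pytest.raises(ValidationError):
            lrt(a, b)


@pytest.fixture(scope="module")
def interaction_frame():
    return simulate_beta_mixed(
        20, 32,
        beta={"intercept": 0.5, "turn_taking_z": 0.05, "time_z": 0.03,
              "turn_taking_z:time_z": 0.08},
        sigma={"intercept": 0.2, "turn_taking_z": 0.02, "time_z": 0.02,
               "turn_taking_z:time_z": 0.02},
        phi=30, seed=42)


@pytest.fixture(scope="module")
def ladder_with_all_predictors(interaction_frame):
    frame = interaction_frame.copy()
    rng = np.random.default_rng(0)
    for col in ("turn_duration_z", "relevance_z", "intrusiveness_z",
                "contingency_z"):
        per_dyad = {d: rng.standard_normal()
                    for d in frame["dyad_id"].unique()}
        frame[col] = frame["dyad_id"].map(per_dyad)
    frame["epoch"] = np.tile(np.arange(1, 9), len(frame) // 8)
    return model_ladder(frame, upto="M7", method="laplace")


class TestModelLadder:
    def test_interaction_detected_and_loglik_monotone(
            self, ladder_with_all_predictors):
        ladder = ladder_with_all_predictors
        comp = ladder.comparisons.set_index("comparison")
        assert comp.loc["M3 vs M2", "p"] < 0.05
        # nested fits never lose likelihood
        for name, base in (("M1", "M0"), ("M2", "M1"), ("M3", "M2"),
                           ("M4", "M3"), ("M5", "M3"), ("M6", "M3"),
                           ("M7", "M3")):
            assert ladder.fits[name].loglik >= ladder.fits[base].loglik - 1e-6
        assert list(ladder.comparisons["df"]) == [2] * 7

    def test_missing_column_named(self, interaction_frame):
        frame = interaction_frame.copy()
        with pytest.raises(KeyError, match="turn_duration_z"):
            model_ladder(frame, upto="M7")
        rng = np.random.default_rng(0)
        for col in ("turn_duration_z", "relevance_z", "intrusiveness_z"):
            frame[col] = rng.standard_normal(len(frame))
        with pytest.raises(KeyError, match="contingency_z"):
            model_ladder(frame, upto="M7")

    def test_fitted_means_inside_unit_interval(
            self, ladder_with_all_predictors):
        from scipy.special import expit

        fit = ladder_with_all_predictors.fits["M3"]
        assert 0 < expit(fit.beta[0]) < 1
        assert np.all(np.isfinite(fit.beta))
        assert fit.phi > 0


class TestTrendContrast:
    def test_linear_identity_and_symmetry(self, ladder_with_all_predictors):
        fit = ladder_with_all_predictors.fits["M3"]
        trends = trend_contrast(fit)
        bf = fit.coef("turn_taking_z")
        bi = fit.coef("turn_taking_z:time_z")
        for _, row in trends.iloc[:2].iterrows():
            assert row["trend"] == pytest.approx(
                bf + bi * row["moderator_value"], abs=1e-12)
        m_early, m_late = trends["moderator_value"].iloc[:2]
        assert m_early == pytest.approx(-m_late, abs=1e-9)
        assert trends["trend"].iloc[0] + trends["trend"].iloc[1] \
            == pytest.approx(2 * bf, abs=1e-9)

    def test_positive_interaction_gives_larger_late_trend(
            self, ladder_with_all_predictors):
        trends = trend_contrast(ladder_with_all_predictors.fits["M3"])
        assert trends.set_index("level").loc["late", "trend"] \
            > trends.set_index("level").loc["early", "trend"]

    def test_median_split(self, ladder_with_all_predictors):
        trends = trend_contrast(ladder_with_all_predictors.fits["M3"],
                                split_spec="median", moderator="time_z")
        assert set(trends["level"]) == {"low", "high", "high-low"}

    def test_missing_interaction_rejected(self, interaction_frame):
        fit = fit_beta_mixed(interaction_frame,
                             FormulaSpec(fixed=("turn_taking_z",)),
                             compute_se=False)
        with pytest.raises(ValidationError, match="interaction"):
            trend_contrast(fit)


class TestPairingComparison:
    def test_zero_draw_surrogate_rejected(self, rng):
        tables, _ = fake_tables_and_scores(rng, n_dyads=2)
        surr = SurrogateSet(kind="random_pair", n_draws=0, seed=0,
                            values=np.zeros((0, 2, 16, 8)),
                            pairings=np.zeros((0, 2), int),
                            child_ids=["d00", "d01"])
        with pytest.raises(ValidationError):
            pairing_frame(tables, surr)

    def test_detects_original_excess(self, rng):
        montage = build_default_montage()
        tables = []
        n_child = 8
        surr_vals = np.empty((5, n_child, 16, 8))
        for d in range(n_child):
            tables.append(CoherenceTable(
                dyad_id=f"d{d:02d}", chromophore="HbO",
                values=np.clip(rng.normal(0.40, 0.05, (16, 8)), 0.05, 0.95),
                montage=montage, channel_mask=np.ones(16, bool)))
            surr_vals[:, d] = np.clip(rng.normal(0.30, 0.05, (5, 16, 8)),
                                      0.05, 0.95)
        surr = SurrogateSet(kind="random_pair", n_draws=5, seed=0,
                            values=surr_vals,
                            pairings=np.zeros((5, n_child), int),
                            child_ids=[f"d{d:02d}" for d in range(n_child)])
        result = pairing_comparison(tables, surr, compute_se=False)
        comp = result.comparisons.set_index("comparison")
        assert comp.loc["P1 vs P0", "p"] < 0.01
        assert result.fits["P1"].coef("pairing_random") < 0  # random < original
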