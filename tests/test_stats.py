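"""Statistics layer: kappa, bands, Spearman, proportional odds, LMM."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, rankdata
from statsmodels.miscmodels.ordinal_model import OrderedModel

from fibroscore.errors import (
    DegenerateAgreementError,
    InvalidArgumentError,
    JoinError,
    SeparationError,
    ShapeError,
)
from fibroscore.stats import (
    agreement_band,
    cohens_kappa,
    fit_proportional_odds,
    fit_slope_lmm,
    kappa_table,
    odds_ratio_table,
    spearman_corr,
)
from fibroscore.synthetic import (
    RaterProfile,
    simulate_proportional_odds_data,
    simulate_rater_scores,
)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]).kappa == 1.0

    def test_hand_computed_2x2_table(self):
        r = cohens_kappa([1, 1, 0, 0], [1, 0, 1, 0])
        assert r.p_observed == pytest.approx(0.5)
        assert r.p_expected == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.0)

    def test_exhaustive_small_tables_match_contingency_formula(self):
        # every 2x2 table with cell counts <= 6 against the closed form
        # computed directly from the table (independent arithmetic path)
        for a, b, c, d in product(range(7), repeat=4):
            n = a + b + c + d
            if n < 2:
                continue
            r1 = [0] * (a + b) + [1] * (c + d)
            r2 = [0] * a + [1] * b + [0] * c + [1] * d
            p_o = (a + d) / n
            p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
            if p_e >= 1 - 1e-15:
                with pytest.raises(DegenerateAgreementError):
                    cohens_kappa(r1, r2)
                continue
            expected = (p_o - p_e) / (1 - p_e)
            assert cohens_kappa(r1, r2).kappa == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_on_multicategory_data(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 6, 500)
        b = np.clip(a + rng.integers(-1, 2, 500), 0, 5)
        assert cohens_kappa(a, b).kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_raters_have_near_zero_kappa(self, rng):
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohens_kappa(a, b).kappa) < 0.05

    def test_length_mismatch_is_shape_error(self):
        with pytest.raises(ShapeError):
            cohens_kappa([0, 1], [0, 1, 0])

    @given(st.integers(0, 5))
    @settings(deadline=None, max_examples=6)
    def test_kappa_symmetric_in_raters(self, shift):
        rng = np.random.default_rng(shift)
        a = rng.integers(0, 3, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 0, 2 + shift % 2)
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(b, a).kappa)


class TestAgreementBands:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (-0.2, "no agreement"),
            (0.0, "no agreement"),
            (0.005, "none to slight"),
            (0.20, "none to slight"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.60, "moderate"),
            (0.70, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_band_cutpoints(self, kappa, band):
        assert agreement_band(kappa) == band

    def test_kappa_above_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            agreement_band(1.1)


class TestSpearman:
    def test_three_point_example(self):
        assert spearman_corr([1, 2, 3], [3, 1, 2]).rho == pytest.approx(-0.5)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        base = spearman_corr(x, y).rho
        assert spearman_corr(np.exp(x), y).rho == pytest.approx(base)
        assert spearman_corr(x, 2 * y + 1).rho == pytest.approx(base)

    def test_ties_match_average_rank_pearson_oracle(self, rng):
        x = rng.integers(0, 5, 40).astype(float)
        y = rng.integers(0, 5, 40).astype(float)
        rho = spearman_corr(x, y).rho
        oracle = pearsonr(rankdata(x), rankdata(y))[0]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_for_tiny_n(self):
        r = spearman_corr([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], exact=True)
        assert r.method == "exact permutation"
        assert 0 < r.p <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spearman_corr([1.0, 1.0, 1.0], [1, 2, 3])


class TestProportionalOdds:
    def test_binary_case_equals_logistic_mle(self):
        x, y = simulate_proportional_odds_data(0.7, 800, [0.3], x_sd=1.5, seed=9)
        r = fit_proportional_odds(y, x)
        logit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert abs(r.beta - logit.params[1]) < 1e-6
        assert abs(r.thresholds[0] + logit.params[0]) < 1e-6

    def test_six_category_fit_matches_statsmodels_ordered_model(self):
        x, y = simulate_proportional_odds_data(0.3, 2000, [-2, -1, 0, 1, 2], x_sd=2.0, seed=4)
        r = fit_proportional_odds(y, x)
        om = OrderedModel(y, x[:, None], distr="logit").fit(method="bfgs", disp=0)
        assert abs(r.beta - om.params[0]) < 1e-4

    def test_null_effect_gives_near_unit_or(self, rng):
        x, y = simulate_proportional_odds_data(0.6, 5000, [0.0], x_sd=1.0, seed=12)
        x = rng.permutation(x)  # break the association
        r = fit_proportional_odds(y, x)
        assert 0.93 <= r.or_ <= 1.07

    def test_planted_or_recovered_within_3_se(self):
        beta = np.log(2.01)
        x, y = simulate_proportional_odds_data(beta, 5000, [0.0], x_sd=2.0, seed=1)
        r = fit_proportional_odds(y, x)
        assert abs(r.beta - beta) < 3 * r.se

    def test_ci_brackets_point_estimate(self):
        x, y = simulate_proportional_odds_data(0.4, 1000, [-1, 1], x_sd=1.0, seed=5)
        r = fit_proportional_odds(y, x)
        assert r.ci_low <= r.or_ <= r.ci_high
        assert r.or_ > 0

    def test_separation_detected(self):
        x = np.linspace(-2, 2, 60)
        y = (x > 0).astype(int)  # perfectly separated
        with pytest.raises(SeparationError):
            fit_proportional_odds(y, x)

    def test_single_category_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_proportional_odds(np.zeros(50, int), np.arange(50.0))


def _sheets_and_predictor(n=120, seed=3):
    rng = np.random.default_rng(seed)
    sev = rng.uniform(0, 1, n)
    truth = pd.DataFrame(
        {
            "biopsy_id": [f"B{i:03d}" for i in range(n)],
            "severity": sev,
            "collagen_fraction": 0.2 + 0.5 * sev,
            "fat_vacuole_density": 28 * (1 - 0.6 * sev),
            "vessel_ectasia_count": (2 + 10 * sev).astype(int),
            "infiltrate_density": 60 + 140 * sev,
        }
    )
    sheets = simulate_rater_scores(
        truth, (RaterProfile("R1"), RaterProfile("R2")), sessions=2, seed=seed
    )
    predictor = pd.Series(15 + 25 * sev, index=truth["biopsy_id"])
    return sheets, predictor


class TestOddsRatioTable:
    def test_all_16_parameters_reported(self):
        sheets, predictor = _sheets_and_predictor()
        table = odds_ratio_table(sheets, predictor)
        assert len(table) == 16
        assert {"or", "ci_low", "ci_high", "p", "note"} <= set(table.columns)
        fitted = table[table["or"].notna()]
        assert (fitted["ci_low"] <= fitted["or"]).all()
        assert (fitted["or"] <= fitted["ci_high"]).all()
        failed = table[table["or"].isna()]
        assert (failed["note"] != "").all()  # NA rows carry a reason

    def test_predictor_shift_leaves_ors_unchanged(self):
        sheets, predictor = _sheets_and_predictor()
        t1 = odds_ratio_table(sheets, predictor)
        t2 = odds_ratio_table(sheets, predictor + 100.0)
        ok = t1["or"].notna() & t2["or"].notna()
        assert np.allclose(t1.loc[ok, "or"], t2.loc[ok, "or"], rtol=1e-6)

    def test_unjoinable_biopsy_is_join_error(self):
        sheets, predictor = _sheets_and_predictor(n=20)
        with pytest.raises(JoinError):
            odds_ratio_table(sheets, predictor.iloc[:-2])

    def test_planted_effect_signs_recovered(self):
        # score sheets generated under the proportional-odds model with
        # planted per-parameter odds ratios: the sign of (OR - 1) must be
        # recovered for every planted parameter at n = 500
        from fibroscore import schema

        planted = {
            "telangiectasia": 2.01,
            "sc_fat_loss_widened_septa": 1.47,
            "thickened_intima": 1.21,
            "eccrine_entrapment": 1.14,
            "hyalinized_collagen": 1.10,
            "cd34": 0.85,
        }
        n = 500
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 2.0, n)
        rows = {"biopsy_id": [f"B{i:03d}" for i in range(n)],
                "rater_id": "R1", "session": 1}
        for p, kind in schema.PARAMETERS.items():
            if p in planted:
                thr = [0.0] if kind == schema.BINARY else [-2, -1, 0, 1, 2]
                # sample y | x under the cumulative-logit law (the same
                # construction simulate_proportional_odds_data uses, but
                # conditioned on this test's shared predictor draw)
                from scipy.special import expit

                cum = expit(np.asarray(thr, float)[None, :] - np.log(planted[p]) * x[:, None])
                y = (rng.random(n)[:, None] > cum).sum(axis=1)
                rows[p] = y
            elif kind == schema.BINARY:
                rows[p] = rng.integers(0, 2, n)
            elif kind == schema.ORDINAL:
                rows[p] = rng.integers(0, 6, n)
            else:
                rows[p] = rng.normal(50, 10, n).clip(0)
        sheets = pd.DataFrame(rows)
        predictor = pd.Series(x, index=sheets["biopsy_id"])
        table = odds_ratio_table(sheets, predictor).set_index("parameter")
        for p, target in planted.items():
            assert np.sign(table.loc[p, "or"] - 1.0) == np.sign(target - 1.0), p


class TestKappaTable:
    def test_noiseless_raters_agree_perfectly(self):
        rng = np.random.default_rng(5)
        sev = rng.uniform(0, 1, 60)
        truth = pd.DataFrame(
            {
                "biopsy_id": [f"B{i}" for i in range(60)],
                "severity": sev,
                "collagen_fraction": 0.2 + 0.5 * sev,
                "fat_vacuole_density": 28 * (1 - 0.6 * sev),
                "vessel_ectasia_count": (2 + 10 * sev).astype(int),
                "infiltrate_density": 60 + 140 * sev,
            }
        )
        quiet = tuple(
            RaterProfile(r, flip_prob=0, ordinal_noise=(0, 1, 0), continuous_cv=0, session_drift=0)
            for r in ("R1", "R2")
        )
        table = kappa_table(simulate_rater_scores(truth, quiet, seed=1))
        for _, row in table.iterrows():
            assert row["kappa"] == pytest.approx(1.0) or "degenerate" in row["note"]


class TestSlopeLMM:
    def test_noiseless_linear_trend_recovered_exactly(self):
        weeks = np.tile([0.0, 24.0, 52.0], 5)
        pid = np.repeat(np.arange(5), 3)
        r = fit_slope_lmm(2 + 0.1 * weeks, weeks, pid)
        assert r.slope_per_week == pytest.approx(0.1, abs=1e-8)
        assert r.var_intercept < 1e-8 and r.var_slope < 1e-8 and r.var_resid < 1e-8

    def test_planted_slope_recovered_within_3_se(self):
        rng = np.random.default_rng(2)
        n = 200
        pid = np.repeat(np.arange(n), 3)
        weeks = np.tile([0.0, 24.0, 52.0], n)
        y = (
            2.0 + 0.05 * weeks
            + rng.normal(0, 1.0, n)[pid]
            + rng.normal(0, 0.02, n)[pid] * weeks
            + rng.normal(0, 0.5, 3 * n)
        )
        r = fit_slope_lmm(y, weeks, pid)
        # conservative SE bound from the random-slope spread alone
        se = 0.02 / np.sqrt(n) + 0.5 / (np.sqrt(3 * n) * np.std(weeks))
        assert abs(r.slope_per_week - 0.05) < 3 * se
        assert r.var_intercept >= 0 and r.var_slope >= 0 and r.var_resid >= 0
        assert r.p < 0.05

    def test_single_patient_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_slope_lmm([1.0, 2.0, 3.0], [0, 24, 52], ["A", "A", "A"])

    def test_constant_weeks_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_slope_lmm([1.0, 2.0, 3.0, 4.0], [5, 5, 5, 5], ["A", "A", "B", "B"])
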