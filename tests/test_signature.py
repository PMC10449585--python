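"""Stepwise-AIC signature pooling and the named Cox risk scores."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from bodyrad.coxmath import cox_loglik_from_lp
from bodyrad.phantom import simulate_feature_cohort
from bodyrad.signature import (
    BODYCOMP_SCORE,
    CLINICAL_SCORE,
    RADIOMICS_SCORE,
    FittedScore,
    SignatureCoxModel,
    combine_scores,
    compute_score,
    fit_final_score,
    pool_signatures,
    select_signature,
    stepwise_cox_aic,
)


class TestStepwiseAIC:
    def test_strong_single_candidate_retained(self):
        X, t, e = simulate_feature_cohort(300, {"sig": 1.0}, n_noise=0, seed=0)
        assert stepwise_cox_aic(X, t, e, ["sig"]) == ("sig",)

    def test_pure_noise_candidate_usually_dropped(self):
        drops = 0
        for seed in range(20):
            X, t, e = simulate_feature_cohort(300, {}, n_noise=1,
                                              seed=50 + seed)
            drops += stepwise_cox_aic(X, t, e, ["noise_000"]) == ()
        assert drops >= 16

    def test_step_decision_matches_explicit_aic_comparison(self):
        from bodyrad.coxmath import cox_newton_fit

        X, t, e = simulate_feature_cohort(100, {}, n_noise=1, seed=3)
        # AIC(null) = -2 * null log PL with k=0; AIC(full) = 2 - 2 * ll(beta)
        aic_null = -2 * cox_loglik_from_lp(np.zeros(len(t)), t, e)
        _, ll_full = cox_newton_fit(X[["noise_000"]].to_numpy(), t, e)
        aic_full = 2 - 2 * ll_full
        sel = stepwise_cox_aic(X, t, e, ["noise_000"])
        assert (sel == ()) == (aic_null < aic_full)

    def test_planted_kept_noise_dropped_together(self):
        X, t, e = simulate_feature_cohort(400, {"a": 1.0, "b": 0.9},
                                          n_noise=2, seed=7)
        sel = stepwise_cox_aic(X, t, e, list(X.columns))
        assert {"a", "b"} <= set(sel)

    def test_empty_candidates_rejected(self):
        X, t, e = simulate_feature_cohort(50, {}, n_noise=1, seed=0)
        with pytest.raises(ValueError):
            stepwise_cox_aic(X, t, e, [])


class TestSignaturePooling:
    def test_unanimous_selection(self):
        pool = pool_signatures([("f1", "f2")] * 10)
        assert pool == Counter({("f1", "f2"): 10})
        assert select_signature(pool) == ("f1", "f2")

    def test_tie_broken_by_smaller_set(self):
        pool = Counter({("a",): 300, ("b", "c"): 300})
        assert select_signature(pool) == ("a",)

    def test_tie_broken_lexicographically_at_equal_size(self):
        pool = Counter({("b",): 5, ("a",): 5})
        assert select_signature(pool) == ("a",)

    def test_sets_are_canonicalized_by_sorted_names(self):
        pool = pool_signatures([("b", "a"), ("a", "b")])
        assert pool == Counter({("a", "b"): 2})

    def test_empty_pool_gives_empty_signature(self):
        assert select_signature(Counter()) == ()


class TestShippedScores:
    def test_clinical_score_equation(self):
        row = {"age": 0.0, "asa_ge3": 0.0, "sex_male": 0.0}
        assert compute_score(CLINICAL_SCORE, row).iloc[0] == 0.0
        row["sex_male"] = 1.0
        assert compute_score(CLINICAL_SCORE, row).iloc[0] == \
            pytest.approx(0.2803)
        lp = compute_score(CLINICAL_SCORE,
                           {"age": 70.0, "asa_ge3": 1.0, "sex_male": 1.0})
        assert lp.iloc[0] == pytest.approx(0.01353 * 70 + 0.4087 + 0.2803)

    def test_bodycomp_score_equation(self):
        assert compute_score(BODYCOMP_SCORE, {"vati": 2.5}).iloc[0] == \
            pytest.approx(0.1988 * 2.5)

    def test_radiomics_score_equation_with_printed_aliases(self):
        row = {"SATI_original_shape2D_Perimeter": 1.0,
               "VATI_original_glszm_SmallAreaEmphasis": 2.0,
               "VATI_original_firstorder_Maximum": 3.0}
        lp = compute_score(RADIOMICS_SCORE, row).iloc[0]
        assert lp == pytest.approx(0.3100 * 1 - 0.2302 * 2 + 0.1353 * 3)

    def test_score_linearity_in_each_feature(self):
        base = {"vati": 1.0}
        doubled = {"vati": 2.0}
        d = (compute_score(BODYCOMP_SCORE, doubled)
             - compute_score(BODYCOMP_SCORE, base)).iloc[0]
        assert d == pytest.approx(0.1988)

    def test_missing_feature_gives_nan(self):
        lp = compute_score(BODYCOMP_SCORE, {"smi": 1.0})
        assert np.isnan(lp.iloc[0])

    def test_coefficient_feature_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            FittedScore(name="x", features=("a", "b"), coefficients=(1.0,))


class TestFinalFit:
    def test_recovers_planted_coefficients(self):
        X, t, e = simulate_feature_cohort(500, {"a": 0.8, "b": -0.5},
                                          n_noise=0, seed=11)
        score = fit_final_score(X, t, e, ["a", "b"], "demo")
        assert score.coefficients[0] == pytest.approx(0.8, abs=0.2)
        assert score.coefficients[1] == pytest.approx(-0.5, abs=0.2)

    def test_collinear_design_rejected_with_names(self):
        X, t, e = simulate_feature_cohort(100, {"a": 0.5}, n_noise=0, seed=2)
        X["a_copy"] = X["a"]
        with pytest.raises(ValueError, match="a_copy"):
            fit_final_score(X, t, e, ["a", "a_copy"], "bad")

    def test_empty_feature_set_yields_empty_score(self):
        X, t, e = simulate_feature_cohort(50, {}, n_noise=1, seed=0)
        score = fit_final_score(X, t, e, [], "empty")
        assert score.features == ()


class TestCombinedScores:
    def test_combining_score_with_itself_is_singular(self):
        X, t, e = simulate_feature_cohort(100, {"a": 0.8}, n_noise=0, seed=4)
        lp = X[["a"]].rename(columns={"a": "s1"})
        lp["s2"] = lp["s1"]
        with pytest.raises(ValueError, match="collinear"):
            combine_scores(lp, t, e, "dup")

    def test_combined_training_fit_never_loses_loglik(self):
        from bodyrad.evaluate import concordance

        X, t, e = simulate_feature_cohort(400, {"a": 0.8, "b": 0.6},
                                          n_noise=0, seed=8)
        s_a = fit_final_score(X, t, e, ["a"], "A")
        s_b = fit_final_score(X, t, e, ["b"], "B")
        lp = pd.DataFrame({"A": compute_score(s_a, X),
                           "B": compute_score(s_b, X)})
        comb = combine_scores(lp, t, e, "AB")
        c_comb, _ = concordance(compute_score(comb, lp), t, e)
        c_parts = max(concordance(lp["A"], t, e)[0],
                      concordance(lp["B"], t, e)[0])
        assert c_comb >= c_parts - 0.01  # in-sample nesting, small slack

    def test_combined_tracks_informative_component(self):
        diffs = []
        for seed in range(8):
            X, t, e = simulate_feature_cohort(400, {"r": 1.0}, n_noise=2,
                                              seed=20 + seed)
            from bodyrad.evaluate import concordance

            s_r = fit_final_score(X, t, e, ["r"], "R")
            s_c = fit_final_score(X, t, e, ["noise_000"], "C")
            lp = pd.DataFrame({"R": compute_score(s_r, X),
                               "C": compute_score(s_c, X)})
            comb = combine_scores(lp, t, e, "CR")
            c_comb, _ = concordance(compute_score(comb, lp), t, e)
            c_r, _ = concordance(lp["R"], t, e)
            diffs.append(c_comb - c_r)
        assert abs(np.mean(diffs)) < 0.03


class TestSignatureCoxModel:
    def test_planted_signature_is_modal(self):
        X, t, e = simulate_feature_cohort(300, {"a": 1.0, "b": 0.9},
                                          n_noise=3, seed=13)
        model = SignatureCoxModel(candidates=["a", "b", "noise_000",
                                              "noise_001", "noise_002"],
                                  B=30, random_state=3).fit(X, (t, e))
        assert set(model.signature_) >= {"a", "b"}
        lp = model.predict(X)
        assert lp.std() > 0

    def test_empty_candidates_reports_status(self):
        X, t, e = simulate_feature_cohort(60, {}, n_noise=2, seed=1)
        model = SignatureCoxModel(candidates=[], B=5).fit(X, (t, e))
        assert model.status_ == "empty-signature"
        assert (model.predict(X) == 0).all()

    def test_subsample75_mode_runs(self):
        X, t, e = simulate_feature_cohort(120, {"a": 1.2}, n_noise=2, seed=2)
        model = SignatureCoxModel(candidates=["a", "noise_000"], B=10,
                                  resample_mode="subsample75",
                                  random_state=0).fit(X, (t, e))
        assert "a" in model.signature_

    def test_pooling_deterministic_under_shared_plan(self):
        from bodyrad.selection import make_bootstrap_plan

        X, t, e = simulate_feature_cohort(100, {"a": 1.0}, n_noise=2, seed=3)
        plan = make_bootstrap_plan(100, 12, seed=5)
        m1 = SignatureCoxModel(candidates=list(X.columns), plan=plan,
                               B=12).fit(X, (t, e))
        m2 = SignatureCoxModel(candidates=list(X.columns), plan=plan,
                               B=12).fit(X, (t, e))
        assert m1.signature_pool_ == m2.signature_pool_
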