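import itertools
import math

import numpy as np
import pandas as pd
import pytest

from peergaze.inference import (akaike_weights, build_model_table,
                                code_predictors, design_matrix,
                                enumerate_candidates, global_terms,
                                model_average, model_factors, run_analysis,
                                term_name)
from peergaze.lmm import LMMFit, fit_crossed_lmm
from peergaze.simulate import generate_design


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def brute_force_candidates(factors):
    """Filter the full power set of terms by the marginality constraint."""
    terms = global_terms(factors)
    keep = []
    for r in range(len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            ok = all(
                all(sub in subset
                    for k in range(1, len(t))
                    for sub in itertools.combinations(t, k))
                for t in subset)
            if ok:
                keep.append(frozenset(subset))
    return set(keep)


class TestEnumeration:
    def test_two_factor_global_model(self):
        cands = enumerate_candidates(("perspective", "valence"))
        as_sets = [set(term_name(t) for t in c) for c in cands]
        assert len(cands) == 5
        assert {"perspective", "valence", "perspective:valence"} in as_sets
        assert set() in as_sets

    @pytest.mark.parametrize("factors", [
        ("perspective", "valence"),
        ("perspective", "valence", "fixation")])
    def test_matches_power_set_filter(self, factors):
        got = {frozenset(c) for c in enumerate_candidates(factors)}
        assert got == brute_force_candidates(factors)

    def test_marginality_for_three_way_terms(self):
        for cand in enumerate_candidates(model_factors("anxiety")):
            members = set(cand)
            for t in cand:
                if len(t) == 3:
                    for pair in itertools.combinations(t, 2):
                        assert pair in members

    def test_four_factor_count_and_determinism(self):
        a = enumerate_candidates(model_factors("anxiety"))
        b = enumerate_candidates(model_factors("anxiety"))
        assert a == b
        assert len(a) == len(brute_force_candidates(model_factors("anxiety")))


# ---------------------------------------------------------------------------
# Akaike weights and averaging
# ---------------------------------------------------------------------------

class TestWeights:
    def test_equal_aics_split_evenly(self):
        assert np.allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])

    def test_delta_two_closed_form(self):
        w = akaike_weights([10.0, 12.0])
        assert w[0] == pytest.approx(0.731, abs=0.001)
        assert w[1] == pytest.approx(0.269, abs=0.001)

    def test_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(0)
        aics = rng.uniform(100, 140, 12)
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, akaike_weights(aics + 57.3))
        assert (w >= 0).all()

    def test_all_infinite_errors(self):
        with pytest.raises(ValueError):
            akaike_weights([np.inf, np.inf])


def _toy_fit(beta, se, aic, n=100):
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    k = len(beta) + 3
    return LMMFit(beta=beta, se=se, loglik=-(aic - 2 * k) / 2, k=k, aic=aic,
                  sigma_subject=1.0, sigma_scene=1.0, sigma_resid=1.0,
                  converged=True, n=n)


class TestModelAverage:
    TERMS = [("a",), ("b",)]

    def test_single_candidate_degenerate(self):
        fit = _toy_fit([10.0, 2.0, -1.0], [1.0, 0.5, 0.25], 200.0)
        res = model_average([(("a",), ("b",))], [fit], np.array([1.0]),
                            self.TERMS)
        c = res.coefficients[1]
        assert c.estimate == pytest.approx(2.0)
        assert c.ci_low == pytest.approx(2.0 - 1.96 * 0.5)
        assert c.ci_high == pytest.approx(2.0 + 1.96 * 0.5)

    def test_zero_weight_candidate_ignored(self):
        f1 = _toy_fit([10.0, 2.0], [1.0, 0.5], 100.0)
        f2 = _toy_fit([0.0, -5.0], [1.0, 0.5], 500.0)
        res = model_average([(("a",),), (("a",),)], [f1, f2],
                            np.array([1.0, 0.0]), self.TERMS)
        assert res.coefficients[1].estimate == pytest.approx(2.0)

    def test_three_model_toy_matches_arithmetic_oracle(self):
        """Hand-built candidates; expectations computed with plain
        spreadsheet-style arithmetic, frozen below."""
        # candidates: {}, {a}, {a, b}; AICs 102, 100, 101
        fits = [_toy_fit([9.0], [1.0], 102.0),
                _toy_fit([10.0, 2.0], [1.0, 0.5], 100.0),
                _toy_fit([11.0, 3.0, -1.0], [1.0, 0.6, 0.2], 101.0)]
        cands = [(), (("a",),), (("a",), ("b",))]
        aics = np.array([f.aic for f in fits])
        w = akaike_weights(aics)
        # independent oracle
        d = aics - aics.min()
        ew = np.exp(-d / 2)
        w_exp = ew / ew.sum()
        assert np.allclose(w, w_exp, atol=1e-12)
        theta_a = w_exp[0] * 0.0 + w_exp[1] * 2.0 + w_exp[2] * 3.0
        se_a = (w_exp[0] * math.sqrt(0.0 + (0.0 - theta_a) ** 2)
                + w_exp[1] * math.sqrt(0.5 ** 2 + (2.0 - theta_a) ** 2)
                + w_exp[2] * math.sqrt(0.6 ** 2 + (3.0 - theta_a) ** 2))
        res = model_average(cands, fits, w, self.TERMS)
        c_a = res.coefficients[1]
        assert c_a.estimate == pytest.approx(theta_a, abs=1e-9)
        assert c_a.se == pytest.approx(se_a, abs=1e-9)
        assert c_a.ci_low == pytest.approx(theta_a - 1.96 * se_a, abs=1e-9)
        # summed weight of models containing 'a'
        assert c_a.weight_sum == pytest.approx(w_exp[1] + w_exp[2], abs=1e-12)

    def test_full_average_magnitude_bounded_by_candidates(self):
        fits = [_toy_fit([9.0], [1.0], 102.0),
                _toy_fit([10.0, 2.0], [1.0, 0.5], 100.0),
                _toy_fit([11.0, 3.0, -1.0], [1.0, 0.6, 0.2], 101.0)]
        cands = [(), (("a",),), (("a",), ("b",))]
        w = akaike_weights(np.array([f.aic for f in fits]))
        res = model_average(cands, fits, w, self.TERMS)
        assert abs(res.coefficients[1].estimate) <= 3.0
        assert abs(res.coefficients[2].estimate) <= 1.0

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            model_average([()], [], np.array([1.0]), self.TERMS)


# ---------------------------------------------------------------------------
# coding and the model table
# ---------------------------------------------------------------------------

def _tables(n_participants=4):
    design = generate_design(n_participants, seed=2)
    rng = np.random.default_rng(0)
    metrics = design[["trial_id", "participant_id", "scene_id", "perspective",
                      "valence"]].copy()
    metrics["total_aoi_fixation_ms"] = rng.uniform(200, 3000, len(design))
    ratings = design[["trial_id"]].copy()
    ratings["rating"] = rng.uniform(0, 100, len(design))
    participants = pd.DataFrame({
        "participant_id": design.participant_id.unique(),
        "anxiety": rng.normal(47, 10, n_participants),
        "age": rng.uniform(14, 19.75, n_participants)})
    return metrics, ratings, participants


class TestModelTable:
    def test_zscored_predictors(self):
        metrics, ratings, participants = _tables()
        rec = build_model_table(metrics, ratings, participants, "anxiety")
        for col in ("fixation", "anxiety"):
            assert rec[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert rec[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert set(rec.perspective.unique()) == {-0.5, 0.5}

    def test_row_conservation(self):
        metrics, ratings, participants = _tables()
        rec = build_model_table(metrics, ratings, participants, "age")
        assert len(rec) == len(metrics)

    def test_unmatched_ids_error(self):
        metrics, ratings, participants = _tables()
        ratings = ratings.iloc[:-5]
        with pytest.raises(ValueError, match="without ratings"):
            build_model_table(metrics, ratings, participants, "anxiety")

    def test_label_swap_flips_coefficient_sign(self):
        """Swapping self/other labels flips the perspective coefficient."""
        rng = np.random.default_rng(1)
        design = generate_design(6, seed=3)
        anx = dict(zip(design.participant_id.unique(),
                       rng.normal(47, 10, 6)))
        design["anxiety"] = design.participant_id.map(anx)
        fix = rng.uniform(500, 2000, len(design))
        rec = code_predictors(design, fix, "anxiety")
        y = 50 + 4.0 * rec["perspective"].to_numpy() + rng.normal(0, 1, len(rec))
        X = design_matrix(rec, [("perspective",)], ("perspective",))
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        flipped = design.copy()
        flipped["perspective"] = np.where(design.perspective == "self",
                                          "other", "self")
        rec2 = code_predictors(flipped, fix, "anxiety")
        X2 = design_matrix(rec2, [("perspective",)], ("perspective",))
        beta2 = np.linalg.lstsq(X2, y, rcond=None)[0]
        assert beta2[1] == pytest.approx(-beta[1], rel=1e-9)


# ---------------------------------------------------------------------------
# the mixed-model fitter
# ---------------------------------------------------------------------------

class TestLMMFitter:
    def _crossed_data(self, sig_s, sig_c, sig_e, nsub=10, nsc=8, seed=0):
        rng = np.random.default_rng(seed)
        subj = np.repeat(np.arange(nsub), nsc)
        scene = np.tile(np.arange(nsc), nsub)
        X = np.column_stack([np.ones(nsub * nsc),
                             rng.normal(size=nsub * nsc),
                             rng.normal(size=nsub * nsc)])
        y = (X @ [20.0, 3.0, -2.0]
             + np.repeat(rng.normal(0, sig_s, nsub), nsc)
             + np.tile(rng.normal(0, sig_c, nsc), nsub)
             + rng.normal(0, sig_e, nsub * nsc))
        return y, X, subj, scene

    def test_degenerate_limit_matches_ols(self):
        # large n so the boundary variance estimates shrink toward zero
        y, X, subj, scene = self._crossed_data(0.0, 0.0, 2.0,
                                               nsub=40, nsc=30, seed=5)
        fit = fit_crossed_lmm(y, X, subj, scene)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-3)
        assert fit.sigma_subject < 0.3 and fit.sigma_scene < 0.3

    def test_intercept_only_constant_response(self):
        n = 60
        y = np.full(n, 50.0)
        X = np.ones((n, 1))
        subj = np.repeat(np.arange(6), 10)
        scene = np.tile(np.arange(10), 6)
        fit = fit_crossed_lmm(y, X, subj, scene)
        assert fit.beta[0] == pytest.approx(50.0, abs=1e-6)
        assert fit.sigma_resid == pytest.approx(0.0, abs=1e-3)

    def test_aic_identity(self):
        y, X, subj, scene = self._crossed_data(2.0, 1.0, 2.0)
        fit = fit_crossed_lmm(y, X, subj, scene)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k, rel=1e-12)
        assert fit.k == X.shape[1] + 3

    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: generic variance-component ML fit."""
        import statsmodels.api as sm
        y, X, subj, scene = self._crossed_data(3.0, 2.0, 2.0, seed=7)
        fit = fit_crossed_lmm(y, X, subj, scene)
        df = pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2],
                           "subj": subj, "scene": scene, "g": 1})
        md = sm.MixedLM.from_formula(
            "y ~ x1 + x2", groups="g",
            vc_formula={"subj": "0 + C(subj)", "scene": "0 + C(scene)"},
            data=df)
        ref = md.fit(reml=False)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert np.allclose(fit.beta, ref.fe_params.values, atol=1e-3)
        assert np.allclose(fit.se, ref.bse_fe.values, rtol=0.05)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

class TestRunAnalysis:
    def test_sixteen_rows_and_weights_sum(self):
        from peergaze.simulate import simulate_model_records
        rec = simulate_model_records(8, which="anxiety", seed=0)
        res = run_analysis(rec, "anxiety")
        assert len(res.coefficients) == 16
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.n_candidates == 167

    def test_strong_effect_recovered(self):
        from peergaze.simulate import TruthModel, simulate_model_records
        truth = TruthModel(beta={"intercept": 50.0, "valence:fixation": -6.0},
                           sigma_subject=3.0, sigma_scene=2.0, sigma_resid=10.0)
        rec = simulate_model_records(20, truth, "anxiety", seed=4)
        res = run_analysis(rec, "anxiety")
        by_term = {c.term: c for c in res.coefficients}
        c = by_term["valence:fixation"]
        assert c.significant
        assert c.ci_low <= -6.0 <= c.ci_high
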