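"""Joint logistic model, cross-validation, AUC, calibration, NRI."""

import numpy as np
import pandas as pd
import pytest

import multiprs as mp
from multiprs.types import PerfectSeparationError


class TestFit:
    def test_full_predictor_set_gives_15_coefficients(self, small_study):
        m = mp.fit_multiprs(small_study.scores, small_study.cohort, "major_macro")
        assert len(m.coef) == 15  # 10 wPRS + pc1 + sex + age + duration + intercept
        assert m.predictors[:1] == ["wPRS_diabetes"]
        assert m.predictors[-3:] == ["sex", "age_at_onset", "diabetes_duration"]
        assert m.converged

    def test_two_by_two_closed_form_slope(self):
        """Events 10/100 at x=0 and 30/100 at x=1: slope = ln(27/7) ~ 1.3499."""
        x = np.repeat([0.0, 1.0], 100).reshape(-1, 1)
        y = np.concatenate([np.repeat([1, 0], [10, 90]), np.repeat([1, 0], [30, 70])])
        m = mp.fit_logistic(x, y, ["x"], "toy")
        assert m.coef["x"] == pytest.approx(np.log((30 / 70) / (10 / 90)), abs=1e-6)
        assert m.coef["x"] == pytest.approx(1.3499, abs=1e-4)

    def test_single_class_outcome_raises(self, small_study):
        cohort = small_study.cohort
        cohort.table["always_zero"] = 0
        try:
            with pytest.raises(ValueError, match="single class"):
                mp.fit_multiprs(small_study.scores, cohort, "always_zero")
        finally:
            cohort.table.drop(columns=["always_zero"], inplace=True)

    def test_perfect_separation_flagged(self):
        x = np.repeat([0.0, 1.0], 50).reshape(-1, 1)
        y = np.repeat([0, 1], 50)
        with pytest.raises(PerfectSeparationError):
            mp.fit_logistic(x, y, ["x"], "sep")

    def test_model_json_round_trip(self, small_study, tmp_path):
        m = mp.fit_multiprs(small_study.scores, small_study.cohort, "stroke")
        m.to_json(tmp_path / "m.json")
        back = mp.MultiPRSModel.from_json(tmp_path / "m.json")
        assert back.coef == m.coef and back.predictors == m.predictors


class TestCrossval:
    def make_toy(self, n=20, events=10, seed=0):
        rng = np.random.default_rng(seed)
        from conftest import toy_weightset, toy_genotypes

        ws = toy_weightset([0.2, 0.3, 0.1])
        geno = toy_genotypes(rng.integers(0, 3, (n, 3)).astype(float), ws)
        scores = mp.compute_wprs(geno, ws)
        y = np.zeros(n, dtype=int)
        y[:events] = 1
        table = pd.DataFrame(
            {
                "individual_id": scores.individual_ids,
                "sex": rng.integers(0, 2, n),
                "age_at_onset": rng.normal(58, 9, n).clip(30, 80),
                "diabetes_duration": rng.normal(8, 5, n).clip(0, 30),
                "pc1": rng.normal(0, 1, n),
                "y": rng.permutation(y),
            }
        )
        cohort = mp.TrialCohort(table=table, outcomes=["y"])
        return scores, cohort

    def test_leave_one_out_when_n_equals_folds(self):
        scores, cohort = self.make_toy(n=10, events=5)
        oof = mp.crossval_predict(scores, cohort, "y", folds=10, seed=1,
                                  predictors=["wPRS_cvd"])
        assert len(oof) == 10
        assert oof["prob"].notna().all()
        assert sorted(oof["fold"].unique()) == list(range(10))

    def test_stratified_folds_hold_one_event_each(self):
        scores, cohort = self.make_toy(n=20, events=10)
        oof = mp.crossval_predict(scores, cohort, "y", folds=10, seed=3,
                                  predictors=["wPRS_cvd"])
        per_fold = oof.groupby("fold")["outcome_value"].sum()
        assert (per_fold == 1).all()

    def test_fixed_seed_reproducible(self, small_study):
        a = mp.crossval_predict(small_study.scores, small_study.cohort, "stroke", seed=9)
        b = mp.crossval_predict(small_study.scores, small_study.cohort, "stroke", seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_exactly_one_prediction_per_individual(self, small_study):
        oof = mp.crossval_predict(small_study.scores, small_study.cohort,
                                  "major_macro", seed=2)
        assert len(oof) == small_study.cohort.n
        assert oof["individual_id"].is_unique


class TestAUC:
    def test_printed_four_point_example(self):
        """3 of 4 case-control pairs concordant: AUC = 0.75."""
        r = mp.auc_with_ci(np.array([0.1, 0.4, 0.35, 0.8]),
                           np.array([0, 0, 1, 1]), n_boot=200, seed=0)
        assert r.auc == pytest.approx(0.75)
        assert r.ci_low <= r.auc <= r.ci_high

    def test_perfect_separation_gives_one(self):
        assert mp.mann_whitney_auc(np.array([1, 2, 3, 10, 11]),
                                   np.array([0, 0, 0, 1, 1])) == 1.0

    def test_constant_scores_give_half_by_tie_correction(self):
        assert mp.mann_whitney_auc(np.full(10, 0.5),
                                   np.array([0, 1] * 5)) == pytest.approx(0.5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        y = (rng.random(200) < p).astype(int)
        logit = np.log(p / (1 - p))
        assert mp.mann_whitney_auc(p, y) == pytest.approx(mp.mann_whitney_auc(logit, y))

    def test_roc_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(1)
        r = mp.auc_with_ci(rng.random(100), rng.integers(0, 2, 100), n_boot=100, seed=1)
        roc = r.roc
        assert roc["fpr"].iloc[0] == 0 and roc["tpr"].iloc[0] == 0
        assert roc["fpr"].iloc[-1] == 1 and roc["tpr"].iloc[-1] == 1
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()

    def test_one_class_absent_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            mp.mann_whitney_auc(np.array([0.2, 0.4]), np.array([1, 1]))


class TestHosmerLemeshow:
    def test_observed_equals_expected_gives_zero_statistic(self):
        probs = np.repeat([0.1, 0.2, 0.3, 0.4], 10)
        labels = np.concatenate(
            [np.repeat([1, 0], [int(p * 10), 10 - int(p * 10)]) for p in (0.1, 0.2, 0.3, 0.4)]
        )
        r = mp.hosmer_lemeshow(probs, labels, bins=4)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pi == pytest.approx(1.0)
        assert r.df == 2

    def test_four_bin_hand_fixture(self):
        """Statistic equals the hand-summed value on a printed fixture."""
        # bins: n=10 each, mean predicted (0.1, 0.2, 0.3, 0.4), observed (2, 1, 4, 5)
        probs = np.repeat([0.1, 0.2, 0.3, 0.4], 10)
        observed = [2, 1, 4, 5]
        labels = np.concatenate([np.repeat([1, 0], [o, 10 - o]) for o in observed])
        hand = 0.0
        for p, o in zip((0.1, 0.2, 0.3, 0.4), observed):
            e = 10 * p
            hand += (o - e) ** 2 / (e * (1 - p))
        r = mp.hosmer_lemeshow(probs, labels, bins=4)
        assert r.statistic == pytest.approx(hand, abs=1e-10)
        assert (r.bins["n"] == 10).all()

    def test_bins_partition_the_cohort(self, small_study):
        oof = mp.crossval_predict(small_study.scores, small_study.cohort,
                                  "major_macro", seed=1)
        y = small_study.cohort.outcome_vector("major_macro")
        r = mp.hosmer_lemeshow(oof["prob"].to_numpy(), y)
        assert r.bins["n"].sum() == small_study.cohort.n
        assert r.df == len(r.bins) - 2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            mp.hosmer_lemeshow(np.random.rand(100), np.zeros(100, int), bins=2)


class TestNRI:
    def test_identical_scores_give_zero(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 1, 0, 1])
        r = mp.continuous_nri(p, p, y)
        assert r.nri_total == 0 == r.nri_events == r.nri_nonevents

    def test_maximum_is_two(self):
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.9, 0.9, 0.1, 0.1])
        y = np.array([1, 1, 0, 0])
        assert mp.continuous_nri(old, new, y).nri_total == pytest.approx(2.0)

    def test_printed_count_example(self):
        """Events 3 up / 1 down of 4; nonevents 6 down / 2 up of 8: NRI = 1.0."""
        y = np.array([1] * 4 + [0] * 8)
        old = np.full(12, 0.5)
        new = np.array([0.6, 0.6, 0.6, 0.4] + [0.4] * 6 + [0.6] * 2)
        r = mp.continuous_nri(old, new, y)
        assert r.nri_events == pytest.approx(0.5)
        assert r.nri_nonevents == pytest.approx(0.5)
        assert r.nri_total == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        old, new = rng.random(50), rng.random(50)
        y = rng.integers(0, 2, 50)
        fwd = mp.continuous_nri(old, new, y)
        rev = mp.continuous_nri(new, old, y)
        assert fwd.nri_events == pytest.approx(-rev.nri_events)
        assert fwd.nri_nonevents == pytest.approx(-rev.nri_nonevents)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            mp.continuous_nri(np.zeros(3), np.zeros(4), np.array([0, 1, 0, 1]))


class TestDecomposition:
    def test_components_reported_and_full_model_best(self, small_study):
        dec = mp.auc_decomposition(small_study.scores, small_study.cohort,
                                   "cardiovascular_death", seed=4, n_boot=50)
        assert set(dec["component"]) == {"genomic", "sex", "age_at_onset",
                                         "diabetes_duration", "full"}
        aucs = dict(zip(dec["component"], dec["auc"]))
        assert aucs["full"] >= max(v for k, v in aucs.items() if k != "full") - 0.02
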