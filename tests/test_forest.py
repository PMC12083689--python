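import numpy as np
import pandas as pd
import pytest
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

import sirisurv.forest as sf
import sirisurv.synthetic as syn
from sirisurv.errors import DomainError, InvalidConfigError, UndefinedResultError

from conftest import censored_instance


def brute_force_cindex(scores, times, events) -> float:
    """Independent oracle: explicit loop over all n(n-1)/2 pairs."""
    n = len(scores)
    concordant = 0.0
    evaluable = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i] == 1:
                evaluable += 1
                if scores[i] > scores[j]:
                    concordant += 1.0
                elif scores[i] == scores[j]:
                    concordant += 0.5
    return concordant / evaluable


class TestConcordance:
    def test_perfect_and_inverted_rankings(self):
        times = np.array([5.0, 3.0, 8.0, 1.0])
        events = np.ones(4, dtype=int)
        assert sf.concordance_index(-times, times, events) == 1.0
        assert sf.concordance_index(times, times, events) == 0.0

    def test_matches_bruteforce_on_censored_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            scores, times, events = censored_instance(rng, 50)
            assert sf.concordance_index(scores, times, events) == pytest.approx(
                brute_force_cindex(scores, times, events), abs=1e-12)

    def test_agrees_with_sksurv(self):
        # continuous times/scores: no ties, where the censoring-orderability
        # conventions of every implementation coincide
        rng = np.random.default_rng(8)
        times = rng.exponential(20, 80)
        censor = rng.exponential(30, 80)
        obs = np.minimum(times, censor)
        events = (times <= censor).astype(int)
        scores = rng.normal(size=80)
        ours = sf.concordance_index(scores, obs, events)
        theirs = concordance_index_censored(events.astype(bool), obs, scores)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores, times, events = censored_instance(rng, 60)
        base = sf.concordance_index(scores, times, events)
        assert sf.concordance_index(np.exp(scores), times, events) == pytest.approx(base)
        assert sf.concordance_index(3 * scores + 7, times, events) == pytest.approx(base)

    def test_no_evaluable_pair_raises(self):
        with pytest.raises(UndefinedResultError):
            sf.concordance_index([1, 2], [5.0, 5.0], [1, 1])  # tied times
        with pytest.raises(UndefinedResultError):
            sf.concordance_index([1, 2], [1.0, 2.0], [0, 0])  # no events


class TestTimeDependentAUC:
    def test_constant_scores_give_half(self):
        rng = np.random.default_rng(1)
        _, times, events = censored_instance(rng, 60)
        events[:5] = 1
        assert sf.time_dependent_auc(np.ones(60), times, events, 15.0) == pytest.approx(0.5)

    def test_perfect_separation_no_censoring(self):
        times = np.array([2.0, 4.0, 6.0, 20.0, 30.0, 40.0])
        events = np.ones(6, dtype=int)
        scores = np.array([9.0, 8.0, 7.0, 1.0, 2.0, 3.0])
        assert sf.time_dependent_auc(scores, times, events, 10.0) == 1.0

    def test_agrees_with_sksurv_oracle(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(20, 120) + 0.1
        censor = rng.exponential(40, 120) + 0.1
        obs = np.minimum(times, censor)
        events = (times <= censor).astype(int)
        scores = rng.normal(size=120)
        y = Surv.from_arrays(event=events.astype(bool), time=obs)
        for horizon in (10.0, 20.0):
            ours = sf.time_dependent_auc(scores, obs, events, horizon)
            theirs = cumulative_dynamic_auc(y, y, scores, [horizon])[0][0]
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_no_cases_raises(self):
        with pytest.raises(UndefinedResultError):
            sf.time_dependent_auc([1, 2], [50.0, 60.0], [1, 1], 10.0)


class TestSingleTree:
    def test_min_terminal_size_n_gives_single_leaf(self, signal_cohort):
        tree = sf.grow_survival_tree(
            signal_cohort, sf.ForestConfig(min_terminal_size=len(signal_cohort)))
        assert tree.n_leaves == 1
        assert tree.root_split() is None

    def test_fixed_seed_reproduces_tree(self, signal_cohort):
        a = sf.grow_survival_tree(signal_cohort, random_state=3)
        b = sf.grow_survival_tree(signal_cohort, random_state=3)
        assert np.array_equal(a.model.tree_.threshold, b.model.tree_.threshold)
        assert np.array_equal(a.model.tree_.feature, b.model.tree_.feature)

    def test_root_split_recovers_planted_step(self):
        """Single covariate with a step effect at 3.5: the root threshold
        lands within +-0.5 of the truth in >= 80% of 20 seeds."""
        hits = 0
        for seed in range(20):
            cfg = syn.CohortConfig(n_subjects=500, siri_log_sd=syn.SIRI_LOG_SD_WIDE,
                                   seed=seed)
            spec = syn.HazardSpec(baseline_rate=0.01, threshold_effects=(
                syn.ThresholdEffect("siri", 3.5, "ge", float(np.log(2.5))),))
            cohort = syn.assign_survival(syn.generate_covariates(cfg), spec, seed=seed)
            tree = sf.grow_survival_tree(cohort, variables=["siri"], random_state=seed)
            var, threshold = tree.root_split()
            hits += var == "siri" and abs(threshold - 3.5) <= 0.5
        assert hits >= 16


class TestForest:
    def test_default_config_matches_published_settings(self):
        cfg = sf.ForestConfig()
        assert cfg.n_trees == 1000
        with pytest.raises(InvalidConfigError):
            sf.ForestConfig(n_trees=0)

    def test_refuses_eventless_cohort(self, null_cohort):
        dead = null_cohort.copy()
        dead["event"] = 0
        with pytest.raises(DomainError):
            sf.fit_forest(dead, sf.ForestConfig(n_trees=5))

    def test_single_leaf_forest_scores_everyone_equally(self, signal_cohort):
        model = sf.fit_forest(signal_cohort, sf.ForestConfig(
            n_trees=5, min_terminal_size=len(signal_cohort), seed=1))
        scores = sf.predict_mortality(model, signal_cohort)
        assert np.allclose(scores, scores[0])

    def test_ensemble_score_is_mean_of_tree_scores(self, signal_cohort):
        model = sf.fit_forest(signal_cohort.head(150),
                              sf.ForestConfig(n_trees=10, seed=2))
        X = model.X[:20]
        ensemble = model.model.predict(X)
        per_tree = model.tree_scores(X)
        assert np.allclose(per_tree.mean(axis=0), ensemble, rtol=1e-10)

    def test_crossing_high_risk_threshold_raises_score(self, signal_forest,
                                                       signal_cohort):
        low = signal_cohort.iloc[[0]].copy()
        low["siri"] = 1.0
        high = low.copy()
        high["siri"] = 6.0
        s_low = sf.predict_mortality(signal_forest, low)[0]
        s_high = sf.predict_mortality(signal_forest, high)[0]
        assert s_high > s_low

    def test_forest_reproducible_from_seed(self, signal_cohort):
        small = signal_cohort.head(200)
        cfg = sf.ForestConfig(n_trees=30, seed=5)
        a = sf.fit_forest(small, cfg)
        b = sf.fit_forest(small, cfg)
        assert np.allclose(sf.predict_mortality(a, small), sf.predict_mortality(b, small))
        assert sf.permutation_vimp(a, seed=3) == sf.permutation_vimp(b, seed=3)

    def test_oob_cindex_signal_vs_null(self, signal_forest, null_cohort):
        assert sf.oob_concordance(signal_forest) > 0.6
        null_model = sf.fit_forest(null_cohort, sf.ForestConfig(n_trees=150, seed=3))
        assert sf.oob_concordance(null_model) == pytest.approx(0.5, abs=0.07)


class TestVimp:
    def test_signal_variable_beats_noise(self, signal_cohort):
        rng = np.random.default_rng(0)
        cohort = signal_cohort.copy()
        cohort["noise"] = rng.normal(size=len(cohort))
        model = sf.fit_forest(cohort, sf.ForestConfig(n_trees=200, seed=4),
                              variables=["siri", "kps_cat", "noise"])
        vimp = sf.permutation_vimp(model, seed=9, n_repeats=10)
        assert vimp["siri"] > vimp["noise"]
        assert abs(vimp["noise"]) <= 0.02

    def test_vimp_requires_known_variable(self, signal_forest):
        with pytest.raises(DomainError):
            sf.extract_split_thresholds(signal_forest, "not_a_variable")


class TestSplitExtraction:
    def test_never_split_variable_returns_empty(self, signal_cohort):
        cohort = signal_cohort.copy()
        cohort["constant"] = 1.0
        model = sf.fit_forest(cohort, sf.ForestConfig(n_trees=20, seed=1),
                              variables=["siri", "constant"])
        thresholds, sizes = sf.extract_split_thresholds(model, "constant")
        assert len(thresholds) == 0 and len(sizes) == 0

    def test_two_valued_covariate_always_splits_at_midpoint(self):
        """x in {3, 4} with a strong survival difference: every split on x
        must fall at the midpoint 3.5, once per tree."""
        rng = np.random.default_rng(6)
        n = 200
        x = np.repeat([3.0, 4.0], n // 2)
        rate = np.where(x == 4.0, 0.1, 0.01)
        df = pd.DataFrame({
            "x": x,
            "time_months": rng.exponential(1 / rate),
            "event": np.ones(n, dtype=int),
        })
        model = sf.fit_forest(df, sf.ForestConfig(n_trees=25, seed=2,
                                                  variables_per_split=1,
                                                  min_terminal_size=50),
                              variables=["x"])
        thresholds, _ = sf.extract_split_thresholds(model, "x")
        assert len(thresholds) == 25
        assert np.allclose(thresholds, 3.5)

    def test_multiset_cardinality_matches_full_traversal(self, signal_forest):
        thresholds, sizes = sf.extract_split_thresholds(signal_forest, "siri")
        j = signal_forest.variables.index("siri")
        count = 0
        for est in signal_forest.model.estimators_:
            t = est.tree_
            stack = [0]
            while stack:  # explicit DFS, independent of the mask-based path
                node = stack.pop()
                if t.children_left[node] >= 0:
                    if t.feature[node] == j:
                        count += 1
                    stack.extend([t.children_left[node], t.children_right[node]])
        assert len(thresholds) == count == len(sizes)


def test_split_cohort_is_stratified_and_disjoint(signal_cohort):
    train, test = sf.split_cohort(signal_cohort, test_size=0.3, seed=1)
    assert len(train) + len(test) == len(signal_cohort)
    assert not set(train["id"]) & set(test["id"])
    assert test["event"].mean() == pytest.approx(train["event"].mean(), abs=0.05)
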