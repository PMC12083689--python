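import numpy as np
import pandas as pd
import pytest

import sirisurv.risktree as rt
import sirisurv.synthetic as syn
from sirisurv.distill import CutoffSet
from sirisurv.errors import DomainError, InvalidConfigError


def _cutoffset(variable, cutoffs):
    return CutoffSet(variable=variable, cutoffs=np.asarray(cutoffs, dtype=float))


def _three_level_cohort(seed, n=600):
    """Categorical survival data with a planted 3-variable hazard ladder."""
    rng = np.random.default_rng(seed)
    siri_cat = rng.integers(0, 2, n)       # 1 ~ SIRI above cutoff
    kps_cat = rng.integers(0, 2, n)        # 1 ~ KPS <= 70
    smoking = rng.choice(["never", "former", "current"], n)
    log_rate = np.log(0.02) + np.log(3.0) * siri_cat + np.log(2.2) * kps_cat \
        + np.log(1.8) * (smoking == "current")
    times = rng.exponential(1 / np.exp(log_rate))
    censor = np.minimum(rng.exponential(80, n), 120.0)
    obs = np.minimum(times, censor)
    events = (times <= censor).astype(int)
    cats = pd.DataFrame({"siri": siri_cat, "kps_cat": kps_cat, "smoking": smoking})
    return cats, obs, events


class TestDiscretize:
    def test_bmi_intervals_and_boundary_convention(self):
        cohort = pd.DataFrame({"bmi": [27.0, 24.9, 25.0, 30.0, 18.0],
                               "siri": [3.5, 1.0, 4.0, 2.0, 3.49]})
        cats = rt.discretize(cohort, [_cutoffset("bmi", [25.0, 30.0]),
                                      _cutoffset("siri", [3.5])])
        # BMI 27 lands in the middle interval (2nd of 3, zero-based index 1)
        assert cats["bmi"].tolist() == [1, 0, 1, 2, 0]
        # boundary value equals the cutoff -> upper interval
        assert cats["siri"].tolist() == [1, 0, 1, 0, 0]

    def test_empty_cutoffset_collapses_with_warning(self):
        cohort = pd.DataFrame({"siri": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="single category"):
            cats = rt.discretize(cohort, [_cutoffset("siri", [])])
        assert (cats["siri"] == 0).all()

    def test_missing_value_raises(self):
        cohort = pd.DataFrame({"siri": [1.0, np.nan]})
        with pytest.raises(DomainError):
            rt.discretize(cohort, [_cutoffset("siri", [3.5])])


class TestGrowTree:
    def test_config_defaults_and_validation(self):
        cfg = rt.RiskTreeConfig()
        assert cfg.max_depth == 3 and cfg.min_node_size == 40
        with pytest.raises(InvalidConfigError):
            rt.RiskTreeConfig(max_depth=0)
        with pytest.raises(InvalidConfigError):
            rt.RiskTreeConfig(min_node_size=1)

    def test_depth_and_node_size_constraints_hold(self):
        for seed in range(20):
            cats, times, events = _three_level_cohort(seed, n=400)
            cfg = rt.RiskTreeConfig(max_depth=3, min_node_size=40)
            tree = rt.grow_risk_tree(cats, times, events, cfg)
            leaves = tree.leaves()
            assert sum(len(l.indices) for l in leaves) == 400
            for leaf in leaves:
                assert leaf.depth <= 3
                assert len(leaf.indices) >= 40

    def test_single_binary_covariate_gives_at_most_two_leaves(self):
        cats, times, events = _three_level_cohort(3)
        tree = rt.grow_risk_tree(cats[["siri"]], times, events)
        assert len(tree.leaves()) <= 2

    def test_planted_variables_recovered(self):
        """>=2 of the 3 planted split variables appear in the grown tree in
        >=80% of 20 seeds."""
        hits = 0
        for seed in range(20):
            cats, times, events = _three_level_cohort(seed)
            tree = rt.grow_risk_tree(cats, times, events)
            used = set()

            def walk(node):
                if not node.is_leaf:
                    used.add(node.variable)
                    walk(node.left)
                    walk(node.right)

            walk(tree.root)
            hits += len(used & {"siri", "kps_cat", "smoking"}) >= 2
        assert hits >= 16

    def test_eventless_data_rejected(self):
        cats, times, events = _three_level_cohort(1, n=100)
        with pytest.raises(DomainError):
            rt.grow_risk_tree(cats, times, np.zeros(100, dtype=int))


def _grown(seed, n=600, rates=(0.01, 0.04, 0.16, 0.16)):
    """Two binary covariates -> 4 cells with the given hazard rates."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    cell = 2 * a + b
    times = rng.exponential(1 / np.asarray(rates)[cell])
    censor = np.minimum(rng.exponential(120, n), 150.0)
    obs = np.minimum(times, censor)
    events = (times <= censor).astype(int)
    cats = pd.DataFrame({"a": a, "b": b})
    cfg = rt.RiskTreeConfig(max_depth=2, min_node_size=40)
    tree = rt.grow_risk_tree(cats, obs, events, cfg)
    # mortality proxy for leaf ordering: the true cell rate
    scores = np.asarray(rates)[cell]
    return tree, obs, events, scores, cats


class TestMergeLeaves:
    def test_identical_hazard_leaves_merge_to_three_groups(self):
        """4 leaves where the two highest-risk cells share one hazard:
        merging at alpha=0.05 lands on 3 groups in >=80% of 20 seeds."""
        hits = 0
        for seed in range(20):
            tree, obs, events, scores, _ = _grown(seed)
            if len(tree.leaves()) != 4:
                continue
            model = rt.merge_leaves(tree, obs, events, scores, alpha=0.05)
            hits += model.n_groups == 3
        assert hits >= 16

    def test_well_separated_leaves_do_not_merge(self):
        tree, obs, events, scores, _ = _grown(5, n=2000,
                                              rates=(0.005, 0.03, 0.1, 0.5))
        model = rt.merge_leaves(tree, obs, events, scores, alpha=0.05)
        assert model.n_groups == len(tree.leaves())

    def test_target_group_count_one_merges_everything(self):
        tree, obs, events, scores, _ = _grown(2)
        model = rt.merge_leaves(tree, obs, events, scores, target_groups=1)
        assert model.n_groups == 1

    def test_group_mean_mortality_strictly_increasing(self):
        tree, obs, events, scores, _ = _grown(7)
        model = rt.merge_leaves(tree, obs, events, scores, alpha=0.05)
        means = [model.group_mean_scores[g] for g in sorted(model.group_mean_scores)]
        assert np.all(np.diff(means) > 0)


class TestAssignment:
    def test_routing_is_deterministic_and_total(self):
        tree, obs, events, scores, cats = _grown(9)
        model = rt.merge_leaves(tree, obs, events, scores, alpha=0.05)
        groups_a = rt.assign_risk_group(model, cats)
        groups_b = rt.assign_risk_group(model, cats)
        assert np.array_equal(groups_a, groups_b)
        assert set(groups_a) <= set(model.group_mean_scores)
        # identical patients get identical groups
        row = cats.iloc[0].to_dict()
        assert rt.assign_risk_group(model, row) == groups_a[0]

    def test_missing_variable_raises(self):
        tree, obs, events, scores, cats = _grown(9)
        model = rt.merge_leaves(tree, obs, events, scores)
        with pytest.raises(DomainError):
            rt.assign_risk_group(model, {"a": 1})

    def test_event_rate_non_decreasing_in_group(self):
        tree, obs, events, scores, cats = _grown(11, n=1200)
        model = rt.merge_leaves(tree, obs, events, scores, alpha=0.05)
        groups = rt.assign_risk_group(model, cats)
        rates = [events[groups == g].mean() for g in sorted(set(groups))]
        assert np.all(np.diff(rates) >= 0)


class TestThresholdHighRisk:
    def test_quantile_arithmetic(self):
        labels = rt.threshold_high_risk([1.0, 2.0, 3.0, 4.0], quantile=0.75)
        assert labels.tolist() == [False, False, False, True]

    def test_large_sample_high_fraction_near_quarter(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        assert rt.threshold_high_risk(scores).mean() == pytest.approx(0.25, abs=0.01)

    def test_training_reference_applied_to_test_set(self):
        rng = np.random.default_rng(1)
        train, test = rng.normal(size=2000), rng.normal(size=2000)
        frac = rt.threshold_high_risk(test, reference_scores=train).mean()
        assert frac == pytest.approx(0.25, abs=0.03)

    def test_degenerate_scores_raise(self):
        with pytest.raises(DomainError):
            rt.threshold_high_risk([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(DomainError):
            rt.threshold_high_risk([1.0, 2.0])


def test_rules_and_json_serialization():
    tree, obs, events, scores, _ = _grown(4)
    model = rt.merge_leaves(tree, obs, events, scores)
    rules = model.rules()
    assert len(rules) == len(tree.leaves())
    assert all("Group" in r for r in rules)
    payload = model.to_json()
    assert "leaf_to_group" in payload
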