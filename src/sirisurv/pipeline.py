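"""End-to-end orchestration: simulate -> features -> forest -> distill ->
risk tree -> validate -> FT association.

The contract that matters most here is train/test hygiene: the cohort is
split 70/30 (stratified by the event indicator) *before* any model
fitting; the forest, the cutoffs and the risk tree see only the training
rows, and every validation statistic is computed on the held-out test
rows.  The split membership is recorded in the run report so the
separation is checkable after the fact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import distill, forest, ft, risktree, stats, synthetic
from .errors import SirisurvError
from .features import FT_HIGH, FT_LOW, categorize_ft, ensure_siri
from .rand import substream_seed

__all__ = ["PipelineConfig", "run_pipeline", "report_to_json"]

AUC_HORIZONS = (12.0, 24.0, 36.0, 48.0, 60.0)


@dataclass(frozen=True)
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    hazard: synthetic.HazardSpec = field(default_factory=synthetic.default_hazard_spec)
    ft_spec: synthetic.FTSpec | None = field(default_factory=synthetic.FTSpec)
    forest: forest.ForestConfig = field(default_factory=forest.ForestConfig)
    risk_tree: risktree.RiskTreeConfig = field(default_factory=risktree.RiskTreeConfig)
    variables: tuple[str, ...] = ("siri", "kps_cat", "bmi", "smoking")
    continuous_variables: tuple[str, ...] = ("siri", "bmi")
    test_size: float = 0.30
    high_risk_quantile: float = 0.75
    master_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _effect_to_dict(e: stats.EffectEstimate) -> dict:
    return {"hazard_ratio": e.hazard_ratio, "ci_lower": e.ci_lower,
            "ci_upper": e.ci_upper, "p_value": e.p_value}


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run every stage and return the run report (a plain dict, JSON-ready).

    When ``cohort`` is None a synthetic cohort is generated from the
    config; a user-supplied cohort must follow the standard CSV schema
    (``siri`` or CBC columns, ``time_months``, ``event``, covariates).
    """
    seed = config.master_seed
    report: dict = {"config_hash": config.config_hash(), "seeds": {"master": seed}}

    # --- simulate -----------------------------------------------------
    if cohort is None:
        cohort_cfg = dataclasses.replace(config.cohort,
                                         seed=substream_seed(seed, "cohort"))
        cohort = synthetic.generate_cohort(cohort_cfg, config.hazard, config.ft_spec)
        report["seeds"]["cohort"] = cohort_cfg.seed
    cohort = ensure_siri(cohort)
    report["n_subjects"] = int(len(cohort))
    report["n_events"] = int(cohort["event"].sum())

    # --- split (before any fitting) -----------------------------------
    split_seed = substream_seed(seed, "split")
    train, test = forest.split_cohort(cohort, test_size=config.test_size, seed=split_seed)
    report["seeds"]["split"] = split_seed
    train_ids = set(train["id"]) if "id" in train.columns else set(train.index)
    test_ids = set(test["id"]) if "id" in test.columns else set(test.index)
    if train_ids & test_ids:
        raise SirisurvError("train/test hygiene violated: overlapping subjects")
    report["split"] = {"n_train": len(train), "n_test": len(test),
                      "train_test_disjoint": True}

    # --- forest on train only ------------------------------------------
    forest_cfg = dataclasses.replace(config.forest, seed=substream_seed(seed, "forest"))
    model = forest.fit_forest(train, forest_cfg, list(config.variables))
    train_scores = forest.predict_mortality(model, train)
    test_scores = forest.predict_mortality(model, test)
    t_test = test["time_months"].to_numpy(float)
    e_test = test["event"].to_numpy(int)
    perf = {
        "c_index_train": forest.concordance_index(
            train_scores, train["time_months"], train["event"]),
        "c_index_test": forest.concordance_index(test_scores, t_test, e_test),
        "c_index_oob": forest.oob_concordance(model),
        "auc": {},
    }
    for horizon in AUC_HORIZONS:
        try:
            perf["auc"][f"{int(horizon)}m"] = forest.time_dependent_auc(
                test_scores, t_test, e_test, horizon)
        except SirisurvError:
            perf["auc"][f"{int(horizon)}m"] = None
    perf["vimp"] = forest.permutation_vimp(model, seed=substream_seed(seed, "vimp"),
                                           n_repeats=3)
    report["forest"] = perf

    # --- distill cutoffs from the train-fitted forest ------------------
    cutoffsets = []
    report["cutoffs"] = {}
    for var in config.continuous_variables:
        cs = distill.distill_cutoffs(model, var, train[var].to_numpy(float))
        cutoffsets.append(cs)
        report["cutoffs"][var] = {"cutoffs": [float(c) for c in cs.cutoffs],
                                  "status": cs.status}

    # --- risk tree + leaf merging on train ------------------------------
    extra = [v for v in config.variables if v not in config.continuous_variables]
    cat_train = risktree.discretize(train, cutoffsets, extra_categorical=extra)
    tree = risktree.grow_risk_tree(cat_train, train["time_months"], train["event"],
                                   config.risk_tree)
    group_model = risktree.merge_leaves(
        tree, train["time_months"], train["event"], train_scores,
        alpha=config.risk_tree.merge_alpha, target_groups=config.risk_tree.target_groups)
    report["risk_tree"] = {
        "n_leaves": len(tree.leaves()),
        "n_groups": group_model.n_groups,
        "rules": group_model.rules(),
        "group_mean_scores": group_model.group_mean_scores,
    }

    # --- validation on the held-out test set ----------------------------
    cat_test = risktree.discretize(test, cutoffsets, extra_categorical=extra)
    test_groups = risktree.assign_risk_group(group_model, cat_test)
    validation: dict = {"group_sizes": {int(g): int(np.sum(test_groups == g))
                                        for g in np.unique(test_groups)}}
    if len(np.unique(test_groups)) >= 2:
        global_test = stats.logrank_test(t_test, e_test, test_groups)
        validation["global_logrank"] = {"statistic": global_test.statistic,
                                        "df": global_test.df,
                                        "p_value": global_test.p_value}
        pairwise = stats.pairwise_logrank(t_test, e_test, test_groups)
        pairs = sorted(pairwise)
        pvals = [pairwise[p].p_value for p in pairs]
        reject, adjusted = stats.holm_bonferroni(pvals)
        validation["pairwise"] = {}
        for (pair, p_raw, p_adj, rej) in zip(pairs, pvals, adjusted, reject):
            entry = {"p_value": p_raw, "p_holm": float(p_adj), "reject": bool(rej)}
            a, b = pair
            mask = (test_groups == a) | (test_groups == b)
            try:
                hr = stats.cox_univariable(t_test[mask], e_test[mask],
                                           (test_groups[mask] == b).astype(float),
                                           reference=f"Group {a}")
                entry["cox"] = _effect_to_dict(hr)
            except SirisurvError as exc:
                entry["cox"] = {"error": str(exc)}
            validation["pairwise"][f"{a}_vs_{b}"] = entry
    else:
        validation["global_logrank"] = None
        validation["pairwise"] = {}
    # 75th-percentile high/low stratification of the forest risk scores
    high = risktree.threshold_high_risk(test_scores, config.high_risk_quantile,
                                        reference_scores=train_scores)
    validation["high_risk"] = {"n_high": int(high.sum()),
                               "fraction_high": float(high.mean())}
    if 0 < high.sum() < len(high) and e_test[high].sum() + e_test[~high].sum() > 0:
        try:
            hr = stats.cox_univariable(t_test, e_test, high.astype(float),
                                       reference="low-risk")
            validation["high_risk"]["cox"] = _effect_to_dict(hr)
        except SirisurvError as exc:
            validation["high_risk"]["cox"] = {"error": str(exc)}
    report["validation"] = validation

    # --- financial-toxicity association (whole cohort, baseline) --------
    if "ft_level" in cohort.columns:
        levels = cohort["ft_level"].to_numpy(int)
        siri = cohort["siri"].to_numpy(float)
        trend = ft.jonckheere_test(siri, levels, alternative="two-sided")
        ft_group = pd.Series(categorize_ft(levels), index=cohort.index)
        reg_data = pd.DataFrame({
            "log2_siri": np.log2(siri),
            "ft_group": ft_group,
            "age_group": np.where(cohort["age"] > 60, ">60", "<=60"),
            "smoking": cohort["smoking"],
        })
        fit = ft.ols_regression(reg_data, "log2_siri",
                                categorical={"ft_group": FT_HIGH,
                                             "age_group": "<=60",
                                             "smoking": "never"})
        ft_low = fit.coefficient(FT_LOW)
        report["ft"] = {
            "jonckheere": {"statistic": trend.statistic, "p_value": trend.p_value},
            "ols_ft_low": {"beta": float(ft_low["beta"]),
                           "ci_lower": float(ft_low["ci_lower"]),
                           "ci_upper": float(ft_low["ci_upper"]),
                           "p_value": float(ft_low["p_value"])},
            "n": fit.n,
        }

    if outdir is not None:
        _write_artifacts(Path(outdir), config, cohort, cutoffsets, group_model, report)
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=float)


def _write_artifacts(outdir: Path, config: PipelineConfig, cohort: pd.DataFrame,
                     cutoffsets, group_model, report: dict) -> None:
    from . import plots

    outdir.mkdir(parents=True, exist_ok=True)
    synthetic.write_cohort(cohort, outdir / "cohort.csv")
    (outdir / "report.json").write_text(report_to_json(report))
    (outdir / "risk_groups.json").write_text(group_model.to_json())
    for cs in cutoffsets:
        (outdir / f"cutoffs_{cs.variable}.json").write_text(cs.to_json())
        if cs.split_density is not None:
            plots.plot_distillation(cs, outdir / f"cutoffs_{cs.variable}.png")
    plots.plot_km_groups(group_model.group_curves, outdir / "km_groups_train.png",
                         title="Risk groups (training set)")
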