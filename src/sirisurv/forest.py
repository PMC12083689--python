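"""Random survival forest: fitting, mortality scores, OOB evaluation,
permutation importance, discrimination metrics, and split-rule extraction.

The ensemble itself is scikit-survival's ``RandomSurvivalForest`` (log-rank
splitting, bootstrap resampling, Nelson–Aalen leaf estimates) exposed
behind a small cohort-aware surface.  The pieces that the downstream
cutoff-distillation pipeline needs from the forest — in-bag accounting,
out-of-bag concordance, permutation variable importance, and extraction of
every split threshold used for a given continuous predictor — are
implemented here.

The discrimination metrics (pairwise concordance index, IPCW
cumulative/dynamic AUC) are computed by direct sums over subject pairs so
that their definitions are explicit and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble._forest import _generate_sample_indices, _generate_unsampled_indices
from sklearn.model_selection import train_test_split
from sksurv.ensemble import RandomSurvivalForest
from sksurv.nonparametric import CensoringDistributionEstimator
from sksurv.tree import SurvivalTree as _SkSurvivalTree
from sksurv.util import Surv

from .errors import DomainError, InvalidConfigError, UndefinedResultError
from .synthetic import KPS_LEVELS, SMOKING_LEVELS

__all__ = [
    "ForestConfig",
    "SurvivalForest",
    "GrownTree",
    "fit_forest",
    "grow_survival_tree",
    "predict_mortality",
    "oob_mortality",
    "oob_concordance",
    "permutation_vimp",
    "concordance_index",
    "time_dependent_auc",
    "extract_split_thresholds",
    "encode_covariates",
    "split_cohort",
    "DEFAULT_MODEL_VARIABLES",
]

DEFAULT_MODEL_VARIABLES = ["siri", "kps_cat", "bmi", "smoking"]

# Ordinal codes for the clinical categories (both have a natural order).
CATEGORY_CODES: dict[str, dict[str, float]] = {
    "kps_cat": {lvl: code for lvl, code in zip(KPS_LEVELS, (100.0, 85.0, 70.0))},
    "smoking": {lvl: float(i) for i, lvl in enumerate(SMOKING_LEVELS)},
}


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``n_trees`` defaults to 1000; ``variables_per_split`` of ``None`` means
    ceil(sqrt(p)); ``min_terminal_size`` is the minimum number of subjects
    in a leaf.  Candidate thresholds at a node are the midpoints of the
    sorted unique in-node values, scanned exhaustively.
    """

    n_trees: int = 1000
    variables_per_split: int | None = None
    min_terminal_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InvalidConfigError("n_trees must be >= 1")
        if self.min_terminal_size < 1:
            raise InvalidConfigError("min_terminal_size must be >= 1")
        if self.variables_per_split is not None and self.variables_per_split < 1:
            raise InvalidConfigError("variables_per_split must be >= 1 or None")


def encode_covariates(df: pd.DataFrame, variables: list[str]) -> np.ndarray:
    """Encode the model variables as a float matrix.

    Numeric columns pass through; known clinical categories use their
    ordinal codes; any other string column is coded by sorted unique level.
    """
    cols = []
    for var in variables:
        if var not in df.columns:
            raise DomainError(f"missing model variable {var!r}")
        col = df[var]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            codes = CATEGORY_CODES.get(var)
            if codes is None:
                levels = sorted(col.astype(str).unique())
                codes = {lvl: float(i) for i, lvl in enumerate(levels)}
            mapped = col.astype(str).map(codes)
            if mapped.isna().any():
                bad = sorted(set(col.astype(str)) - set(codes))
                raise DomainError(f"unknown level(s) {bad} in variable {var!r}")
            cols.append(mapped.to_numpy(dtype=float))
    return np.column_stack(cols)


def _surv_y(times, events) -> np.ndarray:
    return Surv.from_arrays(event=np.asarray(events).astype(bool),
                            time=np.asarray(times, dtype=float))


@dataclass
class SurvivalForest:
    """A fitted forest plus everything needed for OOB work and distillation."""

    model: RandomSurvivalForest
    variables: list[str]
    config: ForestConfig
    X: np.ndarray
    times: np.ndarray
    events: np.ndarray
    _oob_sets: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def oob_indices(self) -> list[np.ndarray]:
        """Per-tree arrays of out-of-bag subject indices."""
        if not self._oob_sets:
            n = self.n_subjects
            self._oob_sets = [
                _generate_unsampled_indices(est.random_state, n, n, None)
                for est in self.model.estimators_
            ]
        return self._oob_sets

    def inbag_indices(self) -> list[np.ndarray]:
        n = self.n_subjects
        return [_generate_sample_indices(est.random_state, n, n, None)
                for est in self.model.estimators_]

    def tree_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-tree mortality scores (each tree's Nelson–Aalen CHF summed
        over its own event-time grid); their mean is the ensemble score."""
        out = np.empty((len(self.model.estimators_), X.shape[0]))
        Xf = np.asarray(X, dtype=np.float64)
        for k, est in enumerate(self.model.estimators_):
            out[k] = est.predict(Xf)
        return out


def fit_forest(cohort: pd.DataFrame, config: ForestConfig | None = None,
               variables: list[str] | None = None,
               time_col: str = "time_months", event_col: str = "event") -> SurvivalForest:
    """Fit the random survival forest on a cohort.

    Trees are grown on bootstrap resamples with log-rank splitting;
    out-of-bag membership is reproducible from the per-tree random states.
    """
    config = config or ForestConfig()
    variables = list(variables or DEFAULT_MODEL_VARIABLES)
    events = cohort[event_col].to_numpy(dtype=int)
    if events.sum() == 0:
        raise DomainError("cannot fit a survival forest on a cohort with no events")
    times = cohort[time_col].to_numpy(dtype=float)
    X = encode_covariates(cohort, variables)
    p = X.shape[1]
    max_features = config.variables_per_split or int(np.ceil(np.sqrt(p)))
    model = RandomSurvivalForest(
        n_estimators=config.n_trees,
        max_features=min(max_features, p),
        min_samples_leaf=config.min_terminal_size,
        n_jobs=1,
        random_state=config.seed,
        bootstrap=True,
    )
    model.fit(X, _surv_y(times, events))
    return SurvivalForest(model=model, variables=variables, config=config,
                          X=X, times=times, events=events)


@dataclass
class GrownTree:
    """A single survival tree (used for unit-level recovery checks)."""

    model: _SkSurvivalTree
    variables: list[str]

    def root_split(self) -> tuple[str, float] | None:
        t = self.model.tree_
        if t.feature[0] < 0:
            return None
        return self.variables[t.feature[0]], float(t.threshold[0])

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.model.tree_.children_left < 0))


def grow_survival_tree(cohort: pd.DataFrame, config: ForestConfig | None = None,
                       variables: list[str] | None = None, random_state: int = 0,
                       time_col: str = "time_months", event_col: str = "event") -> GrownTree:
    """Grow one log-rank-splitting survival tree (no bootstrap)."""
    config = config or ForestConfig()
    variables = list(variables or DEFAULT_MODEL_VARIABLES)
    if len(cohort) < 2:
        raise DomainError("need at least 2 subjects to grow a tree")
    X = encode_covariates(cohort, variables)
    tree = _SkSurvivalTree(min_samples_leaf=config.min_terminal_size,
                           random_state=random_state)
    tree.fit(X, _surv_y(cohort[time_col], cohort[event_col]))
    return GrownTree(model=tree, variables=variables)


def predict_mortality(forest: SurvivalForest, cohort: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Ensemble mortality score: the mean over trees of each tree's
    Nelson–Aalen cumulative hazard summed over its event-time grid — an
    estimate of the expected number of events.  Higher = higher risk."""
    if isinstance(cohort, pd.DataFrame):
        X = encode_covariates(cohort, forest.variables)
    else:
        X = np.asarray(cohort, dtype=float)
    return forest.model.predict(X)


def oob_mortality(forest: SurvivalForest, X: np.ndarray | None = None) -> np.ndarray:
    """Out-of-bag mortality score per training subject: the mean of the
    per-tree scores over the trees for which the subject is out-of-bag."""
    X = forest.X if X is None else X
    n = X.shape[0]
    total = np.zeros(n)
    count = np.zeros(n)
    Xf = np.asarray(X, dtype=np.float64)
    for est, oob in zip(forest.model.estimators_, forest.oob_indices()):
        if len(oob) == 0:
            continue
        total[oob] += est.predict(Xf[oob])
        count[oob] += 1
    if np.any(count == 0):
        # subjects in every bag keep the ensemble prediction as fallback
        missing = count == 0
        total[missing] = forest.model.predict(Xf[missing])
        count[missing] = 1
    return total / count


def oob_concordance(forest: SurvivalForest) -> float:
    """Honest C-index: OOB scores against the training outcomes."""
    return concordance_index(oob_mortality(forest), forest.times, forest.events)


def permutation_vimp(forest: SurvivalForest, seed: int = 0, n_repeats: int = 5
                     ) -> dict[str, float]:
    """Permutation variable importance.

    For each variable, its column is shuffled across subjects, out-of-bag
    scores are recomputed, and the VIMP is the mean drop in OOB C-index
    over ``n_repeats`` shuffles.  Noise variables hover near zero.
    """
    rng = np.random.default_rng(seed)
    base = oob_concordance(forest)
    vimp: dict[str, float] = {}
    for j, var in enumerate(forest.variables):
        drops = []
        for _ in range(n_repeats):
            Xp = forest.X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            c_perm = concordance_index(oob_mortality(forest, Xp), forest.times, forest.events)
            drops.append(base - c_perm)
        vimp[var] = float(np.mean(drops))
    return vimp


def concordance_index(scores, times, events) -> float:
    """Harrell's concordance index for right-censored data.

    Evaluable pairs are those orderable under censoring: the subject with
    the shorter observed time experienced the event, and the times differ.
    A pair is concordant when the shorter-lived subject has the higher
    score; score ties count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (len(s) == len(t) == len(e)):
        raise DomainError("scores, times and events must have equal length")
    evaluable = (t[:, None] < t[None, :]) & e[:, None]
    n_pairs = int(evaluable.sum())
    if n_pairs == 0:
        raise UndefinedResultError("no censoring-evaluable pair")
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    concordant = float(np.sum(evaluable & higher)) + 0.5 * float(np.sum(evaluable & tied))
    return concordant / n_pairs


def _censoring_weights(times, events, eval_times) -> np.ndarray:
    """IPCW weights 1/G(t) from the Kaplan–Meier censoring distribution."""
    cens = CensoringDistributionEstimator().fit(_surv_y(times, events))
    prob = cens.predict_proba(np.asarray(eval_times, dtype=float))
    if np.any(prob <= 0):
        raise UndefinedResultError("censoring survival reaches 0 before an event time")
    return 1.0 / prob


def time_dependent_auc(scores, times, events, horizon: float) -> float:
    """Cumulative/dynamic time-dependent AUC at one horizon (Uno's IPCW
    estimator).

    Cases are subjects with an event at or before the horizon, controls are
    subjects still under observation past it; case pairs are weighted by
    the inverse probability of remaining uncensored at their event time.
    Score ties count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    is_case = (t <= horizon) & e
    is_control = t > horizon
    if not is_case.any() or not is_control.any():
        raise UndefinedResultError("need at least one case and one control at the horizon")
    w = _censoring_weights(t, e, t[is_case])
    sc, sn = s[is_case], s[is_control]
    greater = (sc[:, None] > sn[None, :]).astype(float)
    tied = (sc[:, None] == sn[None, :]).astype(float)
    num = float(np.sum(w[:, None] * (greater + 0.5 * tied)))
    den = float(np.sum(w)) * len(sn)
    return num / den


def extract_split_thresholds(forest: SurvivalForest, variable: str
                             ) -> tuple[np.ndarray, np.ndarray]:
    """All split thresholds the forest used for one variable.

    Every internal node splitting on the variable contributes its threshold
    once, paired with the (in-bag weighted) node sample size.  Returns
    ``(thresholds, node_sizes)``; both empty when the forest never split on
    the variable.
    """
    if variable not in forest.variables:
        raise DomainError(f"{variable!r} is not a model variable of this forest")
    j = forest.variables.index(variable)
    thresholds: list[float] = []
    sizes: list[float] = []
    for est in forest.model.estimators_:
        t = est.tree_
        internal = t.children_left >= 0
        mask = internal & (t.feature == j)
        thresholds.extend(t.threshold[mask].tolist())
        sizes.extend(t.weighted_n_node_samples[mask].tolist())
    return np.asarray(thresholds, dtype=float), np.asarray(sizes, dtype=float)


def split_cohort(cohort: pd.DataFrame, test_size: float = 0.30, seed: int = 0,
                 event_col: str = "event") -> tuple[pd.DataFrame, pd.DataFrame]:
    """70/30 train/test split, stratified by the event indicator so small
    test sets keep a stable event fraction."""
    train, test = train_test_split(cohort, test_size=test_size, random_state=seed,
                                   stratify=cohort[event_col])
    return train.reset_index(drop=True), test.reset_index(drop=True)
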