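"""Classifier families, cross-validated model selection and the per-core
analysis machinery.

Four model families are supported — logistic regression with L1 or L2
regularisation, support vector machines and gradient-boosted decision
trees — each exposing a real-valued score where larger means more likely to
drop out.  Hyperparameters come from a grid search under stratified k-fold
cross-validation (default k=10) scored by AUC.  The per-core design re-runs
the whole transformation on data truncated at each user's core-c completion
date, so the eligible sample shrinks as the analysis moves through the
programme.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC

from .config import AnalysisConfig, CVSettings
from .features import apply_feature_catalog
from .metrics import (
    ScoredLabels,
    importance_summary,
    pr_auc,
    roc_auc,
    shapley_matrix,
)
from .missing import MissingnessPolicy, delete_by_missingness, impute
from .touchpoints import (
    TouchPointLog,
    UserFeatureTable,
    VariableSpec,
    aggregate_within_window,
    assign_windows,
    carry_forward,
    core_completion_dates,
    drop_constant_categoricals,
    user_level_aggregate,
)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("logreg_l1", "logreg_l2", "svm", "gbt")

#: shipped hyperparameter grids (the study reports grid search without
#: printing its grids; these are conventional ranges)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logreg_l1": {"C": [0.01, 0.03, 0.1, 0.3, 1.0, 10.0]},
    "logreg_l2": {"C": [0.01, 0.03, 0.1, 0.3, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["linear", "rbf"]},
    "gbt": {
        "n_estimators": [100, 300, 500],
        "max_depth": [2, 3, 4],
        "learning_rate": [0.05, 0.1],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus either fixed hyperparameters or a search grid."""

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)
    grid: Any = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


def expand_grid(grid) -> list[dict[str, Any]]:
    """dict-of-lists -> ordered list of hyperparameter settings."""
    if grid is None:
        return [{}]
    if isinstance(grid, Mapping):
        keys = list(grid)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    return [dict(g) for g in grid]


def build_estimator(kind: str, params: Mapping[str, Any], table: UserFeatureTable,
                    seed: int = 0) -> Pipeline:
    """Leak-free sklearn pipeline for one model family.

    Numeric features are standardised inside the pipeline for the margin
    based learners (logistic regression, SVM) and passed through for trees;
    categoricals are one-hot encoded with the encoder fit on training folds
    only.
    """
    num_cols = table.numeric_columns()
    cat_cols = table.categorical_columns()
    if kind in ("logreg_l1", "logreg_l2", "svm"):
        num_tf = StandardScaler()
    else:
        num_tf = "passthrough"
    pre = ColumnTransformer(
        [
            ("num", num_tf, num_cols),
            # min_frequency folds rare levels (e.g. near-unique clock strings)
            # into one bucket instead of exploding the design matrix
            ("cat", OneHotEncoder(handle_unknown="infrequent_if_exist", sparse_output=False,
                                  min_frequency=0.05), cat_cols),
        ],
        remainder="drop",
    )
    p = dict(params)
    if kind == "logreg_l1":
        est = LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000,
                                 random_state=seed, **p)
    elif kind == "logreg_l2":
        est = LogisticRegression(l1_ratio=0.0, solver="lbfgs", max_iter=2000, **p)
    elif kind == "svm":
        est = SVC(random_state=seed, **p)
    elif kind == "gbt":
        est = GradientBoostingClassifier(random_state=seed, **p)
    else:
        raise ValueError(kind)
    return Pipeline([("pre", pre), ("clf", est)])


def decision_scores(model: Pipeline, X: pd.DataFrame) -> np.ndarray:
    """Dropout score: P(dropout) for probabilistic models, the raw
    decision-function margin for SVMs (AUC is rank-based, so calibration
    is unnecessary)."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class CVResult:
    """Out-of-fold evaluation of one hyperparameter setting."""

    fold_aucs: list[float]
    oof_scores: pd.Series
    fold_of_row: pd.Series
    models: list[Pipeline]

    @property
    def mean_auc(self) -> float:
        defined = [a for a in self.fold_aucs if not np.isnan(a)]
        return float(np.mean(defined)) if defined else float("nan")


def fit_predict_cv(
    spec: ModelSpec,
    table: UserFeatureTable,
    cv: CVSettings,
) -> CVResult:
    """Stratified k-fold cross-validation with pooled out-of-fold scores.

    Every row is scored exactly once by the model that did not train on it.
    A validation fold containing a single class has undefined AUC; it is
    recorded as NaN with a warning and the mean is taken over defined
    folds.
    """
    if table.y is None:
        raise ValueError("table carries no outcome labels")
    X, y = table.data, table.y
    if X.isna().any().any():
        raise ValueError("imputation must run before model fitting")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need both classes to cross-validate")
    if len(X) < cv.k_folds:
        raise ValueError(f"n={len(X)} smaller than k_folds={cv.k_folds}")

    splitter = StratifiedKFold(n_splits=cv.k_folds, shuffle=True, random_state=cv.seed)
    splits = splitter.split(X, y) if cv.stratified else None
    if not cv.stratified:
        from sklearn.model_selection import KFold

        splits = KFold(n_splits=cv.k_folds, shuffle=True, random_state=cv.seed).split(X)

    oof = pd.Series(np.nan, index=X.index, dtype=float)
    fold_of_row = pd.Series(-1, index=X.index, dtype=int)
    fold_aucs: list[float] = []
    models: list[Pipeline] = []
    for fold, (tr, va) in enumerate(splits):
        model = build_estimator(spec.kind, spec.params, table, seed=cv.seed)
        model.fit(X.iloc[tr], y.iloc[tr])
        s = decision_scores(model, X.iloc[va])
        oof.iloc[va] = s
        fold_of_row.iloc[va] = fold
        yv = y.iloc[va].to_numpy()
        if len(np.unique(yv)) < 2:
            logger.warning("fold %d has a single class; AUC undefined", fold)
            fold_aucs.append(float("nan"))
        else:
            auc, _ = roc_auc(ScoredLabels(s, yv))
            fold_aucs.append(auc)
        models.append(model)
    return CVResult(fold_aucs, oof, fold_of_row, models)


def grid_search(
    kind: str,
    grid,
    table: UserFeatureTable,
    cv: CVSettings,
) -> tuple[dict[str, Any], float, pd.DataFrame]:
    """Pick the hyperparameters maximising mean CV AUC.

    Candidates are evaluated in grid order; ties keep the first candidate,
    making selection deterministic.  Returns the winner, its mean AUC and a
    per-candidate results frame.
    """
    candidates = expand_grid(grid if grid is not None else DEFAULT_GRIDS.get(kind))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    best_params, best_auc = None, -np.inf
    rows = []
    for params in candidates:
        res = fit_predict_cv(ModelSpec(kind, params), table, cv)
        rows.append({**params, "mean_auc": res.mean_auc})
        if res.mean_auc > best_auc:  # strict: first of ties wins
            best_params, best_auc = params, res.mean_auc
    return best_params, float(best_auc), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-core analyses


def build_variable_specs(log: TouchPointLog, config: AnalysisConfig) -> dict[str, VariableSpec]:
    """Per-variable specs: defaults plus LOCF flags from the config."""
    from .touchpoints import default_spec

    specs = {}
    for name, vt in log.value_types.items():
        s = default_spec(name, vt)
        if name in config.carry_forward:
            s = VariableSpec(name, vt, s.within_window_agg, s.user_agg, carry_forward=True)
        specs[name] = s
    return specs


def build_core_table(
    log: TouchPointLog,
    labels: Mapping,
    config: AnalysisConfig,
    core: int,
    completion: pd.DataFrame | None = None,
) -> UserFeatureTable:
    """Full transformation for one core analysis, *before* missingness
    deletion and imputation.

    Touchpoints are truncated at each eligible user's core completion date,
    windowed and aggregated, questionnaires carried forward, single-level
    categoricals removed, users collapsed to one row, and the theory-driven
    catalog joined on (computed from the truncated log, so it respects the
    cutoff)."""
    if completion is None:
        completion = core_completion_dates(log, config.n_cores)
    done = completion[core].dropna()
    flog = log.restrict_to_dates(done.to_dict())
    wlog = assign_windows(flog, config.window_days, config.origin)
    specs = build_variable_specs(wlog, config)
    jt = aggregate_within_window(wlog, specs)
    jt = carry_forward(jt)
    jt, _removed = drop_constant_categoricals(jt)
    uft = user_level_aggregate(jt, labels=labels, core_cutoff=core,
                               completion_dates=completion)
    uft, _prov = apply_feature_catalog(uft, flog, n_cores=config.n_cores)
    return uft


def finalize_table(
    uft: UserFeatureTable, policy: MissingnessPolicy
) -> tuple[UserFeatureTable, pd.DataFrame]:
    """Missingness deletion + imputation; all-missing columns (which no
    imputer can fill) are dropped first, protected or not, with a log line."""
    all_missing = [c for c in uft.data.columns if uft.data[c].isna().all()]
    if all_missing:
        logger.info("dropping %d all-missing column(s): %s", len(all_missing), all_missing[:8])
        uft = UserFeatureTable(
            uft.data.drop(columns=all_missing),
            {k: v for k, v in uft.value_types.items() if k not in all_missing},
            uft.y, uft.core_cutoff, set(uft.protected) - set(all_missing),
        )
    reduced, report = delete_by_missingness(uft, policy)
    return impute(reduced, policy), report


@dataclass
class CoreAnalysis:
    """Everything one per-core analysis produces."""

    core: int
    n: int
    n_features: int
    best_params: dict[str, Any]
    fold_aucs: list[float]
    auc: float
    prauc: float
    prevalence: float
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    oof_scores: pd.Series
    phi: pd.DataFrame | None
    ranking: pd.DataFrame | None
    deletion_report: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "core": self.core,
            "n": self.n,
            "n_features": self.n_features,
            "best_params": self.best_params,
            "fold_aucs": [None if np.isnan(a) else a for a in self.fold_aucs],
            "auc": self.auc,
            "prauc": self.prauc,
            "prevalence": self.prevalence,
            "top_features": self.ranking["feature"].tolist() if self.ranking is not None else [],
        }


def _explain_out_of_fold(
    cvres: CVResult,
    table: UserFeatureTable,
    config: AnalysisConfig,
) -> pd.DataFrame | None:
    """Shapley-explain a sample of rows, each with the model that held it
    out, using that fold's training rows as background."""
    att = config.attribution
    X = table.data
    cat_cols = table.categorical_columns()
    if cat_cols:
        # attribution operates on the numeric design; categoricals are rare
        # in the shipped pipeline (events and diaries are numeric)
        X = X.drop(columns=cat_cols)
        if X.shape[1] == 0:
            return None
    rng = np.random.default_rng(config.seed + 211)
    idx = np.arange(len(X))
    if len(idx) > att.n_explain:
        idx = np.sort(rng.choice(idx, size=att.n_explain, replace=False))
    parts = []
    for fold, model in enumerate(cvres.models):
        rows = [i for i in idx if cvres.fold_of_row.iloc[i] == fold]
        if not rows:
            continue
        train_mask = (cvres.fold_of_row != fold).to_numpy()
        bg = X.loc[train_mask]
        if len(bg) > att.background:
            bg = bg.iloc[np.sort(rng.choice(len(bg), size=att.background, replace=False))]

        def predict(mat: np.ndarray, _m=model) -> np.ndarray:
            frame = pd.DataFrame(mat, columns=X.columns)
            for c in cat_cols:
                frame[c] = table.data[c].iloc[0]
            return decision_scores(_m, frame[table.data.columns])

        parts.append(
            shapley_matrix(predict, X.iloc[rows], bg, mode=att.mode,
                           draws=att.draws, seed=config.seed + 97 + fold)
        )
    if not parts:
        return None
    return pd.concat(parts).sort_index()


def analyze_core(
    table: UserFeatureTable,
    config: AnalysisConfig,
    model_kind: str | None = None,
    grid=None,
    explain: bool = True,
) -> CoreAnalysis:
    """Grid search + CV + pooled-out-of-fold evaluation + attribution for
    one finalized (imputed) core table."""
    kind = model_kind or config.model_kind
    if config.model_params is not None and grid is None and config.model_grid is None:
        best_params, _, _ = dict(config.model_params), float("nan"), None
    else:
        best_params, _, _search = grid_search(
            kind, grid if grid is not None else config.model_grid, table, config.cv
        )
    cvres = fit_predict_cv(ModelSpec(kind, best_params), table, config.cv)
    sl = ScoredLabels(cvres.oof_scores.to_numpy(), table.y.to_numpy())
    auc, roc_points = roc_auc(sl)
    prauc, prevalence, pr_points = pr_auc(sl)

    phi = ranking = None
    if explain:
        phi = _explain_out_of_fold(cvres, table, config)
        if phi is not None:
            ranking, _dep = importance_summary(
                phi, table.data.loc[phi.index, phi.columns], top_k=config.attribution.top_k
            )
    return CoreAnalysis(
        core=table.core_cutoff if table.core_cutoff is not None else -1,
        n=len(table.data),
        n_features=table.data.shape[1],
        best_params=best_params,
        fold_aucs=cvres.fold_aucs,
        auc=auc,
        prauc=prauc,
        prevalence=prevalence,
        roc_points=roc_points,
        pr_points=pr_points,
        oof_scores=cvres.oof_scores,
        phi=phi,
        ranking=ranking,
    )


def run_core_analyses(
    log: TouchPointLog,
    labels: Mapping,
    config: AnalysisConfig,
    cores: Sequence[int] | None = None,
    explain: bool = True,
) -> dict[int, CoreAnalysis]:
    """Separate analyses after the completion of each core.

    For a C-core programme, cores 0..C-2 are analysed (the outcome is
    completion of the final core); each analysis truncates every user's
    data at their core-c completion date, rebuilds all features, applies
    the missingness policy inside the analysis (no leakage across
    cutoffs), and evaluates by stratified CV.  Cores with fewer eligible
    users than folds, or a single outcome class, are skipped with a
    warning.
    """
    completion = core_completion_dates(log, config.n_cores)
    if cores is None:
        cores = range(config.n_cores - 1)
    policy = config.missingness_policy()
    out: dict[int, CoreAnalysis] = {}
    for c in cores:
        uft = build_core_table(log, labels, config, c, completion)
        if len(uft.data) < config.cv.k_folds:
            logger.warning("core %d: only %d eligible users (< %d folds); skipped",
                           c, len(uft.data), config.cv.k_folds)
            continue
        if uft.y.nunique() < 2:
            logger.warning("core %d: single outcome class; skipped", c)
            continue
        table, report = finalize_table(uft, policy)
        res = analyze_core(table, config, explain=explain)
        res.deletion_report = report
        out[c] = res
    return out


@dataclass
class GridCell:
    """One cell of the model x imputation x threshold configuration grid."""

    model_kind: str
    imputation: str
    threshold: float
    mean_auc: float
    per_core_auc: dict[int, float]


def config_grid(
    log: TouchPointLog,
    labels: Mapping,
    config: AnalysisConfig,
    models: Sequence[str] | None = None,
    imputations: Sequence[str] | None = None,
    thresholds: Sequence[float] | None = None,
    cores: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, GridCell]:
    """Mean AUC across core analyses for every configuration cell.

    The transformation is computed once per core and shared across cells;
    deletion + imputation and the model fit are re-run per cell.  Returns
    the full cell frame and the best cell (argmax mean AUC, first of
    ties).
    """
    models = list(models if models is not None else config.grid_models)
    imputations = list(imputations if imputations is not None else config.grid_imputations)
    thresholds = list(thresholds if thresholds is not None else config.grid_thresholds)
    if not (models and imputations and thresholds):
        raise ValueError("grid axes must be non-empty")
    completion = core_completion_dates(log, config.n_cores)
    if cores is None:
        cores = range(config.n_cores - 1)

    base: dict[int, UserFeatureTable] = {}
    for c in cores:
        uft = build_core_table(log, labels, config, c, completion)
        if len(uft.data) >= config.cv.k_folds and uft.y.nunique() >= 2:
            base[c] = uft

    cells: list[GridCell] = []
    for kind, imp, tau in itertools.product(models, imputations, thresholds):
        policy = MissingnessPolicy(threshold=tau, imputation=imp, knn_k=config.knn_k)
        per_core: dict[int, float] = {}
        for c, uft in base.items():
            table, _ = finalize_table(uft, policy)
            res = analyze_core(table, config, model_kind=kind, explain=False)
            per_core[c] = res.auc
        mean_auc = float(np.mean(list(per_core.values()))) if per_core else float("nan")
        cells.append(GridCell(kind, imp, tau, mean_auc, per_core))

    frame = pd.DataFrame(
        [
            {"model": c.model_kind, "imputation": c.imputation,
             "threshold": c.threshold, "mean_auc": c.mean_auc}
            for c in cells
        ]
    )
    best = max(cells, key=lambda c: (np.nan_to_num(c.mean_auc, nan=-np.inf)))
    return frame, best
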