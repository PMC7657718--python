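"""Analysis configuration: one object (and one YAML file) controlling the
whole pipeline — time window, variable handling, missingness policy, model
grid, cross-validation and attribution settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

from .missing import MissingnessPolicy


@dataclass
class CVSettings:
    """Cross-validation: stratified k-fold (default k=10), AUC scoring."""

    k_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class AttributionSettings:
    """Shapley attribution applied to out-of-fold instances.

    ``n_explain`` caps how many instances are explained per core analysis;
    ``draws`` is the permutation-sampling budget per instance;
    ``background`` caps the background-sample size; ``top_k`` features are
    reported (5, matching the per-core importance summaries)."""

    n_explain: int = 50
    draws: int = 60
    background: int = 100
    top_k: int = 5
    mode: str = "sampled"


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs beyond the data itself."""

    window_days: int = 1
    origin: str = "per_user_first"
    n_cores: int = 7
    #: variables given last-observation-carried-forward treatment
    #: (questionnaires administered before each core)
    carry_forward: list[str] = field(default_factory=list)
    threshold: float = 0.15
    imputation: str = "knn"
    knn_k: int = 5
    model_kind: str = "gbt"
    model_params: dict[str, Any] | None = None
    model_grid: Any = None  # dict-of-lists or list-of-dicts; None -> shipped default
    cv: CVSettings = field(default_factory=CVSettings)
    attribution: AttributionSettings = field(default_factory=AttributionSettings)
    #: config-grid axes (model kinds x imputations x thresholds)
    grid_models: list[str] = field(
        default_factory=lambda: ["logreg_l1", "logreg_l2", "svm", "gbt"]
    )
    grid_imputations: list[str] = field(default_factory=lambda: ["median_mode", "knn"])
    grid_thresholds: list[float] = field(default_factory=lambda: [0.05, 0.10, 0.15, 0.20])
    task: str = "classification"  # the regression branch is reserved, not implemented
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task != "classification":
            raise NotImplementedError("only the classification task is implemented")

    def missingness_policy(self, threshold: float | None = None,
                           imputation: str | None = None) -> MissingnessPolicy:
        return MissingnessPolicy(
            threshold=self.threshold if threshold is None else threshold,
            imputation=self.imputation if imputation is None else imputation,
            knn_k=self.knn_k,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "cv" in d and isinstance(d["cv"], Mapping):
            d["cv"] = CVSettings(**d["cv"])
        if "attribution" in d and isinstance(d["attribution"], Mapping):
            d["attribution"] = AttributionSettings(**d["attribution"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
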