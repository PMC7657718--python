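"""Model/Results facade over the per-core dropout analyses.

`DropoutModel` binds a touchpoint log, dropout labels and an analysis
configuration; `fit()` runs the per-core analyses (transformation, feature
catalog, missingness policy, grid search, stratified CV, attribution) and
returns a `DropoutResults` carrying the estimates and diagnostics with a
`summary()` table.  `fit_grid()` evaluates the full model x imputation x
threshold configuration grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .modeling import CoreAnalysis, GridCell, config_grid, run_core_analyses
from .touchpoints import TouchPointLog, parse_touchpoints


class DropoutModel:
    """Dropout prediction over a user-journey touchpoint log.

    Parameters
    ----------
    log : TouchPointLog
        Validated long-format log (see :func:`parse_touchpoints`).
    labels : mapping user_id -> {0, 1}
        1 = dropped out (did not complete the final core), the positive
        class.
    config : AnalysisConfig, optional
        Pipeline settings; defaults reproduce the shipped study design
        (daily windows, 15% missingness threshold, KNN k=5 imputation,
        boosted trees, stratified 10-fold CV).
    """

    def __init__(self, log: TouchPointLog, labels: Mapping, config: AnalysisConfig | None = None):
        self.log = log
        self.labels = pd.Series(labels)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, log_path, labels_path, config: AnalysisConfig | None = None) -> "DropoutModel":
        """Build from a long-format log CSV and a ``user_id,dropout`` CSV."""
        log = parse_touchpoints(log_path)
        lab = pd.read_csv(labels_path).set_index("user_id")["dropout"]
        return cls(log, lab, config)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, labels: Mapping,
                   config: AnalysisConfig | None = None) -> "DropoutModel":
        """Build from an in-memory long-format DataFrame."""
        return cls(parse_touchpoints(frame), labels, config)

    def fit(self, cores: Sequence[int] | None = None, explain: bool = True) -> "DropoutResults":
        """Run the per-core analyses under the bound configuration."""
        analyses = run_core_analyses(self.log, self.labels, self.config,
                                     cores=cores, explain=explain)
        return DropoutResults(model=self, analyses=analyses)

    def fit_grid(self, cores: Sequence[int] | None = None, **axes) -> "DropoutResults":
        """Evaluate the configuration grid (models x imputations x
        thresholds); per-core analyses are then run under the best cell."""
        frame, best = config_grid(self.log, self.labels, self.config, cores=cores, **axes)
        cfg = AnalysisConfig.from_dict({
            **self.config.to_dict(),
            "model_kind": best.model_kind,
            "imputation": best.imputation,
            "threshold": best.threshold,
        })
        analyses = run_core_analyses(self.log, self.labels, cfg, cores=cores)
        return DropoutResults(model=self, analyses=analyses, grid=frame, best_cell=best)


@dataclass
class DropoutResults:
    """Fitted per-core dropout analyses.

    ``analyses`` maps core index -> :class:`CoreAnalysis` (eligible N,
    chosen hyperparameters, per-fold and pooled AUC, PRAUC with its
    prevalence baseline, ROC/PR point lists, Shapley attributions and the
    top-feature ranking).  ``grid``/``best_cell`` are present after
    :meth:`DropoutModel.fit_grid`.
    """

    model: DropoutModel
    analyses: dict[int, CoreAnalysis]
    grid: pd.DataFrame | None = None
    best_cell: GridCell | None = None

    @property
    def cores(self) -> list[int]:
        return sorted(self.analyses)

    @property
    def eligible_n(self) -> pd.Series:
        return pd.Series({c: a.n for c, a in sorted(self.analyses.items())}, name="n")

    @property
    def aucs(self) -> pd.Series:
        return pd.Series({c: a.auc for c, a in sorted(self.analyses.items())}, name="auc")

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def mean_prauc(self) -> float:
        return float(np.mean([a.prauc for a in self.analyses.values()]))

    @property
    def mean_prevalence(self) -> float:
        return float(np.mean([a.prevalence for a in self.analyses.values()]))

    def summary(self) -> str:
        """Human-readable per-core table plus grid winner, if any."""
        lines = ["Dropout prediction - per-core analyses",
                 "=" * 54,
                 f"{'core':>4} {'n':>5} {'features':>8} {'AUC':>7} {'PRAUC':>7} {'chance':>7}"]
        for c in self.cores:
            a = self.analyses[c]
            lines.append(
                f"{c:>4} {a.n:>5} {a.n_features:>8} {a.auc:>7.3f} {a.prauc:>7.3f} "
                f"{a.prevalence:>7.3f}"
            )
        lines.append("-" * 54)
        lines.append(
            f"mean AUC {self.mean_auc:.3f} | mean PRAUC {self.mean_prauc:.3f} "
            f"(chance {self.mean_prevalence:.3f})"
        )
        if self.best_cell is not None:
            b = self.best_cell
            lines.append(
                f"best grid cell: {b.model_kind}, {b.imputation} imputation, "
                f"threshold {b.threshold:.2f} (mean AUC {b.mean_auc:.3f})"
            )
        for c in self.cores:
            a = self.analyses[c]
            if a.ranking is not None and len(a.ranking):
                top = ", ".join(a.ranking["feature"].tolist())
                lines.append(f"core {c} top features: {top}")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serialisable run report."""
        rep = {
            "schema_version": 1,
            "config": self.model.config.to_dict(),
            "per_core": {str(c): self.analyses[c].to_dict() for c in self.cores},
            "mean_auc": self.mean_auc,
            "mean_prauc": self.mean_prauc,
            "mean_prevalence": self.mean_prevalence,
        }
        if self.grid is not None:
            rep["grid"] = self.grid.to_dict(orient="records")
        if self.best_cell is not None:
            rep["best_cell"] = {
                "model": self.best_cell.model_kind,
                "imputation": self.best_cell.imputation,
                "threshold": self.best_cell.threshold,
                "mean_auc": self.best_cell.mean_auc,
            }
        return rep

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2, default=float)
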