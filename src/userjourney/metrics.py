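"""Classifier evaluation (ROC/AUC, precision-recall) and Shapley-value
feature attribution.

AUC is the Mann-Whitney pair statistic (probability that a random dropout
scores above a random completer, half credit for ties).  PRAUC follows the
average-precision step-curve formulation and is reported with its chance
baseline, the positive-class prevalence.  Shapley values are interventional
(absent features replaced by background-sample values): an exact mode
enumerates all 2^m coalitions for small m, a sampled mode averages marginal
contributions over random feature orderings.  Both satisfy local accuracy:
the attributions plus the base value sum to the model score of the
explained instance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ScoredLabels:
    """Model scores paired with binary labels (dropout=1 is positive)."""

    score: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        if self.score.shape != self.label.shape:
            raise ValueError("score and label lengths differ")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("labels must be 0/1")


def roc_auc(sl: ScoredLabels) -> tuple[float, pd.DataFrame]:
    """Area under the ROC curve plus the curve's (fpr, tpr) point list.

    Computed as the Mann-Whitney statistic on score ranks with half credit
    for ties; the point list steps through the distinct score thresholds
    from (0, 0) to (1, 1).  Raises if only one class is present.
    """
    y, s = sl.label, sl.score
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)  # average ranks give tie half-credit
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    distinct = np.r_[np.nonzero(np.diff(ss))[0], len(ss) - 1]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(1 - ys)[distinct]
    points = pd.DataFrame({
        "fpr": np.r_[0.0, fp / n_neg],
        "tpr": np.r_[0.0, tp / n_pos],
        "threshold": np.r_[np.inf, ss[distinct]],
    })
    return float(auc), points


def pr_auc(sl: ScoredLabels) -> tuple[float, float, pd.DataFrame]:
    """Average-precision PRAUC, its chance baseline, and the PR points.

    The chance baseline of an uninformative scorer equals the positive
    prevalence, the reference line drawn under precision-recall curves.
    Ties are handled by treating each distinct score as one threshold.
    Raises with zero positives.
    """
    y, s = sl.label, sl.score
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PRAUC requires at least one positive")
    prevalence = n_pos / len(y)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    distinct = np.r_[np.nonzero(np.diff(ss))[0], len(ss) - 1]
    tp = np.cumsum(ys)[distinct]
    n_at = distinct + 1.0
    precision = tp / n_at
    recall = tp / n_pos
    # average precision: sum of precision increments over recall steps
    ap = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    points = pd.DataFrame({
        "recall": np.r_[0.0, recall],
        "precision": np.r_[1.0, precision],
        "threshold": np.r_[np.inf, ss[distinct]],
    })
    return ap, float(prevalence), points


# ---------------------------------------------------------------------------
# Shapley attribution

EXACT_MAX_FEATURES = 12


@dataclass
class AttributionResult:
    """Per-feature Shapley values for one prediction.

    ``phi`` is in model-score units; positive values push the score toward
    the positive (dropout) class.  Local accuracy holds:
    ``sum(phi) + base_value == score of the instance`` (exactly in exact
    mode, to Monte-Carlo tolerance of the base estimate in sampled mode).
    """

    phi: pd.Series
    base_value: float
    feature_values: pd.Series
    mode: str

    @property
    def score(self) -> float:
        return float(self.phi.sum() + self.base_value)


def _as_matrix(x, names) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(), list(x.columns)
    arr = np.asarray(x, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(arr.shape[-1])]
    return arr, list(names)


def shapley_values(
    predict: Callable[[np.ndarray], np.ndarray],
    instance,
    background,
    mode: str = "auto",
    draws: int = 2000,
    seed: int | None = None,
    feature_names: Sequence[str] | None = None,
) -> AttributionResult:
    """Interventional Shapley attribution of one model prediction.

    phi_i is the average change in the model score when feature i's value
    is introduced on top of a coalition of already-introduced features,
    with absent features replaced by values from ``background`` rows.

    ``mode='exact'`` enumerates all 2^m coalitions (m <= 12) and averages
    over every background row; ``mode='sampled'`` averages marginal
    contributions over ``draws`` random orderings, one background row per
    draw.  ``'auto'`` picks exact when feasible.
    """
    bg, names = _as_matrix(background, feature_names)
    if bg.ndim != 2 or len(bg) == 0:
        raise ValueError("background must be a non-empty 2-D sample")
    x = np.asarray(instance, dtype=float).reshape(-1)
    m = len(x)
    if bg.shape[1] != m:
        raise ValueError("instance and background dimensions differ")
    if mode == "auto":
        mode = "exact" if m <= EXACT_MAX_FEATURES else "sampled"

    if mode == "exact":
        if m > EXACT_MAX_FEATURES:
            raise ValueError(f"exact mode limited to {EXACT_MAX_FEATURES} features")
        # value of each coalition = mean model score with coalition features
        # from the instance and the rest from each background row
        n_masks = 1 << m
        vals = np.empty(n_masks)
        rows = np.empty((len(bg), m))
        for mask in range(n_masks):
            rows[:] = bg
            for i in range(m):
                if mask >> i & 1:
                    rows[:, i] = x[i]
            vals[mask] = float(np.mean(predict(rows)))
        phi = np.zeros(m)
        fact = [factorial(i) for i in range(m + 1)]
        for mask in range(n_masks):
            size = bin(mask).count("1")
            w = fact[size] * fact[m - size - 1] / fact[m]
            for i in range(m):
                if not mask >> i & 1:
                    phi[i] += w * (vals[mask | (1 << i)] - vals[mask])
        base = vals[0]
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(m) for _ in range(draws)])
        bg_rows = bg[rng.integers(len(bg), size=draws)]
        # build, per draw, the m+1 hybrid rows along the feature ordering
        hybrids = np.repeat(bg_rows[:, None, :], m + 1, axis=1)
        for t in range(1, m + 1):
            intro = perms[:, :t]
            for d in range(draws):
                hybrids[d, t:, intro[d, t - 1]] = x[intro[d, t - 1]]
        flat = hybrids.reshape(draws * (m + 1), m)
        scores = np.asarray(predict(flat), dtype=float).reshape(draws, m + 1)
        deltas = np.diff(scores, axis=1)  # draws x m, in ordering position
        phi = np.zeros(m)
        for i in range(m):
            pos = np.argmax(perms == i, axis=1)
            phi[i] = deltas[np.arange(draws), pos].mean()
        base = float(scores[:, 0].mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return AttributionResult(
        phi=pd.Series(phi, index=names),
        base_value=float(base),
        feature_values=pd.Series(x, index=names),
        mode=mode,
    )


def shapley_matrix(
    predict: Callable[[np.ndarray], np.ndarray],
    X,
    background,
    mode: str = "sampled",
    draws: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Explain many instances; returns an instances x features phi matrix."""
    Xm, names = _as_matrix(X, None)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xm))
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(Xm))
    for i in range(len(Xm)):
        res = shapley_values(
            predict, Xm[i], background, mode=mode, draws=draws,
            seed=int(children[i].generate_state(1)[0] % (2**31)), feature_names=names,
        )
        rows.append(res.phi)
    return pd.DataFrame(rows, index=index)


def importance_summary(
    phi: pd.DataFrame,
    X: pd.DataFrame | None = None,
    top_k: int = 5,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Rank features by mean |phi| and export dependence pairs.

    Returns the top-k ranking (feature, mean |phi|, mean phi) and, when
    feature values are supplied, a map feature -> (value, phi) pairs for
    dependence plots, the reading used to interpret per-core analyses.
    """
    mean_abs = phi.abs().mean().sort_values(ascending=False, kind="stable")
    ranking = pd.DataFrame({
        "feature": mean_abs.index[:top_k],
        "mean_abs_phi": mean_abs.to_numpy()[:top_k],
        "mean_phi": phi.mean().reindex(mean_abs.index[:top_k]).to_numpy(),
    }).reset_index(drop=True)
    dependence: dict[str, pd.DataFrame] = {}
    if X is not None:
        for f in ranking["feature"]:
            dependence[f] = pd.DataFrame({
                "value": X[f].to_numpy(),
                "phi": phi[f].to_numpy(),
            })
    return ranking, dependence
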