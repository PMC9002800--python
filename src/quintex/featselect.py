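"""Feature ranking and selection: DPS, RFE and tree-importance ranking.

DPS (dominant pattern set) is a filter on accumulated histogram counts: sum
the training histograms bin-wise, sort bins by mass, and keep the smallest
prefix covering n% of all counts.  RFE recursively drops the feature with
the smallest linear-SVM coefficient magnitude; FIR ranks by random-forest
impurity importance.  A top-N sweep evaluates cross-validated accuracy as a
function of the number of leading features and returns the best N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SelectionRanking",
    "SweepResult",
    "dps_select",
    "rfe_rank",
    "fir_rank",
    "top_n_sweep",
]


@dataclass
class SelectionRanking:
    """Feature names ordered best-first with their scores and method tag."""

    names: list[str]
    scores: np.ndarray
    method: str
    n_selected: int | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.names) != self.scores.size:
            raise ValueError("names and scores must align")

    def top(self, n: int) -> list[str]:
        return self.names[:n]


@dataclass
class SweepResult:
    ns: list[int]
    accuracies: list[float]
    best_n: int


def _ordered(names: Sequence[str], scores: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Stable descending sort by (score, name asc) for deterministic ties."""
    order = sorted(range(len(names)), key=lambda i: (-scores[i], names[i]))
    return [names[i] for i in order], scores[order]


def dps_select(
    hists: Sequence, n_percent: float = 95.0
) -> SelectionRanking:
    """Dominant pattern set over raw-count histogram vectors.

    ``hists`` is an iterable of FeatureVector-like objects (or arrays) whose
    entries are counts; for mixed histogram/K-spectrum vectors absolute
    values are accumulated, since K-deviations can be negative.  The ranking
    is the descending bin order; ``n_selected`` is the minimal M whose
    cumulative share reaches ``n_percent``.
    """
    if not 0 < n_percent < 100:
        raise ValueError("n_percent must be in (0, 100)")
    total = None
    names = None
    for fv in hists:
        values = np.abs(np.asarray(getattr(fv, "values", fv), dtype=np.float64))
        if total is None:
            total = values.copy()
            names = list(getattr(fv, "names", [f"f{i}" for i in range(values.size)]))
        else:
            total = total + values
    if total is None or total.sum() <= 0:
        raise ValueError("histogram accumulation is empty or all-zero")
    names_sorted, scores_sorted = _ordered(names, total)
    share = np.cumsum(scores_sorted) / scores_sorted.sum()
    m = int(np.searchsorted(share, n_percent / 100.0) + 1)
    m = min(m, int((scores_sorted > 0).sum()))
    return SelectionRanking(names=names_sorted, scores=scores_sorted, method="DPS", n_selected=m)


def _drop_constant(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)")
    return X[:, keep], [n for n, k in zip(names, keep) if k]


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    C: float = 1.0,
    large_step_fraction: float = 0.05,
    small_step_threshold: int = 200,
) -> SelectionRanking:
    """Recursive feature elimination with a linear-margin SVM.

    While more than ``small_step_threshold`` features remain, 5% are dropped
    per iteration; below that, one at a time.  Importance is the summed
    squared coefficient across the one-vs-one binary machines.  Rank 1 is
    the feature retained longest.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < len(np.unique(y)):
        raise ValueError("fewer samples than classes")
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    names = list(names)
    X = StandardScaler().fit_transform(X)
    X, names = _drop_constant(X, names)
    remaining = list(range(len(names)))
    eliminated: list[int] = []
    while len(remaining) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, remaining], y)
        importance = (clf.coef_**2).sum(axis=0)
        step = (
            1
            if len(remaining) <= small_step_threshold
            else max(1, int(large_step_fraction * len(remaining)))
        )
        # drop the weakest `step` features; ties broken by name for determinism
        order = sorted(
            range(len(remaining)),
            key=lambda i: (importance[i], names[remaining[i]]),
        )
        for i in sorted((order[:step]), reverse=True):
            eliminated.append(remaining[i])
        remaining = [r for k, r in enumerate(remaining) if k not in set(order[:step])]
    survivors = remaining + eliminated[::-1]
    ranked_names = [names[i] for i in survivors]
    scores = np.arange(len(survivors), 0, -1, dtype=np.float64)
    return SelectionRanking(names=ranked_names, scores=scores, method="RFE")


def fir_rank(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    n_trees: int = 200,
    seed: int = 0,
) -> SelectionRanking:
    """Random-forest impurity importance ranking (deterministic per seed)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if X.shape[0] < len(np.unique(y)):
        raise ValueError("fewer samples than classes")
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    names_sorted, scores_sorted = _ordered(list(names), forest.feature_importances_)
    return SelectionRanking(names=names_sorted, scores=scores_sorted, method="FIR")


def top_n_sweep(
    ranking: SelectionRanking,
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    plan,
    groups: np.ndarray | None = None,
    step: int | None = None,
) -> SweepResult:
    """Accuracy-vs-N curve over prefixes of a ranking; best N wins, ties small.

    ``plan`` is a :class:`~quintex.classify.ExperimentPlan`; each prefix is
    scored with the full cross-validated pipeline of the classify module.
    """
    from .classify import evaluate

    X = np.asarray(X, dtype=np.float64)
    names = list(names)
    col = {n: i for i, n in enumerate(names)}
    total = len(ranking.names)
    if step is None:
        step = max(1, total // 8)
    ns = list(range(step, total + 1, step))
    if ns[-1] != total:
        ns.append(total)
    accs = []
    for n in ns:
        cols = [col[nm] for nm in ranking.top(n) if nm in col]
        report = evaluate(X[:, cols], y, groups=groups, plan=plan)
        accs.append(report.ca_mean)
    best = int(np.argmax(accs))  # argmax takes the first (smallest N) on ties
    return SweepResult(ns=ns, accuracies=accs, best_n=ns[best])
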