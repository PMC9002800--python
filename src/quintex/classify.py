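"""One-against-all multiclass SVM, CV protocols, metrics and the CV t-test.

The multiclass machine is explicit one-against-all: one binary SVM per
class, prediction by the largest decision margin.  Hyper-parameters (kernel,
gamma, C, polynomial degree) are grid-searched on decade-spaced ranges with
an inner stratified CV; ties prefer the simpler model (RBF over Poly over
Sigmoid, then smaller C, then smaller gamma).

Evaluation schemes: repeated k-fold (optionally woman-grouped so no woman is
split across train and test), leave-one-woman-out, and leave-one-image-out.
Standardisation is fitted on training folds only.  Reported metrics:
classification accuracy (CA, percent), macro one-vs-rest AUCROC, Cohen's
kappa, macro F1 and the multiclass Matthews correlation coefficient, plus a
paired "k-fold CV t-test" between two methods' per-fold accuracies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.metrics import (
    cohen_kappa_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import (
    LeaveOneGroupOut,
    LeaveOneOut,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ExperimentPlan",
    "OneVsAllSVM",
    "EvaluationReport",
    "TTestResult",
    "grid_search",
    "evaluate",
    "cv_t_test",
]

_KERNEL_PREFERENCE = {"rbf": 0, "poly": 1, "sigmoid": 2}


def _decade_grid(lo_exp: int, hi_exp: int) -> tuple[float, ...]:
    return tuple(float(10.0**e) for e in range(lo_exp, hi_exp + 1))


@dataclass(frozen=True)
class ExperimentPlan:
    """CV scheme plus the SVM hyper-parameter grid.

    Defaults follow the full search ranges: gamma in [1e-4, 1e3], C in
    [1e-3, 1e4] (decade-spaced), degree 1..6 for the polynomial kernel.
    """

    scheme: str = "kfold"  # kfold | leave_one_woman_out | leave_one_image_out
    k: int = 10
    runs: int = 1
    seed: int = 0
    kernels: tuple[str, ...] = ("rbf", "poly", "sigmoid")
    gammas: tuple[float, ...] = _decade_grid(-4, 3)
    Cs: tuple[float, ...] = _decade_grid(-3, 4)
    degrees: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    inner_k: int = 3
    group_aware: bool = True

    def grid(self):
        """Yield (kernel, gamma, C, degree) combinations."""
        for kernel in self.kernels:
            degrees = self.degrees if kernel == "poly" else (3,)
            for gamma in self.gammas:
                for C in self.Cs:
                    for degree in degrees:
                        yield kernel, gamma, C, degree

    def grid_size(self) -> int:
        return sum(1 for _ in self.grid())


class OneVsAllSVM:
    """Explicit one-against-all SVM: one binary machine per class."""

    def __init__(self, kernel="rbf", gamma=1.0, C=1.0, degree=3):
        self.kernel = kernel
        self.gamma = gamma
        self.C = C
        self.degree = degree
        self.classes_: np.ndarray | None = None
        self._machines: list[SVC | None] = []

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self._machines = []
        for c in self.classes_:
            target = (y == c).astype(int)
            clf = SVC(
                kernel=self.kernel, gamma=self.gamma, C=self.C, degree=self.degree
            )
            clf.fit(X, target)
            self._machines.append(clf)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Margins, one column per class (higher = more confident)."""
        X = np.asarray(X, dtype=np.float64)
        return np.column_stack([m.decision_function(X) for m in self._machines])

    def predict(self, X) -> np.ndarray:
        margins = self.decision_function(X)
        return self.classes_[np.argmax(margins, axis=1)]


def grid_search(X, y, plan: ExperimentPlan) -> tuple[str, float, float, int]:
    """Pick (kernel, gamma, C, degree) by inner stratified-CV accuracy.

    Folds with a single class are skipped with a warning.  Ties are broken
    toward the simpler model: RBF before Poly before Sigmoid, then smaller
    C, then smaller gamma, then smaller degree.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid search needs at least 2 classes")
    k = max(2, min(plan.inner_k, int(counts.min())))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=plan.seed)
    folds = []
    for tr, te in splitter.split(X, y):
        if len(np.unique(y[tr])) < 2:
            warnings.warn("skipping degenerate single-class inner fold")
            continue
        folds.append((tr, te))
    if not folds:
        raise ValueError("no usable inner folds")
    best_key, best = None, None
    for kernel, gamma, C, degree in plan.grid():
        accs = []
        for tr, te in folds:
            scaler = StandardScaler().fit(X[tr])
            model = OneVsAllSVM(kernel, gamma, C, degree)
            model.fit(scaler.transform(X[tr]), y[tr])
            pred = model.predict(scaler.transform(X[te]))
            accs.append(float(np.mean(pred == y[te])))
        key = (-np.mean(accs), _KERNEL_PREFERENCE[kernel], C, gamma, degree)
        if best_key is None or key < best_key:
            best_key, best = key, (kernel, gamma, C, degree)
    return best


@dataclass
class TTestResult:
    t: float
    p: float
    significant: bool
    mean_diff: float


@dataclass
class EvaluationReport:
    """Per-fold accuracies and the pooled metric set."""

    fold_accuracies: list[float]
    ca_mean: float
    ca_sd: float
    auc_mean: float
    auc_sd: float
    kappa: float
    f1: float
    mcc: float
    confusion: np.ndarray
    classes: list
    y_true: np.ndarray
    y_pred: np.ndarray
    best_params: list
    t_tests: dict[str, TTestResult] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "-----------------",
            f"folds:    {len(self.fold_accuracies)}",
            f"CA:       {self.ca_mean:.2f} +/- {self.ca_sd:.2f} %",
            f"AUCROC:   {self.auc_mean:.3f} +/- {self.auc_sd:.3f}",
            f"Kappa:    {self.kappa:.3f}",
            f"F1:       {self.f1:.3f}",
            f"MCC:      {self.mcc:.3f}",
            f"classes:  {list(self.classes)}",
        ]
        for name, res in self.t_tests.items():
            tag = "significant" if res.significant else "not significant"
            lines.append(f"t-test vs {name}: t={res.t:.3f} p={res.p:.4f} ({tag})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "ca_mean": self.ca_mean,
            "ca_sd": self.ca_sd,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "kappa": self.kappa,
            "f1": self.f1,
            "mcc": self.mcc,
            "confusion": np.asarray(self.confusion).tolist(),
            "classes": [int(c) if np.issubdtype(type(c), np.integer) else c for c in self.classes],
            "best_params": [list(p) for p in self.best_params],
            "t_tests": {k: asdict(v) for k, v in self.t_tests.items()},
            "schema_version": 1,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _macro_ovr_auc(y_true, margins, classes) -> float:
    """Macro one-vs-rest AUC on decision margins over classes present."""
    aucs = []
    for j, c in enumerate(classes):
        pos = y_true == c
        if 0 < pos.sum() < len(y_true):
            aucs.append(roc_auc_score(pos, margins[:, j]))
    if not aucs:
        return float("nan")
    if len(aucs) < len(classes):
        warnings.warn("AUC averaged over present classes only")
    return float(np.mean(aucs))


def _make_folds(y, groups, plan: ExperimentPlan):
    y = np.asarray(y)
    n = len(y)
    if plan.scheme == "kfold":
        folds = []
        for run in range(plan.runs):
            rs = plan.seed + run
            if groups is not None and plan.group_aware:
                splitter = StratifiedGroupKFold(
                    n_splits=plan.k, shuffle=True, random_state=rs
                )
                folds.extend(splitter.split(np.zeros(n), y, groups))
            else:
                splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=rs)
                folds.extend(splitter.split(np.zeros(n), y))
        return folds
    if plan.scheme == "leave_one_woman_out":
        if groups is None:
            raise ValueError("leave_one_woman_out requires woman IDs")
        return list(LeaveOneGroupOut().split(np.zeros(n), y, groups))
    if plan.scheme == "leave_one_image_out":
        return list(LeaveOneOut().split(np.zeros(n)))
    raise ValueError(f"unknown scheme {plan.scheme!r}")


def evaluate(
    X,
    y,
    groups=None,
    plan: ExperimentPlan = ExperimentPlan(),
    do_grid_search: bool = True,
    params: tuple | None = None,
) -> EvaluationReport:
    """Outer-CV evaluation of the one-against-all SVM pipeline.

    Per outer fold: standardise on the training part, optionally grid-search
    hyper-parameters with an inner CV, fit, and predict the held-out part.
    CA is averaged over folds; kappa, F1, MCC and the confusion matrix are
    computed on the pooled out-of-fold predictions.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    groups = None if groups is None else np.asarray(groups)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("evaluation needs at least 2 classes")
    folds = _make_folds(y, groups, plan)
    fold_accs: list[float] = []
    fold_aucs: list[float] = []
    best_params: list[tuple] = []
    n = len(y)
    pooled_pred = np.empty(n, dtype=y.dtype)
    pooled_margin = np.full((n, len(classes)), np.nan)
    seen = np.zeros(n, dtype=bool)
    for tr, te in folds:
        if groups is not None:
            assert not set(groups[tr]) & set(groups[te]), "group leaked across folds"
        if len(np.unique(y[tr])) < 2:
            warnings.warn("skipping outer fold with single-class training part")
            continue
        scaler = StandardScaler().fit(X[tr])
        Xtr = scaler.transform(X[tr])
        Xte = scaler.transform(X[te])
        if params is not None:
            chosen = params
        elif do_grid_search:
            chosen = grid_search(X[tr], y[tr], plan)
        else:
            chosen = ("rbf", 1.0 / X.shape[1], 1.0, 3)
        best_params.append(chosen)
        model = OneVsAllSVM(*chosen).fit(Xtr, y[tr])
        margins = model.decision_function(Xte)
        margins_full = np.full((len(te), len(classes)), -np.inf)
        model_cols = {c: j for j, c in enumerate(model.classes_)}
        for j, c in enumerate(classes):
            if c in model_cols:
                margins_full[:, j] = margins[:, model_cols[c]]
        pred = classes[np.argmax(margins_full, axis=1)]
        fold_accs.append(float(np.mean(pred == y[te])))
        pooled_pred[te] = pred
        pooled_margin[te] = margins_full
        seen[te] = True
        if len(te) > 1 and len(np.unique(y[te])) > 1:
            fold_aucs.append(_macro_ovr_auc(y[te], margins_full, classes))
    if not seen.any():
        raise ValueError("no fold produced predictions")
    yt, yp = y[seen], pooled_pred[seen]
    if not fold_aucs:  # singleton folds: pool margins instead
        fold_aucs = [_macro_ovr_auc(yt, pooled_margin[seen], classes)]
    return EvaluationReport(
        fold_accuracies=fold_accs,
        ca_mean=100.0 * float(np.mean(fold_accs)),
        ca_sd=100.0 * float(np.std(fold_accs, ddof=1)) if len(fold_accs) > 1 else 0.0,
        auc_mean=float(np.nanmean(fold_aucs)),
        auc_sd=float(np.nanstd(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
        kappa=float(cohen_kappa_score(yt, yp)),
        f1=float(f1_score(yt, yp, average="macro")),
        mcc=float(matthews_corrcoef(yt, yp)),
        confusion=confusion_matrix(yt, yp, labels=classes),
        classes=list(classes),
        y_true=yt,
        y_pred=yp,
        best_params=best_params,
    )


def cv_t_test(
    acc_a,
    acc_b,
    alpha: float = 0.05,
    corrected: bool = False,
    test_train_ratio: float | None = None,
) -> TTestResult:
    """Paired t-test on per-fold accuracy differences (df = k - 1).

    With ``corrected=True`` the Nadeau-Bengio variance correction
    ``(1/k + n_test/n_train)`` is applied, which counteracts the optimism of
    reusing overlapping training sets; ``test_train_ratio`` defaults to
    ``1 / (k - 1)`` for k-fold CV.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two aligned per-fold accuracy vectors (k >= 2)")
    diffs = a - b
    k = diffs.size
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, significant=False, mean_diff=0.0)
        warnings.warn("zero variance of non-zero differences; p -> 0")
        return TTestResult(
            t=float(np.inf) if mean > 0 else float(-np.inf),
            p=0.0,
            significant=True,
            mean_diff=mean,
        )
    if corrected:
        ratio = 1.0 / (k - 1) if test_train_ratio is None else test_train_ratio
        se = sd * np.sqrt(1.0 / k + ratio)
    else:
        se = sd / np.sqrt(k)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df=k - 1))
    return TTestResult(t=float(t), p=p, significant=p < alpha, mean_diff=mean)
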