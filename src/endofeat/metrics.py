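"""Confusion-matrix metrics and the cross-validation harness.

Per-class (one-vs-rest) counts TPV/TNV/FPV/FNV feed the standard formulas

    SEN = TPV/(TPV+FNV)          SPE = TNV/(FPV+TNV)
    PRE = TPV/(TPV+FPV)          F1  = 2*SEN*PRE/(SEN+PRE)
    ACC = (TPV+TNV)/total
    MCC = (TPV*TNV - FPV*FNV) / sqrt((TPV+FPV)(TPV+FNV)(TNV+FPV)(TNV+FNV))
    kappa = (p_o - p_e) / (1 - p_e)

with p_o the observed agreement and p_e the chance agreement from marginal
products.  For multiclass problems SEN/SPE/PRE/F1/MCC are macro-averaged
(unweighted mean over one-vs-rest values); ACC is overall agreement and
kappa is the usual multiclass form.  Any zero-denominator cell yields 0 with
a warning so fold aggregation stays total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CLASSIFIER_PRESETS",
    "build_classifier",
    "confusion",
    "metrics_from_confusion",
    "cross_validate",
    "holdout_split",
]

CLASSIFIER_PRESETS = ("f_tree", "c_tree", "q_svm", "f_g_svm", "c_knn", "e_s_disc")


@dataclass
class ConfusionCounts:
    """K x K confusion matrix (rows = true class, cols = predicted)."""

    matrix: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        K = len(self.classes)
        if self.matrix.shape != (K, K):
            raise ValueError("matrix shape must match the class list")
        if (self.matrix < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TPV, TNV, FPV, FNV) treating class index ``i`` as positive."""
        m = self.matrix
        tp = int(m[i, i])
        fn = int(m[i].sum() - tp)
        fp = int(m[:, i].sum() - tp)
        tn = int(m.sum() - tp - fn - fp)
        return tp, tn, fp, fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.classes != other.classes:
            raise ValueError("cannot add confusions over different classes")
        return ConfusionCounts(self.matrix + other.matrix, list(self.classes))


@dataclass
class MetricReport:
    acc: float
    sen: float
    spe: float
    pre: float
    f1: float
    mcc: float
    kappa: float
    averaging: str
    confusion: ConfusionCounts | None = None
    folds: list | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("acc", "sen", "spe", "pre", "f1", "mcc", "kappa", "averaging")}
        if self.confusion is not None:
            d["confusion"] = self.confusion.matrix.tolist()
            d["classes"] = [str(c) for c in self.confusion.classes]
        if self.folds is not None:
            d["folds"] = [f.to_dict() for f in self.folds]
        return d


def confusion(y_true, y_pred, classes=None) -> ConfusionCounts:
    """Exact confusion counts; unknown labels raise."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    classes = list(classes)
    known = set(classes)
    bad = (set(y_true.tolist()) | set(y_pred.tolist())) - known
    if bad:
        raise ValueError(f"labels not in class list: {sorted(bad)}")
    mat = _skm.confusion_matrix(y_true, y_pred, labels=classes)
    return ConfusionCounts(matrix=mat, classes=classes)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {what}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def _binary_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    sen = _safe_div(tp, tp + fn, "SEN")
    spe = _safe_div(tn, fp + tn, "SPE")
    pre = _safe_div(tp, tp + fp, "PRE")
    f1 = _safe_div(2 * sen * pre, sen + pre, "F1")
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, math.sqrt(den), "MCC") if den else _safe_div(0, 0, "MCC")
    return {"sen": sen, "spe": spe, "pre": pre, "f1": f1, "mcc": mcc}


def metrics_from_confusion(cc: ConfusionCounts, averaging: str = "macro") -> MetricReport:
    """Compute the full metric report from confusion counts.

    ``averaging='binary'`` requires two classes and treats the second as
    positive; ``'macro'`` averages one-vs-rest values uniformly over classes.
    """
    if cc.total == 0:
        raise ValueError("confusion matrix is empty")
    if averaging not in ("binary", "macro"):
        raise ValueError(f"unknown averaging {averaging!r}")
    K = len(cc.classes)
    acc = cc.matrix.trace() / cc.total

    if averaging == "binary":
        if K != 2:
            raise ValueError("binary averaging requires exactly two classes")
        tp, tn, fp, fn = cc.one_vs_rest(1)
        per = _binary_metrics(tp, tn, fp, fn)
    else:
        vals = [_binary_metrics(*cc.one_vs_rest(i)) for i in range(K)]
        per = {k: float(np.mean([v[k] for v in vals])) for k in vals[0]}

    total = cc.total
    p_o = acc
    p_e = float((cc.matrix.sum(axis=1) * cc.matrix.sum(axis=0)).sum()) / total**2
    kappa = _safe_div(p_o - p_e, 1.0 - p_e, "kappa")

    return MetricReport(acc=float(acc), sen=per["sen"], spe=per["spe"],
                        pre=per["pre"], f1=per["f1"], mcc=per["mcc"],
                        kappa=float(kappa), averaging=averaging, confusion=cc)


def build_classifier(name: str, n_samples: int, n_features: int, seed: int = 0):
    """Instantiate one of the six classifier presets.

    Mappings: f_tree/c_tree = decision trees capped at 100 / 4 splits; q_svm =
    quadratic-kernel SVM (one-vs-one); f_g_svm = Gaussian SVM with kernel
    scale sqrt(D)/4 (gamma = 16/D); c_knn = k-NN with k = min(100,
    ceil(N/10)); e_s_disc = random-subspace ensemble of 30 linear
    discriminants on ceil(D/2)-dimensional subspaces.
    """
    if name == "f_tree":
        return DecisionTreeClassifier(max_leaf_nodes=101, random_state=seed)
    if name == "c_tree":
        return DecisionTreeClassifier(max_leaf_nodes=5, random_state=seed)
    if name == "q_svm":
        return SVC(kernel="poly", degree=2, coef0=1.0, C=1.0, random_state=seed)
    if name == "f_g_svm":
        return SVC(kernel="rbf", gamma=16.0 / max(n_features, 1), C=1.0,
                   random_state=seed)
    if name == "c_knn":
        k = min(100, max(1, math.ceil(n_samples / 10)))
        return KNeighborsClassifier(n_neighbors=k)
    if name == "e_s_disc":
        return BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=30,
            max_features=max(1, math.ceil(n_features / 2)),
            bootstrap=False,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier preset {name!r}; choose from {CLASSIFIER_PRESETS}")


def cross_validate(X, y, mask=None, preset: str = "q_svm", k: int = 5,
                   seed: int = 0, averaging: str = "macro") -> MetricReport:
    """Stratified k-fold cross-validation of a preset on masked columns.

    Returns the pooled-confusion report with per-fold reports attached; the
    pooled confusion is the exact sum of the fold confusions.
    """
    from .texture import FeatureMatrix  # local import to avoid cycle

    if isinstance(X, FeatureMatrix):
        if y is None and X.labels is not None:
            y = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if mask is not None:
        bits = getattr(mask, "bits", mask)
        X = X[:, np.flatnonzero(np.asarray(bits))]
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"class {small[0]!r} has fewer than {k} members")
    classes = classes.tolist()

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports = []
    pooled = ConfusionCounts(np.zeros((len(classes), len(classes)), dtype=np.int64),
                             classes)
    for tr, te in skf.split(X, y):
        clf = build_classifier(preset, n_samples=len(tr), n_features=X.shape[1],
                               seed=seed)
        clf.fit(X[tr], y[tr])
        cc = confusion(y[te], clf.predict(X[te]), classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_reports.append(metrics_from_confusion(cc, averaging))
        pooled = pooled + cc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = metrics_from_confusion(pooled, averaging)
    report.folds = fold_reports
    return report


def holdout_split(y, train_frac: float = 0.7, seed: int = 0):
    """Stratified train/test split of indices; per-class train share within
    one sample of ``train_frac``.  Classes need at least two members."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        n_tr = int(round(train_frac * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.extend(idx[:n_tr])
        test.extend(idx[n_tr:])
    return np.sort(np.array(train)), np.sort(np.array(test))
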