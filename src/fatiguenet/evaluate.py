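"""Cross-validated classification and method comparison.

Per subject, features from one of four extractors (PSD, WPD, modified
PCANet = per-epoch PCA + PCANet, or PCANet on raw epochs) are classified
as awake vs fatigue by a linear SVM or KNN under stratified 10-fold
cross-validation.  Any fitted feature model (the PCANet filter banks)
is learned inside each fold on the training split only, so held-out
epochs never influence the filters.

Reported metrics: per-fold accuracy, their mean/SD, and ROC-AUC (mean of
per-fold rank AUCs).  Methods are compared across subjects with paired
two-sided t-tests on the per-subject means.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .baselines import StftSpec, WpdSpec, stft_band_power, wpd_features
from .errors import ConfigurationError, DegenerateInputError
from .pca import ReducedEpoch, ReductionSpec, reduce_epoch
from .pcanet import PCANetSpec, fit as pcanet_fit, transform as pcanet_transform

__all__ = [
    "CvSpec",
    "ClassifierSpec",
    "EvalReport",
    "ComparisonResult",
    "PsdExtractor",
    "WpdExtractor",
    "ModifiedPCANetExtractor",
    "RawPCANetExtractor",
    "make_extractor",
    "METHOD_NAMES",
    "cross_validate",
    "roc_auc",
    "paired_ttest",
    "filter_sweep",
    "compare_methods",
]

METHOD_NAMES = ("wpd", "psd", "modified_pcanet", "pcanet_raw")


@dataclass
class CvSpec:
    folds: int = 10
    stratified: bool = True
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")


@dataclass
class ClassifierSpec:
    family: str = "svm"
    svm_kernel: str = "linear"
    svm_C: float = 1.0
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.family not in ("svm", "knn"):
            raise ConfigurationError(f"unknown classifier family {self.family!r}")
        if self.svm_C <= 0:
            raise ConfigurationError("svm_C must be positive")
        if self.knn_k < 1:
            raise ConfigurationError("knn_k must be >= 1")

    def build(self):
        if self.family == "svm":
            return SVC(kernel=self.svm_kernel, C=self.svm_C)
        return KNeighborsClassifier(n_neighbors=self.knn_k)


@dataclass
class EvalReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    auc: float
    method: str = ""
    subject_id: str = ""
    feature_time: float | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "subject_id": self.subject_id,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "auc": self.auc,
            "fold_accuracies": list(self.fold_accuracies),
            "feature_time": self.feature_time,
        }


@dataclass
class ComparisonResult:
    method_a: str
    method_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    t: float
    p: float
    metric: str = "accuracy"


# ---------------------------------------------------------------------------
# feature extractors with a uniform fit/transform surface


class PsdExtractor:
    """Stateless band-power features; fit is a no-op."""

    name = "psd"

    def __init__(self, stft: StftSpec | None = None, bands=None):
        self.stft = stft
        self.bands = bands

    def fit(self, epochs):
        return self

    def transform(self, epochs) -> np.ndarray:
        return np.stack(
            [stft_band_power(e, self.stft, self.bands) for e in epochs]
        )

    def fit_transform(self, epochs) -> np.ndarray:
        return self.fit(epochs).transform(epochs)


class WpdExtractor:
    """Stateless wavelet-packet features; fit is a no-op."""

    name = "wpd"

    def __init__(self, spec: WpdSpec | None = None):
        self.spec = spec

    def fit(self, epochs):
        return self

    def transform(self, epochs) -> np.ndarray:
        return np.stack([wpd_features(e, self.spec) for e in epochs])

    def fit_transform(self, epochs) -> np.ndarray:
        return self.fit(epochs).transform(epochs)


class ModifiedPCANetExtractor:
    """Per-epoch PCA compression followed by PCANet.

    The PCA step is per-sample (no cross-epoch state); only the PCANet
    filter banks are fitted, on the training epochs' reduced forms.
    """

    name = "modified_pcanet"

    def __init__(self, reduction: ReductionSpec | None = None,
                 pcanet_spec: PCANetSpec | None = None):
        self.reduction = reduction if reduction is not None else ReductionSpec()
        self.pcanet_spec = pcanet_spec if pcanet_spec is not None else PCANetSpec()
        self.model = None

    def _reduce(self, epochs):
        # per-sample reduction: already-reduced epochs pass through, so
        # callers may precompute scores once outside cross-validation
        return [
            e if isinstance(e, ReducedEpoch) else reduce_epoch(e, self.reduction)
            for e in epochs
        ]

    def fit(self, epochs):
        self.model = pcanet_fit(self._reduce(epochs), self.pcanet_spec)
        return self

    def transform(self, epochs) -> np.ndarray:
        if self.model is None:
            raise ConfigurationError("extractor not fitted")
        return np.stack(
            [pcanet_transform(self.model, re) for re in self._reduce(epochs)]
        )

    def fit_transform(self, epochs) -> np.ndarray:
        return self.fit(epochs).transform(epochs)


class RawPCANetExtractor:
    """PCANet on full epochs, no PCA compression (the traditional form)."""

    name = "pcanet_raw"

    def __init__(self, pcanet_spec: PCANetSpec | None = None):
        self.pcanet_spec = pcanet_spec
        self.model = None

    def _spec_for(self, shape) -> PCANetSpec:
        if self.pcanet_spec is not None:
            return self.pcanet_spec
        m, n = shape
        # default blocks: quarter the map in each direction (B = 16)
        return PCANetSpec(block_h=max(1, m // 4), block_w=max(1, n // 4))

    def fit(self, epochs):
        arrays = [np.asarray(e.data, dtype=np.float64) for e in epochs]
        self.model = pcanet_fit(arrays, self._spec_for(arrays[0].shape))
        return self

    def transform(self, epochs) -> np.ndarray:
        if self.model is None:
            raise ConfigurationError("extractor not fitted")
        return np.stack(
            [pcanet_transform(self.model, np.asarray(e.data)) for e in epochs]
        )

    def fit_transform(self, epochs) -> np.ndarray:
        return self.fit(epochs).transform(epochs)


def make_extractor(method: str, reduction: ReductionSpec | None = None,
                   pcanet_spec: PCANetSpec | None = None):
    if method == "psd":
        return PsdExtractor()
    if method == "wpd":
        return WpdExtractor()
    if method == "modified_pcanet":
        return ModifiedPCANetExtractor(reduction, pcanet_spec)
    if method == "pcanet_raw":
        return RawPCANetExtractor(pcanet_spec)
    raise ConfigurationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# metrics


def roc_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC: probability that a random positive is
    scored above a random negative, ties counted 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def paired_ttest(acc_a, acc_b, metric: str = "accuracy",
                 method_a: str = "a", method_b: str = "b") -> ComparisonResult:
    """Two-sided paired t-test on per-subject differences.

    Zero-variance differences are degenerate: all-zero differences give
    t = 0, p = 1; constant non-zero differences give t = +-inf, p = 0.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ConfigurationError("need two equal-length vectors, n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(d.mean()) * np.inf), 0.0
    else:
        t, p = stats.ttest_rel(a, b)
    return ComparisonResult(method_a=method_a, method_b=method_b,
                            values_a=a, values_b=b,
                            t=float(t), p=float(p), metric=metric)


# ---------------------------------------------------------------------------
# cross-validation


def _fold_scores(clf, spec: ClassifierSpec, X) -> np.ndarray:
    if spec.family == "svm":
        return clf.decision_function(X)
    proba = clf.predict_proba(X)
    pos_col = int(np.argmax(clf.classes_ == 1))
    return proba[:, pos_col]


def cross_validate(
    data,
    labels,
    cv: CvSpec | None = None,
    clf: ClassifierSpec | None = None,
    extractor_factory=None,
) -> EvalReport:
    """K-fold evaluation with in-fold feature fitting.

    ``data`` is a precomputed feature matrix, or — when
    ``extractor_factory`` is given — a sequence of epochs from which a
    fresh extractor (``extractor_factory()``) builds features per fold,
    fitted on the training split only.  Labels must be 0/1 with both
    classes present.  Deterministic given ``cv.shuffle_seed``.
    """
    cv = cv if cv is not None else CvSpec()
    clf = clf if clf is not None else ClassifierSpec()
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise DegenerateInputError("labels contain a single class")
    n = len(data) if extractor_factory is not None else np.asarray(data).shape[0]
    if y.size != n:
        raise ConfigurationError("labels length does not match data")

    if cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.folds, shuffle=True,
                                   random_state=cv.shuffle_seed)
    else:
        splitter = KFold(n_splits=cv.folds, shuffle=True,
                         random_state=cv.shuffle_seed)

    accs, aucs = [], []
    idx = np.arange(n)
    for tr, te in splitter.split(idx, y):
        if extractor_factory is not None:
            ext = extractor_factory()
            Xtr = ext.fit_transform([data[i] for i in tr])
            Xte = ext.transform([data[i] for i in te])
        else:
            X = np.asarray(data)
            Xtr, Xte = X[tr], X[te]
        model = clf.build()
        model.fit(Xtr, y[tr])
        pred = model.predict(Xte)
        accs.append(float(np.mean(pred == y[te])))
        if np.unique(y[te]).size == 2:
            aucs.append(roc_auc(_fold_scores(model, clf, Xte), y[te]))
    accs_arr = np.asarray(accs)
    return EvalReport(
        fold_accuracies=accs,
        mean_accuracy=float(accs_arr.mean()),
        sd_accuracy=float(accs_arr.std(ddof=1)) if len(accs) > 1 else 0.0,
        auc=float(np.mean(aucs)) if aucs else float("nan"),
    )


# ---------------------------------------------------------------------------
# comparison harness


def _binary_labels(labels) -> np.ndarray:
    """Map state labels to 0/1 (fatigue = positive class)."""
    y = np.asarray(labels)
    if y.dtype.kind in "iub":
        return y.astype(int)
    return np.asarray([1 if str(v) == "fatigue" else 0 for v in y])


def filter_sweep(
    dataset: dict,
    L_values,
    reduction: ReductionSpec | None = None,
    base_spec: PCANetSpec | None = None,
    cv: CvSpec | None = None,
    clf: ClassifierSpec | None = None,
) -> pd.DataFrame:
    """Modified-PCANet accuracy per filter count L (L1 = L2 = L).

    ``dataset`` maps subject_id -> (epochs, labels).  Returns one row
    per L with per-subject mean accuracies and their average; a cell
    that fails records NaN and the sweep continues.
    """
    base = base_spec if base_spec is not None else PCANetSpec()
    rows = []
    for L in L_values:
        if L < 1:
            raise ConfigurationError("filter count must be >= 1")
        spec = PCANetSpec(
            k1=base.k1, k2=base.k2, L1=int(L), L2=int(L),
            block_h=base.block_h, block_w=base.block_w,
            block_overlap=base.block_overlap, layer2_mode=base.layer2_mode,
        )
        row: dict = {"L": int(L)}
        for subject_id, (epochs, labels) in dataset.items():
            try:
                rep = cross_validate(
                    epochs, _binary_labels(labels), cv, clf,
                    extractor_factory=lambda: ModifiedPCANetExtractor(
                        reduction, spec
                    ),
                )
                row[subject_id] = rep.mean_accuracy
            except Exception:
                row[subject_id] = float("nan")
        subj_cols = [k for k in row if k != "L"]
        row["mean"] = float(np.nanmean([row[k] for k in subj_cols]))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_methods(
    dataset: dict,
    methods=METHOD_NAMES,
    cv: CvSpec | None = None,
    clf: ClassifierSpec | None = None,
    reduction: ReductionSpec | None = None,
    pcanet_spec: PCANetSpec | None = None,
    record_timing: bool = True,
) -> tuple[list[EvalReport], list[ComparisonResult]]:
    """Evaluate each method per subject and pair them with t-tests.

    Returns (reports, comparisons): one report per subject x method
    (with feature-extraction wall time when ``record_timing``), and one
    accuracy comparison per unordered method pair, paired over subjects.
    Timing numbers are reported only, never asserted — they depend on
    the machine.
    """
    for m in methods:
        if m not in METHOD_NAMES:
            raise ConfigurationError(f"unknown method {m!r}")
    if len(dataset) < 2:
        raise ConfigurationError("paired tests need >= 2 subjects")
    reports: list[EvalReport] = []
    for subject_id, (epochs, labels) in dataset.items():
        y = _binary_labels(labels)
        for method in methods:
            def factory(method=method):
                return make_extractor(method, reduction, pcanet_spec)

            t_feat = None
            if record_timing:
                t0 = time.perf_counter()
                factory().fit_transform(list(epochs))
                t_feat = time.perf_counter() - t0
            rep = cross_validate(epochs, y, cv, clf,
                                 extractor_factory=factory)
            rep.method = method
            rep.subject_id = subject_id
            rep.feature_time = t_feat
            reports.append(rep)

    comparisons: list[ComparisonResult] = []
    subjects = list(dataset)
    by_method = {
        m: np.array([
            next(r for r in reports if r.method == m and r.subject_id == s
                 ).mean_accuracy
            for s in subjects
        ])
        for m in methods
    }
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            comparisons.append(
                paired_ttest(by_method[ma], by_method[mb],
                             method_a=ma, method_b=mb)
            )
    return reports, comparisons
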