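"""Case-level feature assembly, selection, classification and statistics.

The per-case feature vector is 1,087 values: 37 spectral features plus
350 radiomics features from each of the three parametric maps (NDM, DEA,
RF-I). The classification protocol is LASSO-initialized SVM evaluated by
repeated stratified 10-fold cross-validation (50 repeats by default),
reporting the mean and standard deviation of AUC, accuracy, sensitivity
and specificity across repeats.

Feature selection and standardization are re-fit inside every training
fold by default ("nested"), so held-out labels never influence the
trained model; a "pre" mode (one selection on all data before CV) is also
provided for comparison but is vulnerable to selection leakage.

The positive class is "malignant" throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (
    IncompleteCaseError,
    InvalidDesignError,
    PartitionError,
    UndefinedROCError,
)
from .feature_maps import MAP_KINDS, MapConfig, dea_map, nakagami_map, skewness_map
from .phantom import CohortData
from .radiomics import map_features, radiomics_feature_names
from .rf_io import RFFrameStack, ROIRect, extract_roi, hilbert_envelope
from .spectral import SPECTRAL_FEATURE_NAMES, SpectralConfig, spectral_feature_vector

__all__ = [
    "FEATURE_COLUMNS",
    "POSITIVE_LABEL",
    "extract_case_features",
    "extract_cohort_features",
    "build_feature_table",
    "LassoSelection",
    "lasso_select",
    "CVResult",
    "svm_evaluate",
    "compare_classifiers",
    "roc_curve",
    "ttest_features",
]

POSITIVE_LABEL = "malignant"

#: Canonical column order of the per-case feature vector (length 1,087).
FEATURE_COLUMNS: list[str] = list(SPECTRAL_FEATURE_NAMES) + [
    f"{kind}_{name}" for kind in MAP_KINDS for name in radiomics_feature_names()
]


def extract_case_features(
    stack: RFFrameStack,
    roi: ROIRect | None = None,
    map_config: MapConfig | None = None,
    spectral_config: SpectralConfig | None = None,
    n_levels: int = 32,
) -> pd.Series:
    """The full 1,087-element feature vector for one case.

    The three parametric maps and the patch spectra are computed on the
    first frame of the (ROI-cropped) stack; S1/S2 use the slow-time series
    across frames.
    """
    roi_stack = extract_roi(stack, roi) if roi is not None else stack
    meta = roi_stack.meta
    cfg = map_config or MapConfig.for_meta(meta)

    values = spectral_feature_vector(roi_stack, config=spectral_config)

    frame0 = roi_stack.frame(0)
    env = hilbert_envelope(frame0, meta)
    maps = {
        "NDM": nakagami_map(env, cfg),
        "DEA": dea_map(frame0, cfg, meta),
        "RFI": skewness_map(frame0, cfg),
    }
    parts = [values]
    for kind in MAP_KINDS:
        vec = map_features(maps[kind], n_levels=n_levels)
        vec.index = [f"{kind}_{name}" for name in vec.index]
        parts.append(vec)
    out = pd.concat(parts).reindex(FEATURE_COLUMNS)
    assert not out.isna().any()
    return out


def extract_cohort_features(
    cohort: CohortData,
    map_config: MapConfig | None = None,
    spectral_config: SpectralConfig | None = None,
) -> pd.DataFrame:
    """Extract every case of a cohort into the canonical wide table."""
    features = {}
    labels = {}
    for case in cohort.cases:
        features[case.case_id] = extract_case_features(
            case.stack, case.roi, map_config=map_config, spectral_config=spectral_config
        )
        labels[case.case_id] = case.label
    return build_feature_table(features, labels)


def build_feature_table(
    features: dict[str, pd.Series],
    labels: dict[str, str],
) -> pd.DataFrame:
    """Assemble per-case feature vectors into the canonical wide table.

    Raises
    ------
    IncompleteCaseError
        Naming the first offending case and its missing features.
    """
    rows = []
    for case_id, vec in features.items():
        missing = [c for c in FEATURE_COLUMNS if c not in vec.index or pd.isna(vec[c])]
        if missing:
            raise IncompleteCaseError(
                f"case {case_id!r} is missing {len(missing)} features, e.g. {missing[:5]}"
            )
        if case_id not in labels:
            raise IncompleteCaseError(f"case {case_id!r} has no label")
        rows.append(pd.concat([pd.Series({"label": labels[case_id]}), vec[FEATURE_COLUMNS]]))
    table = pd.DataFrame(rows, index=list(features.keys()))
    table.index.name = "case_id"
    return table[["label"] + FEATURE_COLUMNS]


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = [c for c in table.columns if c != "label"]
    X = table[cols].to_numpy(dtype=np.float64)
    y = (table["label"] == POSITIVE_LABEL).to_numpy(dtype=int)
    return X, y, cols


# ---------------------------------------------------------------------------
# LASSO feature selection
# ---------------------------------------------------------------------------

@dataclass
class LassoSelection:
    """Outcome of L1-penalized logistic selection."""

    feature_names: list[str]
    indices: np.ndarray
    coefficients: np.ndarray
    chosen_c: float


def lasso_select(
    table: pd.DataFrame | np.ndarray,
    y: np.ndarray | None = None,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> LassoSelection:
    """L1-penalized logistic regression selection over a penalty grid.

    Features are z-score standardized internally; the penalty is chosen by
    cross-validated log-loss. Features with nonzero coefficients at the
    chosen penalty are returned. The grid is expressed as inverse
    regularization strengths C = 1/lambda.
    """
    if isinstance(table, pd.DataFrame):
        X, y, names = _split_xy(table)
    else:
        X = np.asarray(table, dtype=np.float64)
        if y is None:
            raise ValueError("y is required when passing a bare matrix")
        y = np.asarray(y, dtype=int)
        names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise InvalidDesignError("labels contain a single class")
    cs = 1.0 / lambda_grid if lambda_grid is not None else np.logspace(-2, 1, 10)
    folds = int(min(cv_folds, counts.min()))
    if folds < 2:
        raise InvalidDesignError("need at least 2 cases per class for selection CV")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegressionCV(
            Cs=cs,
            cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            refit=True,
            random_state=seed,
        ).fit(Xs, y)
    coefs = model.coef_.ravel()
    idx = np.flatnonzero(coefs != 0.0)
    return LassoSelection(
        feature_names=[names[i] for i in idx],
        indices=idx,
        coefficients=coefs[idx],
        chosen_c=float(model.C_[0]),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC from a threshold sweep over the sorted scores.

    Thresholds are swept over the sorted unique predicted probabilities;
    a case is called positive when its score is >= the threshold. Points
    are (1 - specificity, sensitivity), with (0, 0) and (1, 1) appended;
    AUC is the trapezoid area, which equals the Mann-Whitney concordance
    probability (ties counted half).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError("both classes are required for a ROC curve")
    points = [(0.0, 0.0)]
    for t in np.unique(scores)[::-1]:
        called_pos = scores >= t
        sens = float(np.sum(called_pos & (y == 1)) / n_pos)
        spec = float(np.sum(~called_pos & (y == 0)) / n_neg)
        points.append((1.0 - spec, sens))
    points.append((1.0, 1.0))
    pts = np.array(points)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def _threshold_metrics(scores: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    called = scores >= threshold
    tp = int(np.sum(called & (y == 1)))
    tn = int(np.sum(~called & (y == 0)))
    fp = int(np.sum(called & (y == 0)))
    fn = int(np.sum(~called & (y == 1)))
    return {
        "acc": (tp + tn) / y.size,
        "sens": tp / max(1, tp + fn),
        "spec": tn / max(1, tn + fp),
    }


# ---------------------------------------------------------------------------
# repeated cross-validated classification
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Metrics of one classifier under repeated stratified k-fold CV."""

    per_repeat: pd.DataFrame          # columns auc, acc, sens, spec; one row per repeat
    summary: pd.DataFrame             # rows mean/std
    roc_points: np.ndarray            # pooled ROC curve over all repeats
    fold_assignments: list[np.ndarray]  # per repeat: fold index of each case
    seed: int = 0

    @property
    def mean_auc(self) -> float:
        return float(self.summary.loc["mean", "auc"])


def _median_heuristic_gamma(X: np.ndarray) -> float:
    if X.shape[0] < 2:
        return 1.0
    d2 = pdist(X, metric="sqeuclidean")
    med = float(np.median(d2))
    return 1.0 / med if med > 0 else 1.0


def _make_classifier(name: str, X_train: np.ndarray, seed: int):
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma=_median_heuristic_gamma(X_train),
                   probability=True, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=min(5, X_train.shape[0]))
    raise ValueError(f"unknown classifier {name!r}")


def _fit_and_score_fold(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    classifier: str,
    selection: str,
    pre_selected: np.ndarray | None,
    seed: int,
) -> np.ndarray:
    if np.unique(y[train]).size < 2:
        raise PartitionError("training fold contains a single class")
    scaler = StandardScaler().fit(X[train])
    Xs_train = scaler.transform(X[train])
    Xs_test = scaler.transform(X[test])
    if selection == "nested":
        try:
            sel = lasso_select(Xs_train, y[train], cv_folds=3, seed=seed)
            idx = sel.indices if sel.indices.size else np.arange(X.shape[1])
        except InvalidDesignError:
            warnings.warn("training fold too small for nested selection; using all features",
                          stacklevel=2)
            idx = np.arange(X.shape[1])
    elif selection == "pre":
        idx = pre_selected if pre_selected is not None and pre_selected.size else np.arange(X.shape[1])
    elif selection == "none":
        idx = np.arange(X.shape[1])
    else:
        raise ValueError(f"unknown selection mode {selection!r}")
    clf = _make_classifier(classifier, Xs_train[:, idx], seed)
    clf.fit(Xs_train[:, idx], y[train])
    proba = clf.predict_proba(Xs_test[:, idx])
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return proba[:, pos_col]


def svm_evaluate(
    table: pd.DataFrame,
    repeats: int = 50,
    folds: int = 10,
    seed: int = 0,
    classifier: str = "svm",
    selection: str = "nested",
) -> CVResult:
    """Repeated stratified k-fold evaluation of the selection+SVM pipeline.

    Each repeat draws a fresh stratified partition (seeded from ``seed``);
    feature standardization and LASSO selection are re-fit on every
    training fold; the classifier scores its held-out fold with calibrated
    probabilities. Per repeat, held-out probabilities are pooled across
    folds and AUC/ACC/SENS/SPEC computed; the summary reports the mean and
    standard deviation over repeats.
    """
    X, y, _ = _split_xy(table)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise InvalidDesignError("labels contain a single class")
    folds = int(min(folds, counts.min()))
    if folds < 2:
        raise InvalidDesignError("too few cases per class for the requested folds")

    pre_selected = None
    if selection == "pre":
        pre_selected = lasso_select(table, seed=seed).indices

    repeat_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    rows = []
    assignments: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for r in range(repeats):
        rseed = int(repeat_seeds[r])
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rseed)
        scores = np.empty(y.size)
        fold_of = np.empty(y.size, dtype=int)
        for k, (train, test) in enumerate(skf.split(X, y)):
            fold_of[test] = k
            scores[test] = _fit_and_score_fold(
                X, y, train, test, classifier, selection, pre_selected, rseed
            )
        _, auc = roc_curve(scores, y)
        metrics = _threshold_metrics(scores, y)
        rows.append({"auc": auc, **metrics})
        assignments.append(fold_of)
        all_scores.append(scores)
        all_labels.append(y)
    per_repeat = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {"mean": per_repeat.mean(), "std": per_repeat.std(ddof=0)}
    ).T
    pooled_pts, _ = roc_curve(np.concatenate(all_scores), np.concatenate(all_labels))
    return CVResult(per_repeat=per_repeat, summary=summary,
                    roc_points=pooled_pts, fold_assignments=assignments, seed=seed)


def compare_classifiers(
    table: pd.DataFrame,
    classifiers: tuple[str, ...] = ("svm", "random_forest", "knn"),
    repeats: int = 50,
    folds: int = 10,
    seed: int = 0,
    selection: str = "nested",
) -> dict[str, CVResult]:
    """Evaluate several classifiers under identical CV partitions.

    All classifiers share the same master seed, hence identical stratified
    fold assignments per repeat, enabling paired comparison.
    """
    results = {
        name: svm_evaluate(table, repeats=repeats, folds=folds, seed=seed,
                           classifier=name, selection=selection)
        for name in classifiers
    }
    first = next(iter(results.values()))
    for res in results.values():
        for a, b in zip(first.fold_assignments, res.fold_assignments):
            assert np.array_equal(a, b), "partition pairing violated"
    return results


# ---------------------------------------------------------------------------
# per-feature group statistics
# ---------------------------------------------------------------------------

def ttest_features(
    table: pd.DataFrame,
    features: list[str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per feature between the label groups.

    Welch's unequal-variance form is the default (``equal_var=False``);
    Student's form is available via the flag. Features with zero variance
    in both groups are flagged undefined (t = 0, p = 1).
    """
    if features is None:
        features = [c for c in table.columns if c != "label"]
    pos = table[table["label"] == POSITIVE_LABEL]
    neg = table[table["label"] != POSITIVE_LABEL]
    if len(pos) < 2 or len(neg) < 2:
        raise InvalidDesignError("need >= 2 cases per class for a t-test")
    rows = []
    for feat in features:
        a = pos[feat].to_numpy(dtype=np.float64)
        b = neg[feat].to_numpy(dtype=np.float64)
        undefined = a.std() == 0 and b.std() == 0
        if undefined:
            t, p = 0.0, 1.0
            if np.mean(a) == np.mean(b):
                p = 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "feature": feat,
            "mean_malignant": float(a.mean()),
            "std_malignant": float(a.std(ddof=0)),
            "mean_benign": float(b.mean()),
            "std_benign": float(b.std(ddof=0)),
            "t": float(t),
            "p": float(p),
            "undefined": bool(undefined),
        })
    return pd.DataFrame(rows).set_index("feature")
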