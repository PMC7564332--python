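"""Two-class classifiers and the hierarchical evaluation protocol.

Three algorithms cover the three comparisons in the hierarchy: a linear
discriminant for carcinoid vs NEC, a Gaussian-kernel naive Bayes for TC vs
AC, and a cosine-distance k-nearest-neighbour vote for SCLC vs LCNEC.  All
operate on log2 relative frequencies of a small selected feature set and
use equal class priors (group sizes are near-balanced and plain accuracy is
reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from nen_mirna.core_io import RFMatrix, SampleTable
from nen_mirna.marker_discovery import stratified_folds
from nen_mirna.stats import (
    TestResult,
    UndefinedStatisticError,
    mann_whitney,
    spearman,
)

ALGORITHMS = ("lda", "kernel_nb", "cosine_knn")


@dataclass
class TrainedModel:
    """A fitted two-class model.

    ``classes`` fixes label order; ``params`` holds the algorithm-specific
    fit (class means and pooled covariance for lda; per-class training
    values and kernel bandwidths for kernel_nb; training vectors, labels and
    k for cosine_knn).  ``training_sample_ids`` records provenance so that
    evaluation can verify discovery/validation separation.
    """

    algorithm: str
    features: list[str]
    classes: tuple[str, str]
    params: dict
    training_sample_ids: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        x = X[self.features].to_numpy(dtype=float)
        if self.algorithm == "lda":
            pred = _predict_lda(self.params, x)
        elif self.algorithm == "kernel_nb":
            pred = _predict_kernel_nb(self.params, x)
        elif self.algorithm == "cosine_knn":
            pred = _predict_cosine_knn(self.params, x)
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        return pd.Series([self.classes[i] for i in pred], index=X.index)


def _split_classes(X: pd.DataFrame, labels: pd.Series) -> tuple[tuple[str, str], np.ndarray, np.ndarray]:
    labels = labels.loc[X.index]
    classes = tuple(sorted(labels.unique()))
    if len(classes) != 2:
        raise ValueError(f"binary classification requires 2 classes, got {classes}")
    x0 = X[labels == classes[0]].to_numpy(dtype=float)
    x1 = X[labels == classes[1]].to_numpy(dtype=float)
    return classes, x0, x1


def train_lda(X: pd.DataFrame, labels: pd.Series) -> TrainedModel:
    """Fisher linear discriminant with pooled within-class covariance.

    The covariance receives a ridge of 1e-6 times its mean diagonal for
    invertibility; the decision boundary passes through the midpoint of the
    class means (equal priors).  Requires at least 2 samples per class and
    no more features than samples - 2.
    """
    classes, x0, x1 = _split_classes(X, labels)
    n, p = X.shape
    if x0.shape[0] < 2 or x1.shape[0] < 2:
        raise ValueError("train_lda requires >= 2 samples per class")
    if p > n - 2:
        raise ValueError(f"too many features ({p}) for {n} samples; need p <= n - 2")
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    s = ((x0 - m0).T @ (x0 - m0) + (x1 - m1).T @ (x1 - m1)) / (n - 2)
    # absolute fallback keeps the ridge representable when classes are
    # internally constant (zero within-class scatter)
    ridge = 1e-6 * np.trace(s) / p if np.trace(s) > 0 else 1e-8
    s_r = s + ridge * np.eye(p)
    try:
        w = np.linalg.solve(s_r, m0 - m1)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance even after ridge; use fewer features"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise ValueError("singular pooled covariance even after ridge; use fewer features")
    c = float(w @ (m0 + m1) / 2.0)
    return TrainedModel(
        "lda",
        list(X.columns),
        classes,
        {"weights": w, "threshold": c, "means": (m0, m1), "pooled_cov": s_r},
        training_sample_ids=list(X.index),
    )


def _predict_lda(params: dict, x: np.ndarray) -> np.ndarray:
    score = x @ params["weights"] - params["threshold"]
    return (score <= 0).astype(int)  # > 0 -> first class (nearer m0)


def _silverman_bandwidth(values: np.ndarray, floor: float = 1e-3) -> float:
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = sd
    h = 0.9 * spread * n ** (-1.0 / 5.0)
    return max(float(h), floor)


def train_kernel_nb(X: pd.DataFrame, labels: pd.Series) -> TrainedModel:
    """Naive Bayes with per-class, per-feature Gaussian kernel densities.

    Bandwidths follow Silverman's rule with a floor of 1e-3; the posterior
    is the product of per-feature kernel density estimates with equal class
    priors.
    """
    classes, x0, x1 = _split_classes(X, labels)
    if x0.shape[0] < 2 or x1.shape[0] < 2:
        raise ValueError("train_kernel_nb requires >= 2 samples per class")
    params = {"train": (x0, x1)}
    params["bandwidths"] = tuple(
        np.array([_silverman_bandwidth(xc[:, j]) for j in range(xc.shape[1])])
        for xc in (x0, x1)
    )
    return TrainedModel(
        "kernel_nb", list(X.columns), classes, params, training_sample_ids=list(X.index)
    )


def _class_log_density(xc: np.ndarray, h: np.ndarray, x: np.ndarray) -> np.ndarray:
    # x: (m, p); xc: (nc, p); per-feature KDE log densities summed over features
    z = (x[:, None, :] - xc[None, :, :]) / h[None, None, :]
    log_k = -0.5 * z**2 - 0.5 * np.log(2 * np.pi) - np.log(h)[None, None, :]
    return logsumexp(log_k, axis=1).sum(axis=1) - x.shape[1] * np.log(xc.shape[0])


def _predict_kernel_nb(params: dict, x: np.ndarray) -> np.ndarray:
    x0, x1 = params["train"]
    h0, h1 = params["bandwidths"]
    ll0 = _class_log_density(x0, h0, x)
    ll1 = _class_log_density(x1, h1, x)
    return (ll1 > ll0).astype(int)


def train_cosine_knn(X: pd.DataFrame, labels: pd.Series, k: int = 3) -> TrainedModel:
    """k-nearest-neighbour majority vote under cosine distance.

    k must be odd (no vote ties in a binary problem) and at most n - 1.
    Zero vectors are rejected: cosine distance is undefined for them.
    """
    labels = labels.loc[X.index]
    classes = tuple(sorted(labels.unique()))
    if len(classes) != 2:
        raise ValueError(f"binary classification requires 2 classes, got {classes}")
    if k < 1 or k % 2 == 0 or k > len(X) - 1:
        raise ValueError("k must be odd with 1 <= k <= n - 1")
    x = X.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector in training data; cosine distance undefined")
    y = (labels == classes[1]).to_numpy().astype(int)
    return TrainedModel(
        "cosine_knn",
        list(X.columns),
        classes,
        {"train": x, "train_labels": y, "k": k},
        training_sample_ids=list(X.index),
    )


def _predict_cosine_knn(params: dict, x: np.ndarray) -> np.ndarray:
    train = params["train"]
    y = params["train_labels"]
    k = params["k"]
    qn = np.linalg.norm(x, axis=1)
    if np.any(qn == 0):
        raise ValueError("zero query vector; cosine distance undefined")
    tn = np.linalg.norm(train, axis=1)
    dist = 1.0 - (x @ train.T) / np.outer(qn, tn)
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes = y[nearest].sum(axis=1)
    return (votes * 2 > k).astype(int)


_TRAINERS = {
    "lda": train_lda,
    "kernel_nb": train_kernel_nb,
    "cosine_knn": train_cosine_knn,
}


def train(algorithm: str, X: pd.DataFrame, labels: pd.Series, **kwargs) -> TrainedModel:
    if algorithm not in _TRAINERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return _TRAINERS[algorithm](X, labels, **kwargs)


@dataclass
class SubsetSearchResult:
    algorithm: str
    features: list[str]
    cv_accuracy: float
    table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "features": self.features,
            "cv_accuracy": float(self.cv_accuracy),
        }


def subset_search(
    rf: RFMatrix,
    labels: pd.Series,
    candidates: list[str],
    algorithms: tuple[str, ...] = ALGORITHMS,
    max_subset: int = 3,
    n_folds: int = 5,
    seed: int = 0,
) -> SubsetSearchResult:
    """Exhaustive feature-subset x algorithm search by cross-validated accuracy.

    All subsets of the candidate list of size 1..max_subset are scored by
    stratified k-fold CV accuracy for each algorithm.  Ties prefer the
    smaller subset, then lexicographic feature names, then algorithm order.
    Deterministic under ``seed``.
    """
    if len(candidates) > 25:
        raise ValueError("subset search is exhaustive; at most 25 candidates allowed")
    missing = [c for c in candidates if c not in rf.rf.columns]
    if missing:
        raise KeyError(f"candidate features absent from rf matrix: {missing}")
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    labels = labels.loc[rf.sample_ids]
    min_class = int(labels.value_counts().min())
    folds_used = max(2, min(n_folds, min_class))
    fold = stratified_folds(labels, folds_used, seed)
    log2 = rf.log2()
    results = []
    cand_sorted = sorted(candidates)
    for size in range(1, max_subset + 1):
        for subset in combinations(cand_sorted, size):
            X = log2[list(subset)]
            for ai, alg in enumerate(algorithms):
                correct = 0
                for f in range(folds_used):
                    train_ids = list(fold.index[fold != f])
                    test_ids = list(fold.index[fold == f])
                    model = train(alg, X.loc[train_ids], labels)
                    pred = model.predict(X.loc[test_ids])
                    correct += int((pred == labels.loc[test_ids]).sum())
                acc = correct / len(labels)
                results.append(
                    {
                        "algorithm": alg,
                        "features": list(subset),
                        "cv_accuracy": acc,
                        "_key": (-acc, size, subset, ai),
                    }
                )
    best = min(results, key=lambda r: r["_key"])
    table = [{k: v for k, v in r.items() if k != "_key"} for r in results]
    return SubsetSearchResult(best["algorithm"], best["features"], best["cv_accuracy"], table)


@dataclass
class EvaluationReport:
    """Per-sample predictions plus confusion matrices and accuracies per set.

    Confusion matrices are true x predicted; overall accuracy is
    trace / total.  Subtype accuracy is reported among samples whose
    level-1 (carcinoid vs NEC) call was correct.
    """

    per_sample: pd.DataFrame
    confusion: dict[str, pd.DataFrame]
    accuracy: dict[str, dict[str, float]]
    misclassified: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "per_sample": self.per_sample.to_dict(orient="index"),
            "confusion": {
                s: {t: m.loc[t].to_dict() for t in m.index} for s, m in self.confusion.items()
            },
            "accuracy": self.accuracy,
            "misclassified": self.misclassified,
        }


def confusion_matrix(true: pd.Series, pred: pd.Series, labels: list[str]) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(true, pred):
        mat.loc[t, p] += 1
    return mat


def accuracy_from_confusion(mat: pd.DataFrame) -> float:
    total = mat.to_numpy().sum()
    if total == 0:
        return float("nan")
    return float(np.trace(mat.to_numpy()) / total)


def evaluate_hierarchical(
    level1: TrainedModel,
    level2a: TrainedModel,
    level2b: TrainedModel,
    rf: RFMatrix,
    ann: SampleTable,
) -> EvaluationReport:
    """Hierarchical evaluation: level 1 calls carcinoid vs NEC; the level-2
    model chosen by that call then assigns the subtype (TC/AC or
    SCLC/LCNEC).  Raises if any model's training samples overlap the
    validation set."""
    validation = set(ann.samples_of_set("validation"))
    for model, name in ((level1, "level1"), (level2a, "level2a"), (level2b, "level2b")):
        overlap = validation & set(model.training_sample_ids)
        if overlap:
            raise ValueError(
                f"{name} model was trained on validation samples: {sorted(overlap)}"
            )
    sample_ids = rf.sample_ids
    log2 = rf.log2()
    group_pred = level1.predict(log2[level1.features])
    pred_2a = level2a.predict(log2[level2a.features])
    pred_2b = level2b.predict(log2[level2b.features])
    subtype_pred = group_pred.map(lambda g: "").copy()
    for s in sample_ids:
        subtype_pred[s] = pred_2a[s] if group_pred[s] == "carcinoid" else pred_2b[s]
    per_sample = pd.DataFrame(
        {
            "set_label": ann.table.loc[sample_ids, "set_label"],
            "true_group": ann.subset(sample_ids).group,
            "pred_group": group_pred,
            "true_type": ann.table.loc[sample_ids, "tumor_type"],
            "pred_type": subtype_pred,
        }
    )
    confusion: dict[str, pd.DataFrame] = {}
    accuracy: dict[str, dict[str, float]] = {}
    misclassified: dict[str, list[str]] = {}
    for s in ("discovery", "validation"):
        block = per_sample[per_sample["set_label"] == s]
        mat = confusion_matrix(
            block["true_group"], block["pred_group"], ["carcinoid", "NEC"]
        )
        confusion[s] = mat
        level1_acc = accuracy_from_confusion(mat)
        correct1 = block[block["true_group"] == block["pred_group"]]
        if len(correct1):
            sub_acc = float((correct1["true_type"] == correct1["pred_type"]).mean())
        else:
            sub_acc = float("nan")
        accuracy[s] = {"level1": level1_acc, "subtype_given_level1": sub_acc}
        misclassified[s] = sorted(
            block.index[block["true_group"] != block["pred_group"]]
        )
    return EvaluationReport(per_sample, confusion, accuracy, misclassified)


def correlate_markers(
    rf: RFMatrix, ann: SampleTable, markers: list[str]
) -> pd.DataFrame:
    """Associate each marker's log2 rf with pathology covariates.

    Per marker: Spearman correlation with Ki-67 and with mitotic count;
    Mann-Whitney comparisons across necrosis states (yes vs no and all
    pairwise) and between node-negative (pN = 0) and node-positive
    (pN >= 1) samples.  Constant covariates yield rows flagged undefined,
    not errors.  Returns one tidy table.
    """
    columns = ["marker", "covariate", "comparison", "statistic", "p_value",
               "effect_size", "n", "note"]
    rows: list[dict] = []
    log2 = rf.log2()
    tbl = ann.table.loc[rf.sample_ids]

    def add(marker, covariate, comparison, result: TestResult | None, note=""):
        rows.append(
            {
                "marker": marker,
                "covariate": covariate,
                "comparison": comparison,
                "statistic": None if result is None else result.statistic,
                "p_value": None if result is None else result.p_value,
                "effect_size": None if result is None else result.effect_size,
                "n": None if result is None else sum(result.n),
                "note": note,
            }
        )

    for marker in markers:
        if marker not in log2.columns:
            raise KeyError(f"marker {marker!r} absent from rf matrix")
        x = log2[marker]
        for cov in ("ki67_percent", "mitoses_per_2mm2"):
            try:
                add(marker, cov, "spearman", spearman(x, tbl[cov].astype(float)))
            except UndefinedStatisticError:
                add(marker, cov, "spearman", None, note="undefined")
        nec = tbl["necrosis"]
        pairs = [("yes", "no"), ("yes", "focal"), ("no", "focal")]
        for a, b in pairs:
            xa, xb = x[nec == a], x[nec == b]
            if len(xa) == 0 or len(xb) == 0:
                add(marker, "necrosis", f"{a}_vs_{b}", None, note="undefined")
            else:
                add(marker, "necrosis", f"{a}_vs_{b}", mann_whitney(xa, xb))
        pn = tbl["pN"]
        x0 = x[pn == "0"]
        x1 = x[pn.isin(["1", "2"])]
        if len(x0) == 0 or len(x1) == 0:
            add(marker, "pN", "0_vs_1plus", None, note="undefined")
        else:
            add(marker, "pN", "0_vs_1plus", mann_whitney(x0, x1))
    return pd.DataFrame(rows, columns=columns)
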