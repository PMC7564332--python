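"""High-expression analysis, the miR-21/miR-375 ratio, and ensemble
univariate feature ranking.

The ranking mechanism scores every feature with a basket of fourteen
established univariate two-class criteria, within each training portion of a
stratified k-fold scheme, converts scores to ranks (1 = most
discriminative), and aggregates by the mean rank over methods x folds.  The
basket is a fixed, documented choice and can be restricted via the
``methods`` argument; the contract is the ensemble mechanism, not the exact
basket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from nen_mirna.core_io import RFMatrix, SampleTable
from nen_mirna.stats import TestResult, mann_whitney

logger = logging.getLogger(__name__)

METHODS = (
    "pooled_t",
    "welch_t",
    "ranksum_z",
    "auc",
    "bhattacharyya",
    "sym_kl",
    "fisher_ratio",
    "golub_snr",
    "median_diff",
    "mutual_info",
    "chi2_median_split",
    "gini_split",
    "point_biserial",
    "relieff",
)

_VAR_FLOOR = 1e-12


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def top_expressed(rf: RFMatrix, fraction: float = 0.005) -> list[tuple[str, float]]:
    """Features ranked by median rf, truncated to the top ``fraction``.

    k = round(fraction * F), at least 1; ties broken by mean rf, then name.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if rf.rf.shape[1] == 0:
        raise ValueError("empty rf matrix")
    med = rf.rf.median(axis=0)
    mean = rf.rf.mean(axis=0)
    order = sorted(rf.feature_ids, key=lambda f: (-med[f], -mean[f], f))
    k = max(1, _round_half_up(fraction * len(order)))
    return [(f, float(med[f])) for f in order[:k]]


def ratio_statistic(
    rf: RFMatrix,
    ann: SampleTable,
    numerator: str = "miR-21",
    denominator: str = "miR-375",
) -> tuple[pd.Series, TestResult]:
    """Per-sample log2 expression ratio and its carcinoid-vs-NEC comparison.

    ratio = log2((rf_num + eps) / (rf_den + eps)) with the matrix
    pseudocount; the group comparison is a Mann-Whitney test with carcinoids
    as the first group, so a negative rank-biserial effect size means the
    ratio is lower in carcinoids.
    """
    for f in (numerator, denominator):
        if f not in rf.rf.columns:
            raise KeyError(f"feature {f!r} absent from rf matrix")
    eps = rf.pseudocount
    ratio = np.log2((rf.rf[numerator] + eps) / (rf.rf[denominator] + eps))
    group = ann.table.loc[rf.sample_ids].index.map(dict(zip(ann.sample_ids, ann.group)))
    carc = ratio[np.asarray(group == "carcinoid")]
    nec = ratio[np.asarray(group == "NEC")]
    return ratio, mann_whitney(carc, nec)


# ---------------------------------------------------------------------------
# Univariate scoring basket
# ---------------------------------------------------------------------------


def _moments(x1: np.ndarray, x2: np.ndarray):
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    return m1, m2, v1, v2


def _ratio_or_extreme(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with den == 0 mapped to 0 (num == 0) or +inf (num > 0)."""
    out = np.full(num.shape, np.inf)
    np.divide(num, den, out=out, where=den > 0)
    out[(den <= 0) & (num == 0)] = 0.0
    return out


def _rank_stats(x1: np.ndarray, x2: np.ndarray):
    n1, n2 = x1.shape[0], x2.shape[0]
    pooled = np.vstack([x1, x2])
    ranks = sps.rankdata(pooled, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u_greater = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    tie = np.zeros(pooled.shape[1])
    for j in range(pooled.shape[1]):
        _, counts = np.unique(pooled[:, j], return_counts=True)
        tie[j] = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    z = np.zeros(pooled.shape[1])
    np.divide(
        np.abs(u_greater - n1 * n2 / 2.0), np.sqrt(var), out=z, where=var > 0
    )
    auc = u_greater / (n1 * n2)
    return z, auc


def _mutual_info(x1: np.ndarray, x2: np.ndarray, bins: int = 8) -> np.ndarray:
    pooled = np.vstack([x1, x2])
    n1 = x1.shape[0]
    n = pooled.shape[0]
    lo = pooled.min(axis=0)
    span = np.ptp(pooled, axis=0)
    out = np.zeros(pooled.shape[1])
    labels = np.repeat([0, 1], [n1, n - n1])
    for j in range(pooled.shape[1]):
        if span[j] == 0:
            continue
        idx = np.minimum(
            ((pooled[:, j] - lo[j]) / span[j] * bins).astype(int), bins - 1
        )
        joint = np.zeros((2, bins))
        np.add.at(joint, (labels, idx), 1.0)
        joint /= n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = joint * np.log(joint / (px * py))
        out[j] = np.nansum(term)
    return np.maximum(out, 0.0)


def _chi2_median_split(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    pooled = np.vstack([x1, x2])
    med = np.median(pooled, axis=0)
    a = (x1 > med).sum(axis=0).astype(float)  # class 1 above
    b = x1.shape[0] - a
    c = (x2 > med).sum(axis=0).astype(float)
    d = x2.shape[0] - c
    n = pooled.shape[0]
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = n * (a * d - b * c) ** 2
    return _ratio_or_extreme(num, denom) * (denom > 0)


def _gini_split(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    pooled = np.vstack([x1, x2])
    n1 = x1.shape[0]
    n = pooled.shape[0]
    labels = np.repeat([1.0, 0.0], [n1, n - n1])
    p = n1 / n
    parent = 2.0 * p * (1.0 - p)
    out = np.zeros(pooled.shape[1])
    for j in range(pooled.shape[1]):
        order = np.argsort(pooled[:, j], kind="stable")
        v = pooled[order, j]
        y = labels[order]
        cum1 = np.cumsum(y)[:-1]
        left_n = np.arange(1, n)
        right_n = n - left_n
        p_l = cum1 / left_n
        p_r = (n1 - cum1) / right_n
        child = left_n / n * 2 * p_l * (1 - p_l) + right_n / n * 2 * p_r * (1 - p_r)
        valid = v[:-1] != v[1:]
        if valid.any():
            out[j] = parent - child[valid].min()
    return out


def _relieff(x1: np.ndarray, x2: np.ndarray, k: int = 3) -> np.ndarray:
    """Per-feature ReliefF weight with k nearest hits/misses in the feature's
    own 1-D space; normalized by the feature's value range."""
    pooled = np.vstack([x1, x2])
    n1 = x1.shape[0]
    n, nf = pooled.shape
    labels = np.repeat([0, 1], [n1, n - n1])
    span = np.ptp(pooled, axis=0)
    same = labels[:, None] == labels[None, :]
    out = np.zeros(nf)
    k_hit = min(k, min(n1, n - n1) - 1)
    k_miss = min(k, min(n1, n - n1))
    if k_hit < 1 or k_miss < 1:
        return out
    for j in range(nf):
        if span[j] == 0:
            continue
        d = np.abs(pooled[:, j, None] - pooled[None, :, j])
        d_hit = np.where(same, d, np.inf)
        np.fill_diagonal(d_hit, np.inf)
        d_miss = np.where(~same, d, np.inf)
        hit = np.sort(d_hit, axis=1)[:, :k_hit].mean(axis=1)
        miss = np.sort(d_miss, axis=1)[:, :k_miss].mean(axis=1)
        out[j] = (miss - hit).mean() / span[j]
    return out


def score_features(method: str, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Score every column of two class matrices; higher = more discriminative.

    Zero-variance (constant) features score 0 for variance-based methods.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples")
    n1, n2 = x1.shape[0], x2.shape[0]
    if method in ("pooled_t", "welch_t", "bhattacharyya", "sym_kl", "fisher_ratio",
                  "golub_snr", "point_biserial"):
        m1, m2, v1, v2 = _moments(x1, x2)
        d = m1 - m2
    if method == "pooled_t":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        return _ratio_or_extreme(np.abs(d), denom)
    if method == "welch_t":
        denom = np.sqrt(v1 / n1 + v2 / n2)
        return _ratio_or_extreme(np.abs(d), denom)
    if method == "ranksum_z":
        z, _ = _rank_stats(x1, x2)
        return z
    if method == "auc":
        _, auc = _rank_stats(x1, x2)
        return np.abs(auc - 0.5)
    if method == "bhattacharyya":
        both_zero = (v1 <= 0) & (v2 <= 0)
        v1f = np.maximum(v1, _VAR_FLOOR)
        v2f = np.maximum(v2, _VAR_FLOOR)
        bd = 0.25 * np.log(0.25 * (v1f / v2f + v2f / v1f + 2.0)) + 0.25 * d**2 / (
            v1f + v2f
        )
        return np.where(both_zero, np.where(d == 0, 0.0, np.inf), bd)
    if method == "sym_kl":
        both_zero = (v1 <= 0) & (v2 <= 0)
        v1f = np.maximum(v1, _VAR_FLOOR)
        v2f = np.maximum(v2, _VAR_FLOOR)
        kl = 0.5 * ((v1f + d**2) / v2f + (v2f + d**2) / v1f) - 1.0
        return np.where(both_zero, np.where(d == 0, 0.0, np.inf), np.maximum(kl, 0.0))
    if method == "fisher_ratio":
        return _ratio_or_extreme(d**2, v1 + v2)
    if method == "golub_snr":
        return _ratio_or_extreme(np.abs(d), np.sqrt(v1) + np.sqrt(v2))
    if method == "median_diff":
        return np.abs(np.median(x1, axis=0) - np.median(x2, axis=0))
    if method == "mutual_info":
        return _mutual_info(x1, x2)
    if method == "chi2_median_split":
        return _chi2_median_split(x1, x2)
    if method == "gini_split":
        return _gini_split(x1, x2)
    if method == "point_biserial":
        pooled = np.vstack([x1, x2])
        labels = np.repeat([1.0, 0.0], [n1, n2])
        pv = pooled.var(axis=0)
        lv = labels.var()
        cov = ((pooled - pooled.mean(axis=0)) * (labels - labels.mean())[:, None]).mean(
            axis=0
        )
        denom = np.sqrt(pv * lv)
        return _ratio_or_extreme(np.abs(cov), denom) * (denom > 0)
    if method == "relieff":
        return _relieff(x1, x2)
    raise ValueError(f"unknown scoring method {method!r}")


def score_feature(method: str, x, y) -> float:
    """Score a single feature's two class samples (see :func:`score_features`)."""
    return float(
        score_features(method, np.asarray(x, float)[:, None], np.asarray(y, float)[:, None])[0]
    )


# ---------------------------------------------------------------------------
# Ensemble ranking
# ---------------------------------------------------------------------------


@dataclass
class FeatureRanking:
    """Per-method, per-fold feature ranks and the aggregated score.

    ``ranks`` has shape (n_methods, n_folds, n_features); rank 1 is the most
    discriminative, with mean-rank ties.  The aggregated score is the mean
    (or median) rank over methods x folds and lies in [1, F].
    """

    features: list[str]
    methods: tuple[str, ...]
    n_folds: int
    fold_assignment: pd.Series
    ranks: np.ndarray
    aggregated: pd.Series
    seed: int
    aggregation: str = "mean"

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "n_folds": self.n_folds,
            "seed": self.seed,
            "aggregation": self.aggregation,
            "fold_assignment": {k: int(v) for k, v in self.fold_assignment.items()},
            "aggregated_score": {f: float(s) for f, s in self.aggregated.items()},
        }


def stratified_folds(labels: pd.Series, n_folds: int, seed: int) -> pd.Series:
    """Deterministic stratified fold assignment (fold ids 0..n_folds-1)."""
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=labels.index, dtype=int)
    for cls in sorted(labels.unique()):
        ids = list(labels.index[labels == cls])
        perm = rng.permutation(len(ids))
        for pos, i in enumerate(perm):
            fold.loc[ids[i]] = pos % n_folds
    return fold


def ensemble_rank(
    rf: RFMatrix,
    labels: pd.Series,
    n_folds: int = 5,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
    aggregation: str = "mean",
    within_folds: bool = True,
) -> FeatureRanking:
    """Rank features by mean rank over the scoring basket and CV folds.

    Scoring uses each fold's *training* portion only (``within_folds=True``),
    so feature selection stays honest with respect to later cross-validation;
    ``within_folds=False`` scores once on the full sample set.  A class with
    fewer than ``n_folds`` members reduces the fold count (floor 2) with a
    warning.  Deterministic under ``seed``.
    """
    labels = labels.loc[rf.sample_ids]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"ensemble_rank requires exactly 2 classes, got {classes}")
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown scoring methods: {sorted(unknown)}")
    min_class = int(labels.value_counts().min())
    if not within_folds:
        n_folds_used = 1
    elif min_class < n_folds:
        n_folds_used = max(2, min_class)
        logger.warning(
            "smallest class has %d samples; reducing folds from %d to %d",
            min_class, n_folds, n_folds_used,
        )
    else:
        n_folds_used = n_folds
    log2 = rf.log2()
    features = rf.feature_ids
    nf = len(features)
    if within_folds:
        fold = stratified_folds(labels, n_folds_used, seed)
    else:
        fold = pd.Series(-1, index=labels.index, dtype=int)
    ranks = np.zeros((len(methods), n_folds_used, nf))
    for f in range(n_folds_used):
        train_ids = list(fold.index[fold != f]) if within_folds else list(fold.index)
        x1 = log2.loc[[s for s in train_ids if labels[s] == classes[0]]].to_numpy()
        x2 = log2.loc[[s for s in train_ids if labels[s] == classes[1]]].to_numpy()
        for mi, method in enumerate(methods):
            scores = score_features(method, x1, x2)
            ranks[mi, f] = sps.rankdata(-scores, method="average")
    if aggregation == "mean":
        agg = ranks.reshape(-1, nf).mean(axis=0)
    else:
        agg = np.median(ranks.reshape(-1, nf), axis=0)
    return FeatureRanking(
        features=features,
        methods=tuple(methods),
        n_folds=n_folds_used,
        fold_assignment=fold,
        ranks=ranks,
        aggregated=pd.Series(agg, index=features),
        seed=seed,
        aggregation=aggregation,
    )


def select_top_fraction(ranking: FeatureRanking, fraction: float = 0.05) -> list[str]:
    """The best-ranked ``fraction`` of features (k = round(fraction * F),
    at least 1), name-lexicographic tie-break."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if not ranking.features:
        raise ValueError("empty ranking")
    order = sorted(ranking.features, key=lambda f: (ranking.aggregated[f], f))
    k = max(1, _round_half_up(fraction * len(order)))
    return order[:k]
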