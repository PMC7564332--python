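"""Count-profile preprocessing: feature-kind filtering, correlation-based
outlier detection, and the per-sample 95th-percentile abundance filter.

The canonical order of operations is: kind filter -> relative-frequency
normalization -> outlier removal -> abundance filter (see
:func:`preprocess`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from nen_mirna.core_io import CountMatrix, RFMatrix, SampleTable, normalize_rf

logger = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """What preprocessing removed and with which thresholds.

    ``removed_samples`` maps sample id -> leave-one-out correlation to its
    tumor-type median profile; ``removed_features`` groups dropped feature
    ids by reason (star / nonhuman / calibrator / abundance_filter).
    """

    removed_samples: dict[str, float] = field(default_factory=dict)
    removed_features: dict[str, list[str]] = field(default_factory=dict)
    thresholds: dict[str, float | str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_samples": {k: float(v) for k, v in self.removed_samples.items()},
            "removed_features": self.removed_features,
            "thresholds": self.thresholds,
        }

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        merged = PreprocessReport(
            removed_samples={**self.removed_samples, **other.removed_samples},
            removed_features={**self.removed_features},
            thresholds={**self.thresholds, **other.thresholds},
        )
        for reason, feats in other.removed_features.items():
            merged.removed_features.setdefault(reason, [])
            merged.removed_features[reason] = list(
                dict.fromkeys(merged.removed_features[reason] + feats)
            )
        return merged


def filter_feature_kinds(cm: CountMatrix) -> tuple[CountMatrix, PreprocessReport]:
    """Retain only mature-miRNA features for the analysis matrix.

    STAR passenger strands and non-human sequences are discarded;
    calibrators are excluded here too (they are used separately for miRNA
    content). An all-filtered matrix is allowed, with a warning.
    """
    mature = cm.features_of_kind("mature")
    report = PreprocessReport(
        removed_features={
            "star": cm.features_of_kind("star"),
            "nonhuman": cm.features_of_kind("nonhuman"),
            "calibrator": cm.features_of_kind("calibrator"),
        }
    )
    if not mature:
        logger.warning("no mature features remain after kind filtering")
    return cm.subset_features(mature), report


def detect_outliers(
    rf: RFMatrix,
    ann: SampleTable,
    method: str = "spearman",
    threshold: float | None = None,
    floor: float = 0.3,
) -> PreprocessReport:
    """Flag samples whose log2 rf profile decorrelates from their tumor type.

    For each sample, the correlation (Spearman by default, Pearson via
    ``method="pearson"``) of its log2 rf vector with the element-wise median
    log2 profile of the *other* samples of its type is computed
    (leave-one-out).  Samples with correlation strictly below the threshold
    are flagged.  The default threshold is
    ``max(median(correlations) - 3 * MAD(correlations), floor)`` with the
    (unscaled) median absolute deviation; tumor types with fewer than 3
    samples are skipped with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    log2 = rf.log2()
    corrs: dict[str, float] = {}
    ttype = ann.table.loc[rf.sample_ids, "tumor_type"]
    for t in sorted(ttype.unique()):
        ids = list(ttype.index[ttype == t])
        if len(ids) < 3:
            logger.warning("tumor type %s has <3 samples; outlier check skipped", t)
            continue
        block = log2.loc[ids].to_numpy()
        for i, sid in enumerate(ids):
            others = np.delete(block, i, axis=0)
            centroid = np.median(others, axis=0)
            x = block[i]
            if method == "spearman":
                x, centroid = sps.rankdata(x), sps.rankdata(centroid)
            if np.ptp(x) == 0 or np.ptp(centroid) == 0:
                corrs[sid] = 0.0
                continue
            corrs[sid] = float(np.corrcoef(x, centroid)[0, 1])
    values = np.array(list(corrs.values()))
    if threshold is None and values.size:
        mad = float(np.median(np.abs(values - np.median(values))))
        threshold = max(float(np.median(values)) - 3.0 * mad, floor)
    elif threshold is None:
        threshold = floor
    removed = {sid: c for sid, c in corrs.items() if c < threshold}
    return PreprocessReport(
        removed_samples=removed,
        thresholds={"outlier_correlation": float(threshold), "outlier_method": method},
    )


def abundance_filter(
    rf: RFMatrix,
    ann: SampleTable,
    percentile: float = 95.0,
    min_sample_fraction: float = 0.05,
    scope: str = "every_type",
) -> tuple[RFMatrix, PreprocessReport]:
    """Keep features expressed above the per-sample ``percentile`` in more
    than ``min_sample_fraction`` of samples of each tumor type.

    A feature "passes" in a sample iff its rf strictly exceeds that sample's
    percentile of rf values over all mature features (zeros included;
    linear-interpolation quantile).  With ``scope="every_type"`` (default) a
    feature is retained iff its pass fraction strictly exceeds
    ``min_sample_fraction`` in every tumor type; ``scope="any_type"``
    requires only one type.  Retained rf values are untouched, so filtered
    rows no longer sum to 1.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must lie strictly between 0 and 100")
    if scope not in ("every_type", "any_type"):
        raise ValueError("scope must be 'every_type' or 'any_type'")
    values = rf.rf.to_numpy(dtype=float)
    cutoffs = np.percentile(values, percentile, axis=1)  # linear interpolation
    passes = values > cutoffs[:, None]
    ttype = ann.table.loc[rf.sample_ids, "tumor_type"]
    per_type = []
    for t in sorted(ttype.unique()):
        mask = (ttype == t).to_numpy()
        per_type.append(passes[mask].mean(axis=0))
    per_type = np.vstack(per_type)
    if scope == "every_type":
        keep = np.all(per_type > min_sample_fraction, axis=0)
    else:
        keep = np.any(per_type > min_sample_fraction, axis=0)
    kept = [f for f, k in zip(rf.feature_ids, keep) if k]
    dropped = [f for f, k in zip(rf.feature_ids, keep) if not k]
    out = RFMatrix(rf.rf[kept].copy(), pseudocount=rf.pseudocount, normalized=False)
    report = PreprocessReport(
        removed_features={"abundance_filter": dropped},
        thresholds={
            "abundance_percentile": float(percentile),
            "abundance_min_sample_fraction": float(min_sample_fraction),
            "abundance_scope": scope,
        },
    )
    return out, report


def preprocess(
    cm: CountMatrix,
    ann: SampleTable,
    outlier_method: str = "spearman",
    outlier_threshold: float | None = None,
    percentile: float = 95.0,
    min_sample_fraction: float = 0.05,
    scope: str = "every_type",
) -> tuple[RFMatrix, SampleTable, PreprocessReport]:
    """Full preprocessing chain: kind filter -> normalize -> outlier removal
    -> abundance filter.  Returns the filtered rf matrix, the annotation
    table restricted to retained samples, and a merged report."""
    mature_cm, kind_report = filter_feature_kinds(cm)
    rf = normalize_rf(mature_cm)
    outlier_report = detect_outliers(
        rf, ann, method=outlier_method, threshold=outlier_threshold
    )
    keep_samples = [s for s in rf.sample_ids if s not in outlier_report.removed_samples]
    rf = rf.subset_samples(keep_samples)
    ann_kept = ann.subset(keep_samples)
    filtered, ab_report = abundance_filter(
        rf,
        ann_kept,
        percentile=percentile,
        min_sample_fraction=min_sample_fraction,
        scope=scope,
    )
    report = kind_report.merge(outlier_report).merge(ab_report)
    report.thresholds["log2_pseudocount"] = float(rf.pseudocount)
    return filtered, ann_kept, report
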