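"""Synthetic lung-NEN cohort generator.

Generates sample x miRNA count matrices with the statistical structure the
downstream analysis assumes: four tumor types (TC, AC, SCLC, LCNEC) with
realistic per-type sample counts, log-normally distributed sequencing
depths, Dirichlet-multinomial mature-miRNA compositions with a heavy-tailed
(Zipf) baseline in which a handful of named miRNAs carry ~30% of reads,
planted differential effects on named marker miRNAs, STAR / non-human /
calibrator reads, and pathology covariates (Ki-67, mitoses, necrosis, pN)
whose type-level distributions track the planted marker levels.

The generative model, per sample of tumor type t:

    depth   ~ round(10 ** Normal(depth_log10_mean, depth_log10_sd))
    p       ~ Dirichlet(alpha_t),  alpha_t = baseline * concentration,
              with each planted effect multiplying alpha_t[feature] by
              2**log2_fold_change for the types it applies to
    counts  ~ Multinomial(depth, p)

so the expected log2 fold change of a planted feature's relative frequency
between affected and baseline groups equals the configured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from nen_mirna.cistrons import LUNG_NEN_CISTRONS
from nen_mirna.core_io import (
    ANNOTATION_COLUMNS,
    CountMatrix,
    CistronMap,
    NEC_TYPES,
    SampleTable,
    TUMOR_TYPES,
)

# The eight consistently most abundant mature miRNAs in lung NENs and their
# baseline median shares of mature reads (fractions, summing to ~0.33).
HIGH_ABUNDANCE_BASELINE = {
    "miR-375": 0.082,
    "miR-21": 0.079,
    "miR-143": 0.041,
    "miR-141": 0.029,
    "let-7a": 0.029,
    "let-7f": 0.025,
    "miR-30d": 0.024,
    "miR-148a": 0.020,
}

# Classification marker miRNAs; baseline share chosen at the top of the
# low-abundance marker range so they remain detectable above the per-sample
# 95th-percentile abundance filter in every tumor type.
MARKER_MIRNAS = (
    "miR-18a",
    "miR-155",
    "miR-17",
    "miR-103",
    "miR-127",
    "miR-301a",
    "miR-106b",
    "miR-25",
)
MARKER_BASELINE_FRACTION = 0.0017

# Share of mature reads carried by the 13-member let-7 family cistron and by
# miR-145 (partner of miR-143 in its bicistronic cluster).
CLUSTER98_TOTAL_FRACTION = 0.10
MIR145_FRACTION = 0.003


@dataclass(frozen=True)
class PlantedEffect:
    """A differential-expression effect planted into the generative model.

    The Dirichlet parameter of ``feature`` is multiplied by
    ``2**log2_fold_change`` for every tumor type in ``types``.
    """

    feature: str
    types: tuple[str, ...]
    log2_fold_change: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_fold_change):
            raise ValueError("log2_fold_change must be finite")
        bad = set(self.types) - set(TUMOR_TYPES)
        if bad:
            raise ValueError(f"unknown tumor types in planted effect: {sorted(bad)}")


def default_planted_effects() -> list[PlantedEffect]:
    """The study's marker structure: miR-18a/-155 and a miR-21-up /
    miR-375-down shift in NECs, miR-17/-103 up and miR-127 down in AC vs TC,
    miR-301a/-106b/-25 up in SCLC vs LCNEC."""
    nec = tuple(NEC_TYPES)
    return [
        PlantedEffect("miR-18a", nec, 3.0),
        PlantedEffect("miR-155", nec, 3.0),
        PlantedEffect("miR-21", nec, 1.5),
        PlantedEffect("miR-375", nec, -1.5),
        PlantedEffect("miR-17", ("AC",), 3.0),
        PlantedEffect("miR-103", ("AC",), 3.0),
        PlantedEffect("miR-127", ("AC",), -3.0),
        PlantedEffect("miR-301a", ("SCLC",), 3.0),
        PlantedEffect("miR-106b", ("SCLC",), 3.0),
        PlantedEffect("miR-25", ("SCLC",), 3.0),
    ]


# Type-level pathology parameters: Ki-67 % and mitoses per 2 mm^2 medians by
# tumor type (log-normal noise around them), deterministic necrosis pattern,
# and pN category probabilities (unknown, 0, 1, 2).
KI67_MEDIANS = {"TC": 1.0, "AC": 5.0, "SCLC": 61.0, "LCNEC": 27.5}
MITOSES_MEDIANS = {"TC": 0.3, "AC": 3.9, "SCLC": 88.0, "LCNEC": 27.0}
NECROSIS_BY_TYPE = {"TC": "no", "AC": "focal", "SCLC": "yes", "LCNEC": "yes"}
PN_PROBS = {
    "TC": (2 / 14, 10 / 14, 2 / 14, 0.0),
    "AC": (0.0, 12 / 15, 1 / 15, 2 / 15),
    "SCLC": (1 / 11, 7 / 11, 1 / 11, 2 / 11),
    "LCNEC": (1 / 15, 7 / 15, 5 / 15, 2 / 15),
}
PN_LEVELS_ORDER = ("unknown", "0", "1", "2")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 14/15/11/15 samples of
    TC/AC/SCLC/LCNEC, 1600 mature miRNA features, sequencing depths with
    median ~1.5M mature reads (range ~7e4 - 1.4e7), and the planted marker
    effects of :func:`default_planted_effects`.
    """

    n_per_type: dict[str, int] = field(
        default_factory=lambda: {"TC": 14, "AC": 15, "SCLC": 11, "LCNEC": 15}
    )
    n_features: int = 1600
    concentration: float = 50.0
    zipf_exponent: float = 1.05
    planted_effects: list[PlantedEffect] = field(default_factory=default_planted_effects)
    depth_log10_mean: float = 6.17  # 10**6.17 ~ 1.5M mature reads
    depth_log10_sd: float = 0.45
    star_fraction: float = 0.10
    nonhuman_fraction: float = 0.05
    n_star_features: int = 50
    n_nonhuman_features: int = 20
    calibrator_reads_mean: float = 20000.0
    ki67_log_sd: float = 0.6
    mitoses_log_sd: float = 0.6
    total_rna_median_ug: float = 5.0
    total_rna_log_sd: float = 0.5
    fraction_discovery: float = 0.8
    outlier_samples: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_type) != set(TUMOR_TYPES):
            raise ValueError(f"n_per_type must cover exactly {TUMOR_TYPES}")
        if any(n < 1 for n in self.n_per_type.values()):
            raise ValueError("all per-type sample counts must be >= 1")
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0")
        if self.n_features < len(HIGH_ABUNDANCE_BASELINE) + len(MARKER_MIRNAS) + 20:
            raise ValueError("n_features too small to hold the named miRNAs")


def feature_names_and_baseline(cfg: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    """Mature feature names and baseline composition (fractions summing to 1).

    Named features (the eight high-abundance miRNAs, the classification
    markers, the let-7 cistron members and miR-145) are pinned to fixed
    fractions; the remaining mass follows a Zipf law over filler features.
    """
    names: list[str] = []
    fracs: list[float] = []
    for name, frac in HIGH_ABUNDANCE_BASELINE.items():
        names.append(name)
        fracs.append(frac)
    cluster98 = LUNG_NEN_CISTRONS["cluster-mir-98"]
    w = np.arange(1, len(cluster98) + 1, dtype=float) ** -cfg.zipf_exponent
    w = w / w.sum() * CLUSTER98_TOTAL_FRACTION
    names.extend(cluster98)
    fracs.extend(w.tolist())
    names.append("miR-145")
    fracs.append(MIR145_FRACTION)
    for m in MARKER_MIRNAS:
        names.append(m)
        fracs.append(MARKER_BASELINE_FRACTION)
    n_filler = cfg.n_features - len(names)
    filler_w = np.arange(1, n_filler + 1, dtype=float) ** -cfg.zipf_exponent
    remaining = 1.0 - float(np.sum(fracs))
    filler_w = filler_w / filler_w.sum() * remaining
    names.extend(f"miR-sim-{i:04d}" for i in range(1, n_filler + 1))
    fracs.extend(filler_w.tolist())
    baseline = np.asarray(fracs, dtype=float)
    return names, baseline / baseline.sum()


def type_dirichlet_alphas(cfg: SyntheticConfig) -> tuple[list[str], pd.DataFrame]:
    """Per-tumor-type Dirichlet parameter vectors (types x features)."""
    names, baseline = feature_names_and_baseline(cfg)
    name_index = {n: i for i, n in enumerate(names)}
    alphas = {}
    for t in TUMOR_TYPES:
        a = baseline * cfg.concentration
        for eff in cfg.planted_effects:
            if eff.feature not in name_index:
                raise ValueError(
                    f"planted feature {eff.feature!r} is not among the generated features"
                )
            if t in eff.types:
                a = a.copy()
                a[name_index[eff.feature]] *= 2.0**eff.log2_fold_change
        alphas[t] = a
    return names, pd.DataFrame(alphas, index=names).T


def split_sets(
    tumor_type: pd.Series, fraction_discovery: float = 0.8, seed: int = 0
) -> pd.Series:
    """Stratified discovery/validation assignment.

    Per tumor type, round((1 - fraction_discovery) * n) samples (at least 1)
    go to the validation set; assignment is deterministic under ``seed``.
    """
    if not (0.0 < fraction_discovery < 1.0):
        raise ValueError("fraction_discovery must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    labels = pd.Series("discovery", index=tumor_type.index)
    for t in sorted(tumor_type.unique()):
        ids = list(tumor_type.index[tumor_type == t])
        if len(ids) < 2:
            raise ValueError(f"tumor type {t!r} has fewer than 2 samples")
        n_val = max(1, int(np.floor((1.0 - fraction_discovery) * len(ids) + 0.5)))
        chosen = rng.choice(len(ids), size=n_val, replace=False)
        labels.loc[[ids[i] for i in chosen]] = "validation"
    return labels


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[CountMatrix, SampleTable, CistronMap, dict]:
    """Draw one synthetic cohort.

    Returns the count matrix (mature + STAR + non-human + calibrator
    features), the sample annotation table (with stratified
    discovery/validation labels), the packaged cistron map, and a truth
    record listing the planted features and per-type expected compositions.
    Identical configuration (including seed) yields identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    names, alphas = type_dirichlet_alphas(cfg)

    sample_ids: list[str] = []
    types: list[str] = []
    for t in TUMOR_TYPES:
        for i in range(cfg.n_per_type[t]):
            sample_ids.append(f"{t}-{i + 1:02d}")
            types.append(t)
    n_samples = len(sample_ids)

    depths = np.round(
        10.0 ** rng.normal(cfg.depth_log10_mean, cfg.depth_log10_sd, size=n_samples)
    ).astype(np.int64)
    depths = np.maximum(depths, 1000)

    mature = np.zeros((n_samples, cfg.n_features), dtype=np.int64)
    for i, t in enumerate(types):
        p = rng.dirichlet(alphas.loc[t].to_numpy())
        mature[i] = rng.multinomial(depths[i], p)

    if cfg.outlier_samples:
        k = min(cfg.outlier_samples, n_samples)
        which = rng.choice(n_samples, size=k, replace=False)
        for i in which:
            mature[i] = rng.permutation(mature[i])
        outlier_ids = [sample_ids[i] for i in sorted(which)]
    else:
        outlier_ids = []

    star_totals = rng.poisson(cfg.star_fraction * depths).astype(np.int64)
    nonhuman_totals = rng.poisson(cfg.nonhuman_fraction * depths).astype(np.int64)
    star = np.vstack(
        [
            rng.multinomial(tot, np.full(cfg.n_star_features, 1.0 / cfg.n_star_features))
            for tot in star_totals
        ]
    )
    nonhuman = np.vstack(
        [
            rng.multinomial(
                tot, np.full(cfg.n_nonhuman_features, 1.0 / cfg.n_nonhuman_features)
            )
            for tot in nonhuman_totals
        ]
    )
    calibrator = np.maximum(rng.poisson(cfg.calibrator_reads_mean, size=n_samples), 1)

    star_names = [f"{names[i]}*" for i in range(cfg.n_star_features)]
    nonhuman_names = [f"nonhuman-{i + 1:03d}" for i in range(cfg.n_nonhuman_features)]
    all_names = names + star_names + nonhuman_names + ["calibrator-mix"]
    counts = pd.DataFrame(
        np.hstack([mature, star, nonhuman, calibrator[:, None]]),
        index=sample_ids,
        columns=all_names,
    )
    kinds = pd.Series(
        ["mature"] * cfg.n_features
        + ["star"] * cfg.n_star_features
        + ["nonhuman"] * cfg.n_nonhuman_features
        + ["calibrator"],
        index=all_names,
    )
    cm = CountMatrix(counts, kinds)

    type_series = pd.Series(types, index=sample_ids)
    set_labels = split_sets(type_series, cfg.fraction_discovery, seed=cfg.seed)
    ann_rows = {
        "tumor_type": type_series,
        "set_label": set_labels,
        "ki67_percent": pd.Series(
            [
                float(KI67_MEDIANS[t] * np.exp(rng.normal(0.0, cfg.ki67_log_sd)))
                for t in types
            ],
            index=sample_ids,
        ),
        "mitoses_per_2mm2": pd.Series(
            [
                float(MITOSES_MEDIANS[t] * np.exp(rng.normal(0.0, cfg.mitoses_log_sd)))
                for t in types
            ],
            index=sample_ids,
        ),
        "necrosis": pd.Series([NECROSIS_BY_TYPE[t] for t in types], index=sample_ids),
        "pN": pd.Series(
            [
                PN_LEVELS_ORDER[rng.choice(4, p=PN_PROBS[t])]
                for t in types
            ],
            index=sample_ids,
        ),
        "total_rna_input_ug": pd.Series(
            cfg.total_rna_median_ug
            * np.exp(rng.normal(0.0, cfg.total_rna_log_sd, size=n_samples)),
            index=sample_ids,
        ),
    }
    ann = SampleTable(pd.DataFrame(ann_rows, columns=list(ANNOTATION_COLUMNS)))

    expected_rf = alphas.div(alphas.sum(axis=1), axis=0)
    truth = {
        "seed": cfg.seed,
        "planted_features": sorted({e.feature for e in cfg.planted_effects}),
        "planted_effects": [
            {
                "feature": e.feature,
                "types": list(e.types),
                "log2_fold_change": e.log2_fold_change,
            }
            for e in cfg.planted_effects
        ],
        "outlier_samples": outlier_ids,
        "expected_rf_by_type": {
            t: {f: float(expected_rf.loc[t, f]) for f in truth_features(cfg)}
            for t in TUMOR_TYPES
        },
    }
    return cm, ann, LUNG_NEN_CISTRONS, truth


def truth_features(cfg: SyntheticConfig) -> list[str]:
    named = list(HIGH_ABUNDANCE_BASELINE) + list(MARKER_MIRNAS)
    planted = sorted({e.feature for e in cfg.planted_effects})
    return sorted(set(named) | set(planted))


def null_config(**overrides) -> SyntheticConfig:
    """A configuration with no planted effects (the null cohort)."""
    return replace(SyntheticConfig(**overrides), planted_effects=[])
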