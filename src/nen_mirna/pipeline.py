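"""End-to-end orchestration: simulate (or load) -> preprocess -> high
expression -> ensemble ranking -> subset search -> hierarchical evaluation.

A single top-level seed fans out to per-stage seeds by fixed offsets, so a
run is reproducible bit-for-bit from its configuration.  Artifacts are
written as TSV (matrices), CSV (annotations) and JSON (reports), each run
stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from nen_mirna import core_io
from nen_mirna.cistrons import LUNG_NEN_CISTRONS
from nen_mirna.classification import (
    ALGORITHMS,
    SubsetSearchResult,
    TrainedModel,
    accuracy_from_confusion,
    correlate_markers,
    evaluate_hierarchical,
    subset_search,
    train,
)
from nen_mirna.core_io import CARCINOID_TYPES, NEC_TYPES, RFMatrix, SampleTable
from nen_mirna.marker_discovery import (
    METHODS,
    ensemble_rank,
    ratio_statistic,
    select_top_fraction,
    top_expressed,
)
from nen_mirna.preprocessing import preprocess
from nen_mirna.synthetic_data import PlantedEffect, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

# Per-stage seed offsets (all derived seeds stay below 2**31).
_SEED_RANK_L1, _SEED_SEARCH_L1 = 1, 2
_SEED_RANK_2A, _SEED_SEARCH_2A = 3, 4
_SEED_RANK_2B, _SEED_SEARCH_2B = 5, 6


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serializable to YAML."""

    seed: int = 0
    counts_path: str | None = None
    annotations_path: str | None = None
    cistron_path: str | None = None
    synthetic: dict = field(default_factory=dict)
    outlier_method: str = "spearman"
    outlier_threshold: float | None = None
    abundance_percentile: float = 95.0
    abundance_min_sample_fraction: float = 0.05
    abundance_scope: str = "every_type"
    high_expression_fraction: float = 0.005
    ranking_n_folds: int = 5
    ranking_methods: tuple[str, ...] = METHODS
    ranking_aggregation: str = "mean"
    select_fraction: float = 0.05
    max_subset: int = 3
    cv_n_folds: int = 5
    algorithms: tuple[str, ...] = ALGORITHMS
    calibrator_fmol_total: float = 1.0
    fraction_discovery: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_discovery < 1.0):
            raise ValueError(
                "fraction_discovery must lie strictly in (0, 1): "
                "both discovery and validation sets must be non-empty"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranking_methods"] = list(self.ranking_methods)
        d["algorithms"] = list(self.algorithms)
        d["synthetic"] = dict(self.synthetic)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        overrides = dict(self.synthetic)
        effects = overrides.pop("planted_effects", None)
        cfg = SyntheticConfig(
            seed=self.seed, fraction_discovery=self.fraction_discovery, **overrides
        )
        if effects is not None:
            cfg = dataclasses.replace(
                cfg,
                planted_effects=[
                    PlantedEffect(e["feature"], tuple(e["types"]), e["log2_fold_change"])
                    for e in effects
                ],
            )
        return cfg


@dataclass
class PipelineResult:
    """In-memory view of one run's artifacts."""

    config: PipelineConfig
    rf: RFMatrix
    annotations: SampleTable
    preprocess_report: object
    high_expression: dict
    rankings: dict
    searches: dict[str, SubsetSearchResult]
    models: dict[str, TrainedModel]
    evaluation: object
    marker_correlations: pd.DataFrame
    truth: dict | None = None


def _rank_and_search(
    rf: RFMatrix,
    labels: pd.Series,
    cfg: PipelineConfig,
    seed_rank: int,
    seed_search: int,
) -> tuple[object, list[str], SubsetSearchResult]:
    ranking = ensemble_rank(
        rf,
        labels,
        n_folds=cfg.ranking_n_folds,
        seed=seed_rank,
        methods=cfg.ranking_methods,
        aggregation=cfg.ranking_aggregation,
    )
    selected = select_top_fraction(ranking, cfg.select_fraction)
    if len(selected) > 25:
        selected = selected[:25]
    search = subset_search(
        rf,
        labels,
        selected,
        algorithms=cfg.algorithms,
        max_subset=cfg.max_subset,
        n_folds=cfg.cv_n_folds,
        seed=seed_search,
    )
    return ranking, selected, search


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage in order; optionally write artifacts to ``out_dir``.

    Simulates a cohort when no count matrix path is configured.  Marker
    ranking and the classifier subset search for the carcinoid-vs-NEC level
    use discovery samples only; subtype models are likewise trained on
    discovery samples of their two types, and all models are then assessed
    on the held-out validation set.
    """
    truth = None
    if cfg.counts_path is None:
        syn = cfg.synthetic_config()
        cm, ann, cmap, truth = generate_cohort(syn)
    else:
        cm = core_io.read_count_table(cfg.counts_path)
        ann = core_io.read_annotations(cfg.annotations_path)
        cmap = (
            core_io.read_cistron_map(cfg.cistron_path)
            if cfg.cistron_path
            else LUNG_NEN_CISTRONS
        )

    rf, ann_kept, report = preprocess(
        cm,
        ann,
        outlier_method=cfg.outlier_method,
        outlier_threshold=cfg.outlier_threshold,
        percentile=cfg.abundance_percentile,
        min_sample_fraction=cfg.abundance_min_sample_fraction,
        scope=cfg.abundance_scope,
    )

    # High-expression analysis on the unfiltered normalized matrix
    mature_cm = cm.subset_features(cm.features_of_kind("mature"))
    full_rf = core_io.normalize_rf(mature_cm).subset_samples(rf.sample_ids)
    cistron_rf = core_io.aggregate_cistrons(full_rf, cmap)
    ratio, ratio_test = ratio_statistic(full_rf, ann_kept)
    high_expression = {
        "top_mirnas": top_expressed(full_rf, cfg.high_expression_fraction),
        # the packaged cistron map is small, so all cistrons are ranked
        "top_cistrons": top_expressed(cistron_rf, 1.0),
        "mir21_mir375_log2_ratio": {s: float(v) for s, v in ratio.items()},
        "ratio_test": ratio_test.to_dict(),
        "note": (
            "cistron rf values are sums of member rfs; rows need not sum to 1 "
            "because cistron maps do not partition the feature set"
        ),
    }

    disc_ids = ann_kept.samples_of_set("discovery")
    if not ann_kept.samples_of_set("validation"):
        raise ValueError("validation set is empty after preprocessing")
    rf_disc = rf.subset_samples(disc_ids)
    ann_disc = ann_kept.subset(disc_ids)

    rankings: dict = {}
    searches: dict[str, SubsetSearchResult] = {}
    models: dict[str, TrainedModel] = {}

    # Level 1: carcinoid vs NEC on the discovery set
    group = ann_disc.group
    ranking1, selected1, search1 = _rank_and_search(
        rf_disc, group, cfg, cfg.seed + _SEED_RANK_L1, cfg.seed + _SEED_SEARCH_L1
    )
    rankings["carcinoid_vs_nec"] = ranking1
    searches["carcinoid_vs_nec"] = search1
    models["carcinoid_vs_nec"] = train(
        search1.algorithm, rf_disc.log2()[search1.features], group
    )

    # Level 2: subtype comparisons on discovery samples of the two types
    for key, types, off_rank, off_search in (
        ("tc_vs_ac", CARCINOID_TYPES, _SEED_RANK_2A, _SEED_SEARCH_2A),
        ("sclc_vs_lcnec", NEC_TYPES, _SEED_RANK_2B, _SEED_SEARCH_2B),
    ):
        ids = [
            s for s in disc_ids if ann_disc.table.loc[s, "tumor_type"] in types
        ]
        rf_sub = rf.subset_samples(ids)
        lab = ann_kept.table.loc[ids, "tumor_type"]
        ranking, selected, search = _rank_and_search(
            rf_sub, lab, cfg, cfg.seed + off_rank, cfg.seed + off_search
        )
        rankings[key] = ranking
        searches[key] = search
        models[key] = train(search.algorithm, rf_sub.log2()[search.features], lab)

    evaluation = evaluate_hierarchical(
        models["carcinoid_vs_nec"],
        models["tc_vs_ac"],
        models["sclc_vs_lcnec"],
        rf,
        ann_kept,
    )

    markers = sorted(
        set(search1.features)
        | set(searches["tc_vs_ac"].features)
        | set(searches["sclc_vs_lcnec"].features)
    )
    marker_corr = correlate_markers(rf_disc, ann_disc, markers)

    result = PipelineResult(
        config=cfg,
        rf=rf,
        annotations=ann_kept,
        preprocess_report=report,
        high_expression=high_expression,
        rankings=rankings,
        searches=searches,
        models=models,
        evaluation=evaluation,
        marker_correlations=marker_corr,
        truth=truth,
    )
    if out_dir is not None:
        _write_artifacts(result, cm, ann, cmap, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, cm, ann, cmap, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "config": cfg.to_dict()}
    (out / "run_info.json").write_text(json.dumps(stamp, indent=2, default=str))
    core_io.write_count_table(cm, out / "counts.tsv")
    core_io.write_annotations(ann, out / "annotations.csv")
    core_io.write_cistron_map(cmap, out / "cistrons.tsv")
    core_io.write_rf_table(result.rf, out / "rf_filtered.tsv")
    (out / "preprocess_report.json").write_text(
        json.dumps(result.preprocess_report.to_dict(), indent=2)
    )
    (out / "high_expression.json").write_text(
        json.dumps(result.high_expression, indent=2)
    )
    (out / "rankings.json").write_text(
        json.dumps({k: r.to_dict() for k, r in result.rankings.items()}, indent=2)
    )
    (out / "models.json").write_text(
        json.dumps(
            {
                k: {
                    "search": result.searches[k].to_dict(),
                    "algorithm": m.algorithm,
                    "features": m.features,
                    "classes": list(m.classes),
                    "training_samples": m.training_sample_ids,
                }
                for k, m in result.models.items()
            },
            indent=2,
        )
    )
    (out / "evaluation.json").write_text(
        json.dumps(result.evaluation.to_dict(), indent=2, default=str)
    )
    result.marker_correlations.to_csv(out / "marker_pathology.tsv", sep="\t", index=False)
    if result.truth is not None:
        (out / "truth.json").write_text(json.dumps(result.truth, indent=2))
    # Two-marker scatter data for the level-1 classifier
    feats = result.models["carcinoid_vs_nec"].features[:2]
    scatter = result.rf.log2()[feats].copy()
    scatter["group"] = result.annotations.group
    scatter["set_label"] = result.annotations.set_label
    scatter.to_csv(out / "scatter_level1_markers.tsv", sep="\t")
    (out / "summary.txt").write_text(render_summary(result))


def render_summary(result: PipelineResult) -> str:
    """Human-readable accuracy block, ratio summary, and selected markers."""
    ev = result.evaluation
    lines = [
        f"run {result.config.config_hash()} (seed {result.config.seed})",
        "",
        "Hierarchical classifier, carcinoid vs NEC (level 1)",
    ]
    for s in ("discovery", "validation"):
        mat = ev.confusion[s]
        acc = ev.accuracy[s]
        n = int(mat.to_numpy().sum())
        correct = int(mat.to_numpy().trace())
        lines.append(
            f"  {s}: {correct}/{n} ({acc['level1']:.0%}); "
            f"subtype accuracy among level-1-correct: {acc['subtype_given_level1']:.0%}"
        )
        lines.append(f"    confusion (true x predicted):\n{mat.to_string()}")
    rt = result.high_expression["ratio_test"]
    lines += [
        "",
        "miR-21/miR-375 log2 ratio, carcinoids vs NECs:",
        f"  MWW U = {rt['statistic']:.1f}, p = {rt['p_value']:.3g}, "
        f"rank-biserial r = {rt['effect_size']:.3f}",
        "",
        "Selected markers:",
    ]
    for k, s in result.searches.items():
        lines.append(
            f"  {k}: {', '.join(s.features)} "
            f"({s.algorithm}, CV accuracy {s.cv_accuracy:.0%})"
        )
    lines += [
        "",
        "Top expressed miRNAs (median rf): "
        + ", ".join(f"{f} {m:.3f}" for f, m in result.high_expression["top_mirnas"]),
    ]
    return "\n".join(lines) + "\n"
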