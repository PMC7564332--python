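"""Repeated-cohort experiments: planted-marker recovery and null calibration.

These drive the package's self-validation: across many independently seeded
synthetic cohorts, how often do the planted carcinoid-vs-NEC markers land in
the top-5% selection, and how accurate is the level-1 classifier on the
held-out validation set?  Under a null configuration (no planted effects)
the same pipeline should perform at chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nen_mirna.classification import train, subset_search
from nen_mirna.marker_discovery import ensemble_rank, select_top_fraction
from nen_mirna.preprocessing import preprocess
from nen_mirna.synthetic_data import SyntheticConfig, generate_cohort, null_config

LEVEL1_MARKERS = ("miR-18a", "miR-155")


@dataclass
class Level1Trial:
    seed: int
    validation_accuracy: float
    n_validation: int
    selected_features: list[str]
    both_markers_selected: bool
    model_algorithm: str
    model_features: list[str]
    discovery_cv_accuracy: float


def level1_trial(seed: int, planted: bool = True) -> Level1Trial:
    """One synthetic cohort through the carcinoid-vs-NEC arm of the pipeline.

    Generate -> preprocess -> ensemble rank (discovery) -> top-5% selection
    -> subset search -> train on discovery -> score on validation.
    """
    cfg = SyntheticConfig(seed=seed) if planted else null_config(seed=seed)
    cm, ann, _, _ = generate_cohort(cfg)
    rf, ann_kept, _ = preprocess(cm, ann)
    disc = ann_kept.samples_of_set("discovery")
    val = ann_kept.samples_of_set("validation")
    rf_disc = rf.subset_samples(disc)
    group_disc = ann_kept.subset(disc).group
    ranking = ensemble_rank(rf_disc, group_disc, seed=seed + 1)
    selected = select_top_fraction(ranking)
    search = subset_search(rf_disc, group_disc, selected[:25], seed=seed + 2)
    model = train(search.algorithm, rf_disc.log2()[search.features], group_disc)
    pred = model.predict(rf.subset_samples(val).log2()[search.features])
    acc = float((pred == ann_kept.subset(val).group).mean())
    return Level1Trial(
        seed=seed,
        validation_accuracy=acc,
        n_validation=len(val),
        selected_features=selected,
        both_markers_selected=all(m in selected for m in LEVEL1_MARKERS),
        model_algorithm=search.algorithm,
        model_features=search.features,
        discovery_cv_accuracy=search.cv_accuracy,
    )


def recovery_experiment(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """Planted-effect recovery rates over ``n_seeds`` independent cohorts."""
    trials = [level1_trial(base_seed + i, planted=True) for i in range(n_seeds)]
    accs = np.array([t.validation_accuracy for t in trials])
    return {
        "n_seeds": n_seeds,
        "both_markers_selected": int(sum(t.both_markers_selected for t in trials)),
        "validation_accuracy_ge_090": int((accs >= 0.9).sum()),
        "mean_validation_accuracy": float(accs.mean()),
        "trials": trials,
    }


def null_experiment(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Chance-level calibration with no planted effects."""
    trials = [level1_trial(base_seed + i, planted=False) for i in range(n_seeds)]
    accs = np.array([t.validation_accuracy for t in trials])
    correct = int(round(sum(t.validation_accuracy * t.n_validation for t in trials)))
    total = int(sum(t.n_validation for t in trials))
    return {
        "n_seeds": n_seeds,
        "mean_validation_accuracy": float(accs.mean()),
        "pooled_correct": correct,
        "pooled_total": total,
        "trials": trials,
    }
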