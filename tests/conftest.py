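import numpy as np
import pandas as pd
import pytest

from nen_mirna.core_io import CountMatrix, RFMatrix, SampleTable
from nen_mirna.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture
def small_count_matrix() -> CountMatrix:
    """Two samples, four features covering every feature kind."""
    counts = pd.DataFrame(
        {
            "miR-a": [8, 3],
            "miR-b": [2, 1],
            "miR-a*": [1, 0],
            "spike": [100, 50],
        },
        index=["s1", "s2"],
    )
    kinds = pd.Series(
        {"miR-a": "mature", "miR-b": "mature", "miR-a*": "star", "spike": "calibrator"}
    )
    return CountMatrix(counts, kinds)


def make_annotations(sample_ids, tumor_types, set_labels=None, **overrides) -> SampleTable:
    n = len(sample_ids)
    data = {
        "tumor_type": tumor_types,
        "set_label": set_labels or ["discovery"] * n,
        "ki67_percent": overrides.get("ki67_percent", [1.0] * n),
        "mitoses_per_2mm2": overrides.get("mitoses_per_2mm2", [1.0] * n),
        "necrosis": overrides.get("necrosis", ["no"] * n),
        "pN": overrides.get("pN", ["0"] * n),
        "total_rna_input_ug": overrides.get("total_rna_input_ug", [1.0] * n),
    }
    return SampleTable(pd.DataFrame(data, index=sample_ids))


@pytest.fixture
def annotations_factory():
    return make_annotations


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default (planted-effect) conditions."""
    return generate_cohort(SyntheticConfig(seed=7))


def uniform_rf(values: np.ndarray, sample_ids, feature_ids, **kwargs) -> RFMatrix:
    df = pd.DataFrame(np.asarray(values, float), index=sample_ids, columns=feature_ids)
    return RFMatrix(df, **kwargs)
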