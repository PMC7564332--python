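"""Domain containers and text-format I/O for small-RNA count profiles.

Conventions
-----------
* Count matrices are stored samples x features in memory; the on-disk TSV
  layout is features as rows and samples as columns (the shape in which
  annotation pipelines emit them), with an optional ``kind`` column
  classifying each feature as ``mature``, ``star``, ``nonhuman`` or
  ``calibrator``.
* Relative frequency (RF) is a mature-miRNA read count divided by the
  sample's total mature-miRNA reads; STAR passenger strands, non-human
  sequences and calibrator spike-ins never enter the denominator.
* Feature ids use mature miRNA names as given (e.g. ``miR-18a``); cistron
  ids carry a ``cluster-`` prefix. No miRBase version resolution is
  attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("mature", "star", "nonhuman", "calibrator")

TUMOR_TYPES = ("TC", "AC", "SCLC", "LCNEC")
CARCINOID_TYPES = ("TC", "AC")
NEC_TYPES = ("SCLC", "LCNEC")
SET_LABELS = ("discovery", "validation")
NECROSIS_LEVELS = ("yes", "no", "focal")
PN_LEVELS = ("unknown", "0", "1", "2")

ANNOTATION_COLUMNS = (
    "tumor_type",
    "set_label",
    "ki67_percent",
    "mitoses_per_2mm2",
    "necrosis",
    "pN",
    "total_rna_input_ug",
)


class DataValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class CountMatrix:
    """Raw integer sequence-read counts, samples x features.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per feature id;
        non-negative integers.
    feature_kind
        Series indexed by feature id with values in :data:`FEATURE_KINDS`.
    """

    counts: pd.DataFrame
    feature_kind: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise DataValidationError(f"duplicate feature ids: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values.astype(float))
            if np.any(frac != 0) or np.any(~np.isfinite(values.astype(float))):
                r, c = np.argwhere(frac != 0)[0]
                raise DataValidationError(
                    "non-integer count at sample "
                    f"{self.counts.index[r]!r}, feature {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise DataValidationError(
                "negative count at sample "
                f"{self.counts.index[r]!r}, feature {self.counts.columns[c]!r}"
            )
        self.feature_kind = self.feature_kind.reindex(self.counts.columns)
        unknown = ~self.feature_kind.isin(FEATURE_KINDS)
        if unknown.any():
            bad = self.feature_kind.index[unknown].tolist()
            logger.warning("unknown feature kinds for %s; defaulting to 'mature'", bad)
            self.feature_kind = self.feature_kind.where(~unknown, "mature")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def features_of_kind(self, kind: str) -> list[str]:
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        return list(self.feature_kind.index[self.feature_kind == kind])

    def subset_features(self, features: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[features].copy(), self.feature_kind[features].copy())


def read_count_table(path: str | Path, kind_column: str = "kind") -> CountMatrix:
    """Read a TSV count table (features as rows, samples as columns).

    The first column holds feature ids; an optional ``kind_column`` holds the
    feature kind. Unknown kinds default to ``mature`` with a logged warning.
    Duplicate ids or negative/non-integer counts are hard errors.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if kind_column in raw.columns:
        kind = raw[kind_column].copy()
        raw = raw.drop(columns=[kind_column])
    else:
        kind = pd.Series("mature", index=raw.index)
    try:
        counts = raw.astype(np.int64)
    except ValueError:
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0)
        if bad.any().any():
            feat = bad.index[bad.any(axis=1)][0]
            samp = bad.columns[bad.loc[feat]][0]
            raise DataValidationError(
                f"non-integer count at sample {samp!r}, feature {feat!r}"
            ) from None
        counts = numeric.astype(np.int64)
    counts = counts.T
    counts.index.name = None
    counts.columns.name = None
    kind.index.name = None
    return CountMatrix(counts, kind)


def write_count_table(cm: CountMatrix, path: str | Path, kind_column: str = "kind") -> None:
    """Write a :class:`CountMatrix` in the on-disk layout read by
    :func:`read_count_table` (features as rows)."""
    out = cm.counts.T.copy()
    out.insert(len(out.columns), kind_column, cm.feature_kind)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


@dataclass
class SampleTable:
    """Per-sample pathological annotations.

    Wraps a DataFrame indexed by sample id with columns ``tumor_type``
    (TC/AC/SCLC/LCNEC), ``set_label`` (discovery/validation), ``ki67_percent``,
    ``mitoses_per_2mm2``, ``necrosis`` (yes/no/focal), ``pN``
    (unknown/0/1/2) and ``total_rna_input_ug``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"annotation table missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise DataValidationError("duplicate sample ids in annotation table")
        t = self.table
        for col, levels in (
            ("tumor_type", TUMOR_TYPES),
            ("set_label", SET_LABELS),
            ("necrosis", NECROSIS_LEVELS),
        ):
            bad = ~t[col].isin(levels)
            if bad.any():
                raise DataValidationError(
                    f"invalid {col} value(s) {sorted(t[col][bad].unique())} "
                    f"(allowed: {levels})"
                )
        self.table = t.copy()
        self.table["pN"] = self.table["pN"].astype(str)
        bad = ~self.table["pN"].isin(PN_LEVELS)
        if bad.any():
            raise DataValidationError(
                f"invalid pN value(s) {sorted(self.table['pN'][bad].unique())}"
            )
        if (self.table["ki67_percent"] < 0).any():
            raise DataValidationError("ki67_percent must be >= 0")
        if (self.table["mitoses_per_2mm2"] < 0).any():
            raise DataValidationError("mitoses_per_2mm2 must be >= 0")
        if (self.table["total_rna_input_ug"] <= 0).any():
            raise DataValidationError("total_rna_input_ug must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tumor_type(self) -> pd.Series:
        return self.table["tumor_type"]

    @property
    def set_label(self) -> pd.Series:
        return self.table["set_label"]

    @property
    def group(self) -> pd.Series:
        """Two-class grouping: carcinoid (TC, AC) vs NEC (SCLC, LCNEC)."""
        return self.table["tumor_type"].map(
            lambda t: "carcinoid" if t in CARCINOID_TYPES else "NEC"
        )

    def samples_of_set(self, set_label: str) -> list[str]:
        return list(self.table.index[self.table["set_label"] == set_label])

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        return SampleTable(self.table.loc[sample_ids].copy())


def read_annotations(path: str | Path) -> SampleTable:
    """Read a sample-annotation CSV with a ``sample_id`` column."""
    df = pd.read_csv(path, dtype={"pN": str})
    if "sample_id" not in df.columns:
        raise DataValidationError("annotation CSV must have a 'sample_id' column")
    return SampleTable(df.set_index("sample_id"))


def write_annotations(ann: SampleTable, path: str | Path) -> None:
    out = ann.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


@dataclass
class CistronMap:
    """Mapping of cistron id -> ordered member mature-miRNA feature ids.

    A cistron is a genomic cluster of co-transcribed miRNAs whose relative
    frequencies are summed into one expression feature. Monocistronic
    entries have exactly one member.
    """

    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        for cid, mem in self.members.items():
            if len(mem) == 0:
                raise DataValidationError(f"cistron {cid!r} has no members")
            if len(set(mem)) != len(mem):
                raise DataValidationError(f"cistron {cid!r} lists duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, cistron_id: str) -> list[str]:
        return self.members[cistron_id]

    @property
    def cistron_ids(self) -> list[str]:
        return list(self.members)


def read_cistron_map(path: str | Path) -> CistronMap:
    """Read a two-column TSV: cistron_id <tab> comma-separated members."""
    members: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cid, _, rest = line.partition("\t")
        members[cid] = [m.strip() for m in rest.split(",") if m.strip()]
    return CistronMap(members)


def write_cistron_map(cmap: CistronMap, path: str | Path) -> None:
    lines = [f"{cid}\t{','.join(mem)}" for cid, mem in cmap.members.items()]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RFMatrix:
    """Relative frequencies over mature miRNAs (or cistrons), samples x features.

    ``pseudocount`` is the epsilon added inside :meth:`log2`; by default it is
    half the smallest nonzero rf in the matrix, a scale-free choice that
    avoids -inf while preserving monotonicity.  ``normalized`` records whether
    each row sums to 1 (false for abundance-filtered or cistron-aggregated
    matrices, whose features no longer partition the reads).
    """

    rf: pd.DataFrame
    pseudocount: float = field(default=None)  # type: ignore[assignment]
    normalized: bool = True

    def __post_init__(self) -> None:
        values = self.rf.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1 + 1e-12):
            raise DataValidationError("relative frequencies must lie in [0, 1]")
        if self.normalized:
            sums = values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = self.rf.index[np.abs(sums - 1.0) > 1e-9].tolist()
                raise DataValidationError(f"rf rows do not sum to 1: {bad}")
        if self.pseudocount is None:
            nz = values[values > 0]
            self.pseudocount = float(nz.min() / 2.0) if nz.size else 1e-9
        if self.pseudocount <= 0:
            raise DataValidationError("pseudocount must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rf.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.rf.columns)

    def log2(self) -> pd.DataFrame:
        """log2(rf + pseudocount); strictly monotone in rf."""
        return np.log2(self.rf + self.pseudocount)

    def subset_features(self, features: list[str]) -> "RFMatrix":
        return RFMatrix(
            self.rf[features].copy(), pseudocount=self.pseudocount, normalized=False
        )

    def subset_samples(self, sample_ids: list[str]) -> "RFMatrix":
        return RFMatrix(
            self.rf.loc[sample_ids].copy(),
            pseudocount=self.pseudocount,
            normalized=self.normalized,
        )


def write_rf_table(rf: RFMatrix, path: str | Path) -> None:
    """Write an RF matrix as TSV (features as rows, samples as columns)."""
    out = rf.rf.T.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_rf_table(path: str | Path) -> RFMatrix:
    """Read an RF TSV written by :func:`write_rf_table`.

    Rows summing to 1 within 1e-6 mark the matrix as normalized; otherwise
    it is treated as a filtered/aggregated matrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0).T
    sums = df.to_numpy().sum(axis=1)
    normalized = bool(np.all(np.abs(sums - 1.0) < 1e-6))
    if normalized and np.any(np.abs(sums - 1.0) > 0):
        df = df.div(sums, axis=0)  # repair rounding from text serialization
    return RFMatrix(df, normalized=normalized)


def normalize_rf(cm: CountMatrix) -> RFMatrix:
    """Relative-frequency normalization over mature-miRNA reads only.

    rf(sample, feature) = count / sum of that sample's mature counts.
    STAR, non-human and calibrator features are excluded from numerator and
    denominator alike.

    Raises
    ------
    DataValidationError
        If no mature features exist or any sample has zero mature reads.
    """
    mature = cm.features_of_kind("mature")
    if not mature:
        raise DataValidationError("count matrix has no mature-miRNA features")
    sub = cm.counts[mature].to_numpy(dtype=float)
    totals = sub.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(cm.sample_ids, totals) if t == 0]
        raise DataValidationError(f"samples with zero mature-miRNA reads: {bad}")
    rf = pd.DataFrame(sub / totals[:, None], index=cm.counts.index, columns=mature)
    return RFMatrix(rf)


def aggregate_cistrons(rf: RFMatrix, cmap: CistronMap) -> RFMatrix:
    """Sum member-miRNA relative frequencies into cistron features.

    Members absent from ``rf`` contribute 0. Output rows need not sum to 1:
    cistron maps rarely partition the full feature set.
    """
    if len(cmap) == 0:
        raise DataValidationError("empty cistron map")
    data = {}
    for cid, members in cmap.members.items():
        present = [m for m in members if m in rf.rf.columns]
        if present:
            data[cid] = rf.rf[present].sum(axis=1)
        else:
            data[cid] = pd.Series(0.0, index=rf.rf.index)
    out = pd.DataFrame(data, index=rf.rf.index)
    return RFMatrix(out, pseudocount=rf.pseudocount, normalized=False)


def mirna_content(
    cm: CountMatrix, ann: SampleTable, calibrator_fmol_total: float = 1.0
) -> pd.Series:
    """Absolute miRNA content per sample, in fmol per ug total RNA.

    content = (mature reads / calibrator reads) * calibrator_fmol_total
              / total_rna_input_ug

    The calibrator is a synthetic spiked-in oligonucleotide of known molar
    amount; the default 1 fmol total per sample is a configured constant and
    should be set to match the spike design in use.
    """
    if calibrator_fmol_total <= 0:
        raise ValueError("calibrator_fmol_total must be > 0")
    mature = cm.features_of_kind("mature")
    calib = cm.features_of_kind("calibrator")
    if not calib:
        raise DataValidationError("count matrix has no calibrator features")
    mature_reads = cm.counts[mature].sum(axis=1).astype(float)
    calib_reads = cm.counts[calib].sum(axis=1).astype(float)
    if (calib_reads == 0).any():
        bad = list(calib_reads.index[calib_reads == 0])
        raise DataValidationError(f"zero calibrator reads for samples: {bad}")
    ug = ann.table.loc[cm.sample_ids, "total_rna_input_ug"].astype(float)
    return mature_reads / calib_reads * calibrator_fmol_total / ug
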