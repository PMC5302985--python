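"""Shared data types and tab-separated I/O.

Every stage of the pipeline exchanges data through the small set of
containers defined here.  All on-disk formats are UTF-8, tab-delimited
text with exactly one header line, so that inputs can be prepared with
any spreadsheet or scripting tool and every intermediate stays
human-readable and diff-able.

Expression values are expected on log2 scale.  Readers can optionally
apply ``log2(x + 1)`` for callers whose matrices are on linear scale.
Missing values are rejected: the statistics downstream (binned mutual
information, permutation tests) have no well-defined behaviour for NaN.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("cerna_sponge")

CANCER = "cancer"
NORMAL = "normal"
CONDITIONS = (CANCER, NORMAL)

FEATURE_CLASSES = ("lncRNA", "mRNA", "miRNA")


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicate ids, NaN, ...)."""


class ParseError(ValueError):
    """A file cannot be parsed into the declared format."""


def _check_ids(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    bad = [i for i in ids if "\t" in i or "\n" in i]
    if bad:
        raise ValidationError(f"{what} ids may not contain tab/newline: {bad[:3]!r}")
    if len(set(ids)) != len(ids):
        counts = pd.Series(ids).value_counts()
        dups = sorted(counts[counts > 1].index)
        raise ValidationError(f"duplicate {what} ids: {dups[:5]}")
    return ids


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------
@dataclass
class ExpressionMatrix:
    """Feature x sample matrix of log2 expression values.

    ``data`` carries features on the index and samples on the columns.
    """

    data: pd.DataFrame
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(
                f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}"
            )
        _check_ids(self.data.index, "feature")
        _check_ids(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at feature {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def vector(self, feature_id: str, sample_ids: list[str]) -> np.ndarray:
        """Expression of one feature over an explicit, ordered sample list."""
        if feature_id not in self.data.index:
            raise KeyError(f"{self.feature_class} feature {feature_id!r} not measured")
        return self.data.loc[feature_id, sample_ids].to_numpy(dtype=float)


def read_expression_matrix(
    path: str | Path, feature_class: str, already_log2: bool = True
) -> ExpressionMatrix:
    """Read an expression TSV (header = sample ids, first column = feature ids)."""
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read expression matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"non-numeric cell in {path} at feature {row!r}, sample {col!r}"
            )
    if df.isna().to_numpy().any():
        raise ValidationError(f"missing values in expression matrix {path}")
    if not already_log2:
        if (df.to_numpy() < 0).any():
            raise ValidationError("negative values cannot be log2(x+1) transformed")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df, feature_class)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    # %.17g guarantees bitwise float64 round-trips through the TSV
    matrix.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# ConditionTable
# ---------------------------------------------------------------------------
@dataclass
class ConditionTable:
    """Sample -> condition ("cancer" / "normal") assignment."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        labels = {str(k): str(v) for k, v in dict(self.labels).items()}
        _check_ids(labels, "sample")
        bad = sorted({v for v in labels.values()} - set(CONDITIONS))
        if bad:
            raise ValidationError(f"unknown condition labels {bad}; expected {CONDITIONS}")
        for cond in CONDITIONS:
            if cond not in labels.values():
                raise ValidationError(f"condition {cond!r} has no samples")
        self.labels = labels

    def samples(self, condition: str) -> list[str]:
        """Sample ids of one condition, in insertion order."""
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        return [s for s, c in self.labels.items() if c == condition]

    def condition_of(self, sample_id: str) -> str:
        return self.labels[sample_id]


def read_condition_table(path: str | Path) -> ConditionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise ParseError(
            f"{path}: expected header 'sample_id\\tcondition', got {list(df.columns)}"
        )
    return ConditionTable(dict(zip(df["sample_id"], df["condition"])))


def write_condition_table(table: ConditionTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(table.labels), "condition": list(table.labels.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TargetMap
# ---------------------------------------------------------------------------
TARGET_CLASSES = ("lncRNA", "mRNA")


@dataclass
class TargetMap:
    """miRNA -> target bipartite map, split by target class (lncRNA / mRNA).

    Built from (mirna_id, target_id, target_class) records; duplicates are
    collapsed with a warning and a target id must keep one class throughout.
    """

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["mirna_id", "target_id", "target_class"]
        )
    )

    def __post_init__(self) -> None:
        df = self.records.copy()
        df.columns = ["mirna_id", "target_id", "target_class"]
        for col in df.columns:
            df[col] = df[col].astype(str)
        bad = sorted(set(df["target_class"]) - set(TARGET_CLASSES))
        if bad:
            raise ValidationError(
                f"unknown target_class {bad}; expected one of {TARGET_CLASSES}"
            )
        n0 = len(df)
        df = df.drop_duplicates(["mirna_id", "target_id"], keep="first")
        if len(df) < n0:
            logger.warning("TargetMap: collapsed %d duplicate records", n0 - len(df))
        classes = df.groupby("target_id")["target_class"].nunique()
        mixed = classes[classes > 1]
        if len(mixed):
            raise ValidationError(
                f"targets with inconsistent class: {sorted(mixed.index)[:5]}"
            )
        self.records = df.reset_index(drop=True)
        self._targets_of: dict[str, set[str]] = {}
        self._mirnas_of: dict[str, set[str]] = {}
        self._class_of: dict[str, str] = {}
        for m, t, c in self.records.itertuples(index=False):
            self._targets_of.setdefault(m, set()).add(t)
            self._mirnas_of.setdefault(t, set()).add(m)
            self._class_of[t] = c

    def __len__(self) -> int:
        return len(self.records)

    def targets_of(self, mirna_id: str, target_class: str | None = None) -> frozenset[str]:
        targets = self._targets_of.get(mirna_id, set())
        if target_class is not None:
            targets = {t for t in targets if self._class_of[t] == target_class}
        return frozenset(targets)

    def mirnas_of(self, target_id: str) -> frozenset[str]:
        return frozenset(self._mirnas_of.get(target_id, set()))

    def targets(self, target_class: str | None = None) -> frozenset[str]:
        if target_class is None:
            return frozenset(self._mirnas_of)
        return frozenset(t for t, c in self._class_of.items() if c == target_class)


def read_target_map(path: str | Path) -> TargetMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["mirna_id", "target_id", "target_class"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    return TargetMap(df)


def write_target_map(target_map: TargetMap, path: str | Path) -> None:
    target_map.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneAnnotation
# ---------------------------------------------------------------------------
@dataclass
class GeneAnnotation:
    """feature_id -> (transcript length in nt, exon count)."""

    table: pd.DataFrame  # columns: length, exons; index: feature_id

    def __post_init__(self) -> None:
        df = self.table
        _check_ids(df.index, "feature")
        if (df["length"] < 1).any() or (df["exons"] < 1).any():
            raise ValidationError("transcript length and exon count must be >= 1")
        self.table = df.astype({"length": float, "exons": int})

    def lengths(self, ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(ids), "length"].to_numpy(dtype=float)

    def exon_counts(self, ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(ids), "exons"].to_numpy(dtype=float)


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    expected = ["feature_id", "length", "exons"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    return GeneAnnotation(df.set_index("feature_id"))


def write_gene_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------
@dataclass
class ClinicalTable:
    """Per-patient follow-up: survival time and death indicator."""

    table: pd.DataFrame  # columns: time, event; index: sample_id

    def __post_init__(self) -> None:
        _check_ids(self.table.index, "sample")
        times = self.table["time"].to_numpy(dtype=float)
        if not np.isfinite(times).all() or (times < 0).any():
            raise ValidationError("survival times must be finite and >= 0")
        self.table = self.table.assign(
            time=times, event=self.table["event"].astype(bool)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def aligned(self, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table.loc[list(sample_ids)]
        return sub["time"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=bool)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    expected = ["sample_id", "time", "event"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    if not set(df["event"].astype(int)) <= {0, 1}:
        raise ParseError(f"{path}: event flags must be 0/1")
    return ClinicalTable(
        df.assign(event=df["event"].astype(int).astype(bool)).set_index("sample_id")
    )


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    out = clinical.table.assign(event=clinical.table["event"].astype(int))
    out.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# ReferenceSets, DrugEffectTable
# ---------------------------------------------------------------------------
@dataclass
class ReferenceSets:
    """Reference id sets for enrichment (tumor suppressors, disease miRNAs)."""

    tumor_suppressors: frozenset[str]
    disease_mirnas: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        self.tumor_suppressors = frozenset(self.tumor_suppressors)
        self.disease_mirnas = frozenset(self.disease_mirnas)
        if self.universe_size < 1:
            raise ValidationError("universe_size must be positive")
        if len(self.tumor_suppressors) > self.universe_size:
            raise ValidationError("tumor suppressor set larger than universe")


def read_id_set(path: str | Path) -> frozenset[str]:
    """One-column TSV of feature ids (header line required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 1:
        raise ParseError(f"{path}: expected a single id column")
    return frozenset(df.iloc[:, 0].astype(str))


def write_id_set(ids: Iterable[str], path: str | Path, header: str = "feature_id") -> None:
    pd.DataFrame({header: sorted(ids)}).to_csv(path, sep="\t", index=False)


DRUG_DIRECTIONS = ("up", "down")


@dataclass
class DrugEffectTable:
    """Records of (drug, miRNA, direction of miRNA expression change)."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["drug_name", "mirna_id", "direction"])
    )

    def __post_init__(self) -> None:
        df = self.records.copy()
        df.columns = ["drug_name", "mirna_id", "direction"]
        for col in df.columns:
            df[col] = df[col].astype(str)
        bad = sorted(set(df["direction"]) - set(DRUG_DIRECTIONS))
        if bad:
            raise ValidationError(f"unknown drug direction {bad}; expected {DRUG_DIRECTIONS}")
        n0 = len(df)
        df = df.drop_duplicates()
        if len(df) < n0:
            logger.warning("DrugEffectTable: collapsed %d duplicate records", n0 - len(df))
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


def read_drug_effect_table(path: str | Path) -> DrugEffectTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["drug_name", "mirna_id", "direction"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    return DrugEffectTable(df)


def write_drug_effect_table(table: DrugEffectTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)
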