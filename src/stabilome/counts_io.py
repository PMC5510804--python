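"""Reading and writing of count tables, sample sheets and gene annotations.

Tabular conventions:

* count table — TSV, first column gene id, header row of sample ids,
  integer cells;
* sample sheet — CSV or TSV with columns ``sample_id``, ``time_h``,
  ``arm``, ``replicate``;
* gene annotation — two-column TSV ``gene_id<TAB>length_bp`` (or a BED12
  file from which exonic lengths are derived).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arm",
    "CountMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "ExpressionMatrix",
    "read_count_table",
    "read_sample_sheet",
    "read_gene_lengths",
    "read_bed12_lengths",
    "compute_rpkm",
]

DEFAULT_TIMEPOINTS_H = (0.0, 1.0, 3.0, 24.0, 72.0)


class Arm(str, Enum):
    """Assay arm of a library: stimulation only, stimulation plus
    actinomycin-D chase, or unstimulated control."""

    TNF = "TNF"
    TNF_ACTD = "TNF_ACTD"
    CONTROL = "CONTROL"

    @classmethod
    def parse(cls, label: "Arm | str") -> "Arm":
        if isinstance(label, cls):
            return label
        key = re.sub(r"[^A-Z0-9]+", "_", str(label).strip().upper()).strip("_")
        aliases = {
            "TNF": cls.TNF,
            "TNF_ACTD": cls.TNF_ACTD,
            "TNF_ACT_D": cls.TNF_ACTD,
            "ACTD": cls.TNF_ACTD,
            "CONTROL": cls.CONTROL,
            "CTRL": cls.CONTROL,
            "UNSTIMULATED": cls.CONTROL,
        }
        if key not in aliases:
            raise ValueError(f"unknown assay arm label: {label!r}")
        return aliases[key]


@dataclass(frozen=True)
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = df.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.number):
                raise ValueError("count matrix contains non-numeric cells")
            if np.any(~np.isfinite(vals)):
                raise ValueError("count matrix contains non-finite cells")
            if np.any(vals < 0) or np.any(vals != np.floor(vals)):
                g, s = np.argwhere((vals < 0) | (vals != np.floor(vals)))[0]
                raise ValueError(
                    "count matrix cell is not a non-negative integer: "
                    f"gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing}")
        return CountMatrix(self.counts[list(sample_ids)])

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample design labels: time (h), assay arm, replicate index."""

    table: pd.DataFrame  # columns: sample_id, time_h, arm, replicate

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = ["sample_id", "time_h", "arm", "replicate"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        df = df[required]
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in sheet: {dups}")
        df["time_h"] = df["time_h"].astype(float)
        df["arm"] = [Arm.parse(a).value for a in df["arm"]]
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive integers")
        bad_ctrl = df[(df["arm"] == Arm.CONTROL.value) & (df["time_h"] != 0)]
        if len(bad_ctrl):
            raise ValueError(
                "CONTROL samples must have time_h = 0: "
                f"{bad_ctrl['sample_id'].tolist()}"
            )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, arm: Arm | str | None = None,
                time_h: float | None = None) -> list[str]:
        """Sample ids matching the given arm and/or time point."""
        df = self.table
        if arm is not None:
            df = df[df["arm"] == Arm.parse(arm).value]
        if time_h is not None:
            df = df[df["time_h"] == float(time_h)]
        return list(df["sample_id"])

    def times(self, arm: Arm | str | None = None) -> list[float]:
        df = self.table
        if arm is not None:
            df = df[df["arm"] == Arm.parse(arm).value]
        return sorted(df["time_h"].unique())

    def validate_against(self, counts: CountMatrix) -> None:
        sheet_ids = set(self.sample_ids)
        count_ids = set(counts.sample_ids)
        if sheet_ids != count_ids:
            raise ValueError(
                "sample sheet and count matrix disagree: "
                f"only in sheet {sorted(sheet_ids - count_ids)}, "
                f"only in counts {sorted(count_ids - sheet_ids)}"
            )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene exonic length in bp, the only annotation RPKM needs."""

    lengths: pd.Series  # index gene_id, values length_bp

    def __post_init__(self) -> None:
        s = self.lengths.astype(np.int64)
        if s.index.has_duplicates:
            raise ValueError("duplicate gene ids in annotation")
        if (s < 1).any():
            bad = s.index[s < 1].tolist()
            raise ValueError(f"non-positive exonic lengths for genes: {bad}")
        object.__setattr__(self, "lengths", s)

    def to_tsv(self, path: str | Path) -> None:
        out = self.lengths.rename("length_bp").to_frame()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


class ExpressionUnit(str, Enum):
    RPKM = "RPKM"
    NORM_COUNTS = "NORM_COUNTS"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample non-negative real expression values plus their unit."""

    values: pd.DataFrame
    unit: ExpressionUnit

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if vals.size and (np.any(~np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("expression values must be finite and >= 0")
        object.__setattr__(self, "unit", ExpressionUnit(self.unit))

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> CountMatrix:
    """Read a TSV count table (first column gene id, header sample ids).

    Non-integer or negative cells raise a :class:`ValueError` naming the
    offending gene and sample; duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-integer or negative count in {path}: "
                f"gene {gene!r}, sample {col!r}, value {df.loc[gene, col]!r}"
            )
        numeric[col] = vals
    return CountMatrix(numeric)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet from CSV or TSV (delimiter sniffed)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return SampleSheet(df)


def read_gene_lengths(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    col = df.columns[0]
    return GeneAnnotation(df[col])


def read_bed12_lengths(path: str | Path) -> GeneAnnotation:
    """Derive exonic lengths from a BED12 file (0-based half-open).

    The exonic length of a record is the sum of its block sizes; records
    sharing a name are merged by taking the maximum length across
    transcripts.
    """
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"BED12 requires 12 columns, got {len(fields)}: {line[:60]}"
                )
            name = fields[3]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            total = sum(sizes)
            lengths[name] = max(total, lengths.get(name, 0))
    if not lengths:
        raise ValueError(f"no BED12 records found in {path}")
    return GeneAnnotation(pd.Series(lengths))


def compute_rpkm(counts: CountMatrix, annot: GeneAnnotation) -> ExpressionMatrix:
    """Reads per kilobase of exon per million mapped reads.

    value(g, s) = counts(g, s) * 1e9 / (length_bp(g) * total(s)), where
    total(s) is the column sum of the count table.
    """
    missing = [g for g in counts.gene_ids if g not in annot.lengths.index]
    if missing:
        raise KeyError(f"genes without length annotation: {missing[:20]}"
                       + ("..." if len(missing) > 20 else ""))
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"library size is zero for samples: {zero}")
    lengths = annot.lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    vals = counts.counts.to_numpy(dtype=float) * 1e9
    vals /= lengths[:, None]
    vals /= totals.to_numpy(dtype=float)[None, :]
    df = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, ExpressionUnit.RPKM)
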