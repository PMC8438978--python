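"""Core tabular data structures: count matrix, sample sheet, DE table.

All containers wrap pandas objects, validate their invariants on
construction, and round-trip through plain TSV so every artifact of a run
is diffable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL_CLASS = "control"

SAMPLE_SHEET_COLUMNS = ["sample", "treatment", "control_for", "class", "replicate"]
DE_TABLE_COLUMNS = ["gene", "treatment", "log2fc", "p", "padj"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise DataError("duplicate gene ids in count matrix")
        if df.columns.has_duplicates:
            raise DataError("duplicate sample ids in count matrix")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("count matrix contains non-numeric entries")
        if np.any(values < 0):
            raise DataError("count matrix contains negative entries")
        if not np.allclose(values, np.round(values)):
            raise DataError("count matrix contains non-integer entries")
        self.counts = df.astype(np.int64)
        self.counts.index.name = "gene"

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes].copy())

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[samples].copy())

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


@dataclass
class SampleSheet:
    """Per-sample metadata: treatment group, matched vehicle control, class.

    Control samples carry class ``control`` and an empty ``control_for``;
    every treated sample points at the control *group* (a treatment id
    present in the sheet) it is compared against.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"sample sheet missing columns: {missing}")
        df = df[SAMPLE_SHEET_COLUMNS].copy()
        df["control_for"] = df["control_for"].fillna("").astype(str)
        if df["sample"].duplicated().any():
            raise DataError("duplicate sample ids in sample sheet")
        groups = set(df["treatment"])
        treated = df[df["class"] != CONTROL_CLASS]
        orphans = sorted(set(treated["control_for"]) - groups)
        if orphans or (treated["control_for"] == "").any():
            raise DataError(f"control_for references missing control groups: {orphans}")
        ncontrols = treated.groupby("treatment")["control_for"].nunique()
        if (ncontrols > 1).any():
            bad = list(ncontrols[ncontrols > 1].index)
            raise DataError(f"treatments mapped to multiple controls: {bad}")
        sizes = df.groupby("treatment")["sample"].size()
        if (sizes < 2).any():
            bad = list(sizes[sizes < 2].index)
            raise DataError(f"treatment groups with fewer than 2 replicates: {bad}")
        self.table = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def treatments(self) -> list[str]:
        """Non-control treatment groups, in sheet order."""
        sub = self.table[self.table["class"] != CONTROL_CLASS]
        return list(dict.fromkeys(sub["treatment"]))

    def samples_of(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["treatment"] == group, "sample"])

    def control_of(self, treatment: str) -> str:
        vals = self.table.loc[
            (self.table["treatment"] == treatment)
            & (self.table["class"] != CONTROL_CLASS),
            "control_for",
        ]
        if vals.empty:
            raise DataError(f"unknown treatment: {treatment}")
        return vals.iloc[0]

    def class_of(self, treatment: str) -> str:
        vals = self.table.loc[self.table["treatment"] == treatment, "class"]
        if vals.empty:
            raise DataError(f"unknown treatment: {treatment}")
        return vals.iloc[0]

    def treatments_of_class(self, cls: str) -> list[str]:
        sub = self.table[self.table["class"] == cls]
        return list(dict.fromkeys(sub["treatment"]))

    def subset_samples(self, samples: list[str], validate: bool = True) -> "SampleSheet":
        keep = self.table[self.table["sample"].isin(set(samples))]
        if validate:
            return SampleSheet(keep.copy())
        obj = object.__new__(SampleSheet)
        obj.table = keep.reset_index(drop=True)
        return obj

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype={"control_for": str}, keep_default_na=False)
        df["replicate"] = df["replicate"].astype(int)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class DETable:
    """Long-format differential expression results, one row per (gene, treatment)."""

    table: pd.DataFrame
    validate: bool = field(default=True)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"DE table missing columns: {missing}")
        df = df[DE_TABLE_COLUMNS].copy()
        if self.validate:
            if df.duplicated(subset=["gene", "treatment"]).any():
                raise DataError("duplicate (gene, treatment) rows in DE table")
            if ((df["p"] < 0) | (df["p"] > 1)).any():
                raise DataError("p-values outside [0, 1]")
            if (df["padj"] < df["p"] - 1e-12).any():
                raise DataError("padj < p in DE table")
        self.table = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene"]))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.table["treatment"]))

    @classmethod
    def from_tsv(cls, path) -> "DETable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
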