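"""Shared in-memory data model.

Read-level data are carried as pandas DataFrames with a fixed column
contract (:data:`READ_COLUMNS`); annotation, abundance matrices and gene
set collections get small dedicated containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column contract for read-level records. ``polya_length`` is NaN when the
#: basecaller did not estimate a tail (or estimated < 1 nt).
READ_COLUMNS = [
    "read_id",
    "sample_id",
    "batch",
    "condition",
    "gene_id",
    "transcript_id",
    "read_length",
    "polya_length",
]

CONDITIONS = ("bacterial", "viral")

#: Chromosome names recognised as the mitochondrial genome (case-insensitive).
MITO_CHROMOSOMES = frozenset({"mt", "chrm", "chrmt"})


class FormatError(ValueError):
    """A file violated its format contract."""


def is_mitochondrial_chrom(chromosome: str) -> bool:
    return chromosome.lower() in MITO_CHROMOSOMES


@dataclass
class GeneModel:
    """Annotation-level description of one gene."""

    gene_id: str
    chromosome: str
    transcript_ids: set[str] = field(default_factory=set)
    union_exon_length: int = 0
    gc_fraction: float | None = None

    @property
    def is_mitochondrial(self) -> bool:
        return is_mitochondrial_chrom(self.chromosome)


@dataclass
class AbundanceMatrix:
    """Features x samples non-negative abundance matrix.

    ``data`` is indexed by feature id with one column per sample.
    ``unit`` is one of ``counts``, ``CPM``, ``TPM``; ``level`` one of
    ``gene``, ``transcript``. ``length_normalized`` records whether a
    per-feature length correction was applied before scaling to 1e6
    (the distinction between a true TPM and a CPM-like quantity).
    """

    data: pd.DataFrame
    unit: str = "counts"
    level: str = "gene"
    length_normalized: bool = False

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "CPM", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.level not in ("gene", "transcript"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            raise ValueError("abundances must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.data.copy(), self.unit, self.level, self.length_normalized
        )


@dataclass
class GeneSet:
    set_id: str
    description: str
    genes: list[str]


class GeneSetCollection(dict):
    """Mapping set_id -> :class:`GeneSet`."""

    def add(self, gene_set: GeneSet) -> None:
        self[gene_set.set_id] = gene_set


def validate_read_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the read-record column contract and invariants.

    Returns the validated frame (unchanged) so the call can be chained.
    """
    missing = [c for c in READ_COLUMNS if c not in records.columns]
    if missing:
        raise FormatError(f"read records missing columns {missing}")
    if len(records):
        if (records["read_length"] < 1).any():
            raise FormatError("read_length must be >= 1")
        tails = records["polya_length"]
        if (tails.dropna() < 1).any():
            raise FormatError("present polya_length values must be >= 1")
        bad = set(records["condition"].dropna()) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition labels {sorted(bad)}")
        if records.duplicated(subset=["sample_id", "read_id"]).any():
            raise FormatError("(sample_id, read_id) pairs must be unique")
    return records


def usable_reads(records: pd.DataFrame) -> pd.DataFrame:
    """Reads with a gene assignment and an estimated tail length."""
    mask = records["polya_length"].notna() & records["gene_id"].notna()
    return records.loc[mask]
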