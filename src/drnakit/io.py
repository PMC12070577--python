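"""Readers and writers for the external formats used by the pipeline.

Covers the per-read poly(A) summary table (the three whitespace-delimited
columns produced by extracting the basecaller's tail-length tag), tagged
BAM files, GTF/GFF3 annotation (+ optional genome FASTA for GC content),
abundance TSVs, GMT gene-set files, the sample-metadata sidecar and the
result tables the analysis stages emit.
"""

from __future__ import annotations

import os
from collections.abc import Mapping
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .datatypes import (
    READ_COLUMNS,
    AbundanceMatrix,
    FormatError,
    GeneModel,
    GeneSet,
    GeneSetCollection,
    validate_read_records,
)

# ---------------------------------------------------------------------------
# poly(A) read-level records
# ---------------------------------------------------------------------------


def _finalize_reads(
    frame: pd.DataFrame,
    sample_id: str | None,
    batch: str | None,
    condition: str | None,
) -> pd.DataFrame:
    frame["sample_id"] = sample_id
    frame["batch"] = batch
    frame["condition"] = condition
    # tails below 1 nt mean "not estimated" and become missing
    sub = frame["polya_length"] < 1
    frame.loc[sub, "polya_length"] = np.nan
    frame = frame[READ_COLUMNS]
    frame.attrs["n_subthreshold"] = int(sub.sum())
    return frame


def read_polya_table(
    path: str | os.PathLike,
    *,
    sample_id: str | None = None,
    batch: str | None = None,
    condition: str | None = None,
    gene_id: str | None = None,
) -> pd.DataFrame:
    """Read a 3+-column whitespace table: read_id, read_length, polya_length.

    Sample-level phenotype fields are filled from the keyword arguments
    (the table itself carries none). Tail lengths below 1 nt are stored as
    missing; their count is available as ``df.attrs["n_subthreshold"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    read_ids: list[str] = []
    read_lengths: list[int] = []
    tails: list[float] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                length = int(float(fields[1]))
                tail = float(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric length field"
                ) from exc
            read_ids.append(fields[0])
            read_lengths.append(length)
            tails.append(tail)
    frame = pd.DataFrame(
        {
            "read_id": read_ids,
            "gene_id": gene_id,
            "transcript_id": None,
            "read_length": pd.array(read_lengths, dtype="int64"),
            "polya_length": pd.array(tails, dtype="float64"),
        }
    )
    return _finalize_reads(frame, sample_id, batch, condition)


def _looks_like_header(fields: list[str]) -> bool:
    # a header has a non-numeric read-length column; a malformed data line
    # (numeric length, junk tail) must still raise a parse error
    try:
        float(fields[1])
    except (ValueError, IndexError):
        return True
    return False


def read_polya_bam(
    path: str | os.PathLike,
    *,
    tag_name: str = "pt",
    gene_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
    batch: str | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Extract per-read tail lengths from a BAM carrying an integer aux tag.

    Only primary alignments are kept. ``gene_map`` maps alignment reference
    names to gene ids (genome-interval or transcript-to-gene assignment);
    when omitted, the reference name itself is taken as the gene id
    (transcriptome alignment against gene-named references). Reads lacking
    the tag get a missing tail. Counts of (total, tagged, assigned) primary
    reads are attached as ``df.attrs``.
    """
    import pysam

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple] = []
    n_total = n_tagged = n_assigned = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_secondary or aln.is_supplementary:
                continue
            n_total += 1
            tail: float = np.nan
            if aln.has_tag(tag_name):
                value = aln.get_tag(tag_name)
                if not isinstance(value, (int, np.integer)):
                    raise FormatError(
                        f"{path}: tag {tag_name} on read {aln.query_name} "
                        "is not an integer"
                    )
                n_tagged += 1
                tail = float(value)
            ref = aln.reference_name if not aln.is_unmapped else None
            gene: str | None
            if ref is None:
                gene = None
            elif gene_map is not None:
                gene = gene_map.get(ref)
            else:
                gene = ref
            if gene is not None:
                n_assigned += 1
            length = aln.query_length or (len(aln.query_sequence or "") or 1)
            rows.append((aln.query_name, gene, ref, length, tail))
    frame = pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "transcript_id", "read_length", "polya_length"],
    )
    frame = _finalize_reads(frame, sample_id, batch, condition)
    frame.attrs.update(n_total=n_total, n_tagged=n_tagged, n_assigned=n_assigned)
    return frame


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open [start, end) intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def read_annotation(
    gtf_path: str | os.PathLike, fasta_path: str | os.PathLike | None = None
) -> dict[str, GeneModel]:
    """Parse gene models from GTF/GFF3; optionally add GC from a FASTA.

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open internally; the per-gene length is the length of the union
    of its exon intervals (strand-symmetric). GC is counted over the same
    union when a genome FASTA is supplied.
    """
    gtf_path = Path(gtf_path)
    if not gtf_path.exists():
        raise FileNotFoundError(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        gid = _feature_gene_id(gene)
        genes[gid] = GeneModel(gene_id=gid, chromosome=gene.seqid)

    tx_types = ("transcript", "mRNA")
    tx_to_gene: dict[str, str] = {}
    for ttype in tx_types:
        for tx in db.features_of_type(ttype):
            gid = _feature_gene_id(tx)
            tid = _feature_transcript_id(tx)
            if gid not in genes:
                raise FormatError(
                    f"transcript {tid} references unknown gene {gid}"
                )
            if tid in tx_to_gene and tx_to_gene[tid] != gid:
                raise FormatError(f"transcript {tid} maps to multiple genes")
            tx_to_gene[tid] = gid
            genes[gid].transcript_ids.add(tid)

    exons: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genes}
    for exon in db.features_of_type("exon"):
        if exon.end < exon.start:
            raise FormatError(
                f"exon on {exon.seqid} has end {exon.end} < start {exon.start}"
            )
        gid = _feature_gene_id(exon)
        if gid not in genes:
            tid = _feature_transcript_id(exon)
            gid = tx_to_gene.get(tid, "")
            if gid not in genes:
                raise FormatError(f"exon references unknown gene/transcript")
        # 1-based inclusive -> 0-based half-open
        exons[gid].append((exon.start - 1, exon.end))

    fasta = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path))

    for gid, model in genes.items():
        merged = _merge_intervals(exons[gid])
        model.union_exon_length = sum(e - s for s, e in merged)
        if fasta is not None and merged:
            gc = total = 0
            for start, end in merged:
                seq = str(fasta[model.chromosome][start:end]).upper()
                gc += seq.count("G") + seq.count("C")
                total += sum(seq.count(b) for b in "ACGT")
            model.gc_fraction = gc / total if total else None
    return genes


def _feature_gene_id(feature) -> str:
    for key in ("gene_id", "geneID", "ID", "Parent"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return feature.id


def _feature_transcript_id(feature) -> str:
    for key in ("transcript_id", "ID"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return feature.id


def transcript_to_gene(genes: Mapping[str, GeneModel]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for gid, model in genes.items():
        for tid in model.transcript_ids:
            mapping[tid] = gid
    return mapping


# ---------------------------------------------------------------------------
# abundance matrices, gene sets, metadata, generic tables
# ---------------------------------------------------------------------------


def read_abundance(
    path: str | os.PathLike,
    unit: str = "counts",
    level: str = "gene",
    length_normalized: bool = False,
) -> AbundanceMatrix:
    """Read a features-x-samples TSV (first column feature id, header row)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids")
    return AbundanceMatrix(frame, unit=unit, level=level,
                           length_normalized=length_normalized)


def write_abundance(matrix: AbundanceMatrix, path: str | os.PathLike) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id",
                       float_format="%.12g")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: set_id <TAB> description <TAB> member genes..."""
    sets = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: empty gene set")
            sets.add(GeneSet(fields[0], fields[1], [g for g in fields[2:] if g]))
            if not sets[fields[0]].genes:
                raise FormatError(f"{path}:{lineno}: empty gene set")
    return sets


def write_gmt(sets: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for gene_set in sets.values():
            handle.write(
                "\t".join([gene_set.set_id, gene_set.description, *gene_set.genes])
                + "\n"
            )


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample sidecar TSV with columns sample_id, batch, condition."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "batch", "condition"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in metadata")
    return meta.set_index("sample_id", drop=False)


def attach_metadata(records: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Fill batch/condition on read records from the metadata sidecar."""
    records = records.copy()
    records["batch"] = records["sample_id"].map(metadata["batch"])
    records["condition"] = records["sample_id"].map(metadata["condition"])
    unknown = records.loc[records["batch"].isna(), "sample_id"].unique()
    if len(unknown):
        raise FormatError(f"samples missing from metadata: {list(unknown)[:5]}")
    return validate_read_records(records)


def write_table(frame: pd.DataFrame, path: str | os.PathLike,
                index: bool = False) -> None:
    """Write a result table as UTF-8 TSV, floats at 12 significant digits."""
    frame.to_csv(path, sep="\t", index=index, float_format="%.12g")


def read_reads_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a full read-record TSV previously written by :func:`write_table`."""
    frame = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample_id": str,
                                               "batch": str, "condition": str})
    return validate_read_records(frame)
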