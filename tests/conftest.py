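"""Shared fixtures: tiny hand-built datasets and synthetic files."""

import numpy as np
import pandas as pd
import pytest

from drnakit.datatypes import READ_COLUMNS


def make_records(rows):
    """Build a read-record frame from (read_id, sample, batch, condition,
    gene, tail) tuples."""
    frame = pd.DataFrame(
        rows, columns=["read_id", "sample_id", "batch", "condition",
                       "gene_id", "polya_length"]
    )
    frame["transcript_id"] = None
    frame["read_length"] = 1000
    return frame[READ_COLUMNS]


@pytest.fixture
def toy_records():
    """Two genes, two samples (one per condition), known tails."""
    rows = []
    for i, tail in enumerate([40.0, 50.0, 60.0]):
        rows.append((f"ra{i}", "S1", "b1", "bacterial", "geneA", tail))
    for i, tail in enumerate([80.0, 100.0, 120.0]):
        rows.append((f"rb{i}", "S2", "b2", "viral", "geneA", tail))
    for i, tail in enumerate([45.0, 45.0]):
        rows.append((f"rc{i}", "S1", "b1", "bacterial", "geneB", tail))
    return make_records(rows)


@pytest.fixture
def toy_gtf(tmp_path):
    """Two genes: one nuclear two-transcript gene, one chrM gene."""
    lines = [
        'chr1\tsrc\tgene\t1\t150\t.\t+\t.\tgene_id "g1";',
        'chr1\tsrc\ttranscript\t1\t150\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\ttranscript\t51\t150\t.\t+\t.\tgene_id "g1"; transcript_id "t2";',
        'chr1\tsrc\texon\t51\t150\t.\t+\t.\tgene_id "g1"; transcript_id "t2";',
        'chrM\tsrc\tgene\t10\t39\t.\t+\t.\tgene_id "gm";',
        'chrM\tsrc\ttranscript\t10\t39\t.\t+\t.\tgene_id "gm"; transcript_id "tm";',
        'chrM\tsrc\texon\t10\t39\t.\t+\t.\tgene_id "gm"; transcript_id "tm";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def toy_fasta(tmp_path):
    """Genome with known composition for GC counting."""
    # chr1: 150 bases = 75x "GC" (GC fraction 1.0 over any window of pairs)
    # chrM: 60 bases of A (GC fraction 0.0)
    chr1 = "GC" * 75
    chrm = "A" * 60
    path = tmp_path / "toy.fa"
    path.write_text(f">chr1\n{chr1}\n>chrM\n{chrm}\n")
    return path
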