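"""Readers and writers for the pipeline's file formats.

FASTA in (wrapped lines, CRLF tolerated, sequences uppercased, duplicate
IDs rejected); TSV and Newick out (tab-delimited, UTF-8, LF).  All
coordinates in written tables are 1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .contig import Contig
from .diversity import DendrogramNode
from .mining import SsrLocus
from .polymorphism import PolymorphismCall
from .primers import MarkerDefinition

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_tsv",
    "write_newick",
    "loci_to_frame",
    "markers_to_frame",
    "calls_to_frame",
    "read_allele_matrix",
]


def read_fasta(path) -> list[Contig]:
    """Read contigs from FASTA; tolerant of wrapped lines and CRLF.

    Sequences are uppercased.  Duplicate IDs and empty records raise
    ``ValueError``; an empty file yields an empty list.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA ID {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {record.id!r} in {path}")
        seen.add(record.id)
        contigs.append(Contig(record.id, seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path, wrap: int = 70) -> None:
    """Write contigs as FASTA wrapped at *wrap* columns."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        FastaWriter(fh, wrap=wrap).write_file(records)


def write_tsv(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a DataFrame as a TSV with header (UTF-8, LF)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, lineterminator="\n", na_rep="NA")


def write_newick(root: DendrogramNode, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(root.to_newick() + "\n")


def loci_to_frame(loci: Sequence[SsrLocus]) -> pd.DataFrame:
    """Mined loci as a table with 1-based inclusive coordinates."""
    return pd.DataFrame(
        {
            "contig_id": [l.contig_id for l in loci],
            "start": [l.start + 1 for l in loci],
            "end": [l.end for l in loci],
            "motif": [l.motif for l in loci],
            "canonical_class": [l.canonical_class for l in loci],
            "repeats": [l.repeat_count for l in loci],
            "length_bp": [l.length for l in loci],
        }
    )


def markers_to_frame(markers: Sequence[MarkerDefinition]) -> pd.DataFrame:
    """Designed markers in the layout of a primer supplementary table."""
    return pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "contig_id": [m.locus.contig_id for m in markers],
            "motif": [m.locus.motif for m in markers],
            "repeats": [m.locus.repeat_count for m in markers],
            "forward_primer": [m.primers.forward for m in markers],
            "reverse_primer": [m.primers.reverse for m in markers],
            "annealing_temp_c": [round(min(m.primers.tm_f, m.primers.tm_r), 1) for m in markers],
            "expected_product_bp": [m.expected_size for m in markers],
        }
    )


def calls_to_frame(calls: Sequence[PolymorphismCall]) -> pd.DataFrame:
    """Polymorphism calls as a table (diff is B minus A, in bp)."""
    return pd.DataFrame(
        {
            "contig_a": [c.locus_a.contig_id for c in calls],
            "contig_b": [c.locus_b.contig_id for c in calls],
            "motif_class": [c.locus_a.canonical_class for c in calls],
            "orientation": [c.orientation for c in calls],
            "len_a": [c.locus_a.length for c in calls],
            "len_b": [c.locus_b.length for c in calls],
            "diff": [c.diff for c in calls],
            "passes_type1": [c.passes_type1 for c in calls],
            "passes_min_diff": [c.passes_min_diff for c in calls],
        }
    )


def read_allele_matrix(path) -> pd.DataFrame:
    """Read a genotype x locus allele matrix TSV (genotypes as rows,
    ``NA`` for missing) into an Int64 DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.astype("Int64")
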