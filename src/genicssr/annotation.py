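"""ORF prediction and SSR gene-region classification.

Each contig gets at most one gene model: the longest ATG-to-stop open
reading frame (>= ``min_orf_len`` bp, stop codon included) over all six
frames.  An SSR is then labelled CDS if it overlaps the ORF at all,
5'-UTR if it lies entirely upstream on the oriented contig, 3'-UTR if
entirely downstream, and "unknown" when no qualifying ORF exists.  The
longest-ORF heuristic substitutes for ab initio gene prediction, which is
adequate on transcript contigs with a single dominant coding region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .contig import revcomp
from .mining import SsrLocus

__all__ = [
    "OrfModel",
    "REGION_5UTR",
    "REGION_CDS",
    "REGION_3UTR",
    "REGION_UNKNOWN",
    "find_longest_orf",
    "classify_ssr_region",
    "region_polymorphism_summary",
]

REGION_5UTR = "5'-UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3'-UTR"
REGION_UNKNOWN = "unknown"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfModel:
    """Longest predicted ORF on a contig.

    ``cds_start``/``cds_end`` are 0-based half-open coordinates on the
    *oriented* contig (the reverse complement when ``strand == '-'``);
    ``contig_length`` allows mapping back to the input orientation.
    """

    contig_id: str
    strand: str
    cds_start: int
    cds_end: int
    contig_length: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError("ORF length must be a multiple of 3")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start


def _orfs_one_strand(seq: str, min_len: int) -> list[tuple[int, int]]:
    """All maximal ATG..stop ORFs (stop included) >= min_len, as
    0-based half-open intervals, for one strand."""
    out: list[tuple[int, int]] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in _STOPS:
                if pos + 3 - start >= min_len:
                    out.append((start, pos + 3))
                start = None
    return out


def find_longest_orf(
    sequence: str, min_orf_len: int = 150, contig_id: str = ""
) -> OrfModel | None:
    """Longest ATG-to-stop ORF over all six frames, or ``None``.

    Ties are broken in favour of the plus strand, then the smallest start
    on the oriented contig.
    """
    sequence = sequence.upper()
    candidates: list[tuple[int, int, int, str]] = []  # (-len, strand_rank, start, strand)
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for s, e in _orfs_one_strand(seq, min_orf_len):
            candidates.append((-(e - s), 0 if strand == "+" else 1, s, strand))
    if not candidates:
        return None
    neg_len, _, start, strand = min(candidates)
    return OrfModel(
        contig_id=contig_id,
        strand=strand,
        cds_start=start,
        cds_end=start - neg_len,
        contig_length=len(sequence),
    )


def classify_ssr_region(locus: SsrLocus, orf: OrfModel | None) -> str:
    """Label an SSR relative to the predicted ORF.

    Any overlap with the CDS interval counts as CDS (a boundary-spanning
    SSR gets a single label); otherwise the side of the CDS on the
    oriented contig decides 5'- vs 3'-UTR.
    """
    if orf is None:
        return REGION_UNKNOWN
    if orf.strand == "+":
        s, e = locus.start, locus.end
    else:
        s = orf.contig_length - locus.end
        e = orf.contig_length - locus.start
    if s < orf.cds_end and e > orf.cds_start:
        return REGION_CDS
    if e <= orf.cds_start:
        return REGION_5UTR
    return REGION_3UTR


def region_polymorphism_summary(
    labels: Sequence[str], polymorphic_flags: Sequence[bool]
) -> pd.DataFrame:
    """Per-region marker counts and percent polymorphic (1 d.p.).

    Rows are indexed by region label; columns ``n``, ``n_polymorphic``,
    ``percent_polymorphic``, plus ``percent_of_total`` giving each
    region's share of all classified loci.
    """
    if len(labels) != len(polymorphic_flags):
        raise ValueError("labels and polymorphic_flags differ in length")
    df = pd.DataFrame({"region": list(labels), "poly": list(polymorphic_flags)})
    if df.empty:
        return pd.DataFrame(
            columns=["n", "n_polymorphic", "percent_polymorphic", "percent_of_total"]
        )
    grouped = df.groupby("region", sort=True)["poly"].agg(["count", "sum"])
    out = pd.DataFrame(
        {
            "n": grouped["count"].astype(int),
            "n_polymorphic": grouped["sum"].astype(int),
        }
    )
    out["percent_polymorphic"] = (100.0 * out["n_polymorphic"] / out["n"]).round(1)
    out["percent_of_total"] = (100.0 * out["n"] / out["n"].sum()).round(1)
    out.index.name = "region"
    return out
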