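"""In silico SSR length polymorphism calling between two varieties'
contig sets.

For every mined SSR locus in variety A, the ``anchor_len`` bases
immediately 5' and 3' of the run are looked up in variety B (both
strands).  A call is made only when each anchor occurs exactly once in
all of B, both land on the same contig and strand in consistent order,
and the sequence bracketed between them is a perfect run of the same
motif (hence the same canonical class).  Ambiguous or partial anchor
hits produce no call and are logged.  This replaces manual inspection of
pairwise contig alignments with a deterministic, testable procedure.

The signed allele difference is B minus A; retained calls are usually
restricted to type I loci (both alleles >= 20 bp) with |diff| >= 4 bp,
the size difference resolvable on agarose gels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .contig import Contig, revcomp
from .mining import SsrLocus

__all__ = ["PolymorphismCall", "match_shared_loci", "filter_calls"]

#: Type I SSR threshold: total repeat length in bp.
TYPE_I_MIN_LEN = 20
#: Minimum allele size difference resolvable on agarose gels, in bp.
MIN_GEL_DIFF = 4


@dataclass(frozen=True)
class PolymorphismCall:
    """A matched locus pair between varieties A and B.

    ``locus_b`` coordinates refer to the forward strand of the B contig;
    ``orientation`` records whether the match was to B's reverse strand.
    """

    locus_a: SsrLocus
    locus_b: SsrLocus
    orientation: str  # '+' or '-'

    @property
    def diff(self) -> int:
        """Signed allele length difference in bp, B minus A."""
        return self.locus_b.length - self.locus_a.length

    @property
    def passes_type1(self) -> bool:
        return (
            self.locus_a.length >= TYPE_I_MIN_LEN
            and self.locus_b.length >= TYPE_I_MIN_LEN
        )

    @property
    def passes_min_diff(self) -> bool:
        return abs(self.diff) >= MIN_GEL_DIFF


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def match_shared_loci(
    contigs_a: Sequence[Contig],
    loci_a: Iterable[SsrLocus],
    contigs_b: Sequence[Contig],
    anchor_len: int = 25,
) -> tuple[list[PolymorphismCall], list[tuple[SsrLocus, str]]]:
    """Match A-variety SSR loci into the B-variety contig set by unique
    flanking anchors.

    Returns ``(calls, skipped)`` where *skipped* pairs each unmatched
    locus with a reason (``anchor_out_of_bounds``, ``anchor_not_unique``,
    ``anchors_inconsistent``, ``gap_not_same_motif_run``).  B loci need
    not be supplied: the bracketed gap is verified directly to be a
    perfect run of the A motif, which is equivalent for perfect SSRs and
    keeps the procedure symmetric.
    """
    if anchor_len < 1:
        raise ValueError("anchor_len must be >= 1")
    seq_a = {c.id: c.sequence for c in contigs_a}
    strands_b = [(c.id, "+", c.sequence) for c in contigs_b] + [
        (c.id, "-", revcomp(c.sequence)) for c in contigs_b
    ]

    calls: list[PolymorphismCall] = []
    skipped: list[tuple[SsrLocus, str]] = []
    for locus in loci_a:
        seq = seq_a[locus.contig_id]
        if locus.start < anchor_len or locus.end + anchor_len > len(seq):
            skipped.append((locus, "anchor_out_of_bounds"))
            continue
        left = seq[locus.start - anchor_len : locus.start]
        right = seq[locus.end : locus.end + anchor_len]

        left_hits = [
            (cid, strand, pos, len(s))
            for cid, strand, s in strands_b
            for pos in _find_all(s, left)
        ]
        right_hits = [
            (cid, strand, pos, len(s))
            for cid, strand, s in strands_b
            for pos in _find_all(s, right)
        ]
        if len(left_hits) != 1 or len(right_hits) != 1:
            reason = (
                "anchor_not_found"
                if not left_hits or not right_hits
                else "anchor_not_unique"
            )
            skipped.append((locus, reason))
            continue
        (lcid, lstrand, lpos, blen) = left_hits[0]
        (rcid, rstrand, rpos, _) = right_hits[0]
        gap_start = lpos + anchor_len
        if lcid != rcid or lstrand != rstrand or rpos < gap_start:
            skipped.append((locus, "anchors_inconsistent"))
            continue

        oriented = next(s for cid, st, s in strands_b if cid == lcid and st == lstrand)
        gap = oriented[gap_start:rpos]
        k = locus.unit_length
        if not gap or len(gap) % k != 0 or gap != locus.motif * (len(gap) // k):
            skipped.append((locus, "gap_not_same_motif_run"))
            continue
        n_b = len(gap) // k

        if lstrand == "+":
            b_start, b_motif = gap_start, locus.motif
        else:
            # mirror the oriented interval [gap_start, rpos) back to the
            # forward strand of the B contig
            b_start, b_motif = blen - rpos, revcomp(locus.motif)
        locus_b = SsrLocus(
            contig_id=lcid,
            motif=b_motif,
            repeat_count=n_b,
            start=b_start,
            end=b_start + k * n_b,
        )
        calls.append(PolymorphismCall(locus_a=locus, locus_b=locus_b, orientation=lstrand))
    return calls, skipped


def filter_calls(
    calls: Iterable[PolymorphismCall],
    min_len: int = TYPE_I_MIN_LEN,
    min_diff: int = MIN_GEL_DIFF,
) -> list[PolymorphismCall]:
    """Retain calls whose alleles are both >= *min_len* bp long and whose
    absolute size difference is >= *min_diff* bp."""
    return [
        c
        for c in calls
        if c.locus_a.length >= min_len
        and c.locus_b.length >= min_len
        and abs(c.diff) >= min_diff
    ]
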