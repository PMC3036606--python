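"""Perfect microsatellite (SSR) mining and frequency statistics.

The miner reports every maximal perfect tandem repeat whose primitive unit
is 2-6 nt long and repeats at least five times (so the shortest reportable
locus is 10 bp).  Mononucleotide runs are excluded, as are "compound"
(complex) SSRs — two threshold-passing runs closer together than a
configurable gap.  These thresholds reproduce the standard genic-SSR
screening criteria used for transcriptome marker development.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contig import Contig, revcomp, validate_nucleotides

__all__ = [
    "MiningParams",
    "SsrLocus",
    "FrequencySummary",
    "find_perfect_repeats",
    "mine_contigs",
    "canonical_class",
    "is_primitive",
    "summarize_frequencies",
    "select_validation_panel",
]

_UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class MiningParams:
    """Thresholds controlling SSR detection.

    Defaults: perfect repeats of 2-6 nt units with >= 5 reiterations and
    total length >= 10 bp; mononucleotide runs excluded; two runs closer
    than ``compound_gap`` bp are both discarded as a compound SSR.
    """

    min_unit: int = 2
    max_unit: int = 6
    min_repeats: int = 5
    min_length: int = 10
    compound_gap: int = 10
    exclude_mononucleotide: bool = True
    exclude_compound: bool = True

    def __post_init__(self) -> None:
        if self.exclude_mononucleotide and self.min_unit < 2:
            raise ValueError("min_unit must be >= 2 when mononucleotides are excluded")
        if not 1 <= self.min_unit <= self.max_unit:
            raise ValueError("require 1 <= min_unit <= max_unit")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if self.compound_gap < 0:
            raise ValueError("compound_gap must be >= 0")


@dataclass(frozen=True)
class SsrLocus:
    """One perfect repeat run, reported at its primitive motif.

    ``[start, end)`` covers complete repeat units only, so
    ``end - start == len(motif) * repeat_count``.
    """

    contig_id: str
    motif: str
    repeat_count: int
    start: int
    end: int
    canonical_class: str = field(default="")

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError("locus span must equal motif length x repeat count")
        if not self.canonical_class:
            object.__setattr__(self, "canonical_class", canonical_class(self.motif))

    @property
    def length(self) -> int:
        """Total SSR length in bp (complete units only)."""
        return self.end - self.start

    @property
    def unit_length(self) -> int:
        return len(self.motif)


def is_primitive(motif: str) -> bool:
    """True if *motif* is not itself a tandem repeat of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Canonical class key of a repeat motif.

    A motif and its reverse complement describe the same locus read from
    either strand, so the class key is the lexicographically smaller of
    the two (A < C < G < T).  Cyclic rotations are *not* collapsed: TC/GA
    and AG/CT count as distinct classes, matching the convention of
    EST-SSR frequency tables.
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {len(motif)}")
    validate_nucleotides(motif, allow_n=False)
    return min(motif, revcomp(motif))


_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def find_perfect_repeats(
    sequence: str,
    params: MiningParams | None = None,
    contig_id: str = "",
) -> list[SsrLocus]:
    """Detect all maximal perfect tandem repeats passing the thresholds.

    Each maximal periodic stretch is reported once, at its primitive
    motif, with the repeat count truncated to complete reiterations (a
    trailing partial unit extends neither the count nor the coordinates).
    ``N`` never participates in a repeat.  Runs are returned sorted by
    start; the compound rule then removes clustered runs if
    ``exclude_compound`` is set.
    """
    params = params or MiningParams()
    if not sequence:
        return []
    sequence = sequence.upper()
    validate_nucleotides(sequence)

    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, _ACGT_CODES)

    min_unit = max(params.min_unit, 2) if params.exclude_mononucleotide else params.min_unit
    loci: list[SsrLocus] = []
    for k in range(min_unit, params.max_unit + 1):
        if len(arr) < 2 * k:
            break
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        padded = np.zeros(eq.size + 2, dtype=np.int8)
        padded[1:-1] = eq
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        min_eq = k * (params.min_repeats - 1)
        for s, e in zip(run_starts, run_ends):
            if e - s < min_eq:
                continue
            n = (e - s) // k + 1  # complete units in the stretch [s, e + k)
            motif = sequence[s : s + k]
            if not is_primitive(motif):
                continue
            if k * n < params.min_length or n < params.min_repeats:
                continue
            loci.append(
                SsrLocus(contig_id=contig_id, motif=motif, repeat_count=int(n),
                         start=int(s), end=int(s + k * n))
            )

    loci.sort(key=lambda l: (l.start, l.end, l.motif))
    if params.exclude_compound:
        loci = _drop_compound(loci, params.compound_gap)
    return loci


def _drop_compound(loci: list[SsrLocus], gap: int) -> list[SsrLocus]:
    """Remove every member of any cluster of runs closer than *gap* bp."""
    if not loci:
        return loci
    kept: list[SsrLocus] = []
    cluster: list[SsrLocus] = [loci[0]]
    cluster_end = loci[0].end
    for locus in loci[1:]:
        if locus.start - cluster_end < gap:
            cluster.append(locus)
            cluster_end = max(cluster_end, locus.end)
        else:
            if len(cluster) == 1:
                kept.append(cluster[0])
            cluster = [locus]
            cluster_end = locus.end
    if len(cluster) == 1:
        kept.append(cluster[0])
    return kept


def mine_contigs(
    contigs: Iterable[Contig], params: MiningParams | None = None
) -> list[SsrLocus]:
    """Run :func:`find_perfect_repeats` over a contig collection."""
    out: list[SsrLocus] = []
    for contig in contigs:
        out.extend(find_perfect_repeats(contig.sequence, params, contig.id))
    return out


@dataclass
class FrequencySummary:
    """Frequency tables describing a mined locus set.

    ``abundance_kbp`` is the kbp of surveyed sequence per SSR locus
    (``NaN`` when no loci were found).
    """

    total_loci: int
    by_unit_length: pd.DataFrame
    by_repeat_count: pd.DataFrame
    by_length_bp: pd.DataFrame
    by_class: pd.DataFrame
    loci_per_contig: dict[int, int]
    abundance_kbp: float
    contigs_with_ssr: int


def _freq_table(counter: Counter, total: int, index_name: str) -> pd.DataFrame:
    idx = sorted(counter)
    counts = [counter[i] for i in idx]
    pct = [100.0 * c / total if total else float("nan") for c in counts]
    df = pd.DataFrame({"count": counts, "percent": pct},
                      index=pd.Index(idx, name=index_name))
    return df


def summarize_frequencies(
    loci: Sequence[SsrLocus], total_sequence_bp: int, n_contigs: int
) -> FrequencySummary:
    """Tabulate locus counts by unit length, repeat number, length and
    canonical class, plus per-contig multiplicity and overall abundance."""
    total = len(loci)
    by_unit = Counter(l.unit_length for l in loci)
    by_reps = Counter(l.repeat_count for l in loci)
    by_len = Counter(l.length for l in loci)
    by_cls = Counter(l.canonical_class for l in loci)
    per_contig = Counter(l.contig_id for l in loci)
    histogram = dict(sorted(Counter(per_contig.values()).items()))
    abundance = (total_sequence_bp / 1000.0 / total) if total else float("nan")

    unit_df = _freq_table(by_unit, total, "unit_length")
    unit_df["unit_name"] = [_UNIT_NAMES.get(i, str(i)) for i in unit_df.index]
    return FrequencySummary(
        total_loci=total,
        by_unit_length=unit_df,
        by_repeat_count=_freq_table(by_reps, total, "repeat_count"),
        by_length_bp=_freq_table(by_len, total, "length_bp"),
        by_class=_freq_table(by_cls, total, "canonical_class"),
        loci_per_contig=histogram,
        abundance_kbp=abundance,
        contigs_with_ssr=len(per_contig),
    )


def select_validation_panel(
    loci: Sequence[SsrLocus], min_len: int
) -> list[SsrLocus]:
    """Retain loci of total length >= *min_len* bp, preserving order.

    Long loci (>= 18 bp, and especially type I loci >= 20 bp) are the
    standard choice for wet-lab validation because length polymorphism is
    far more likely in long repeats.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [l for l in loci if l.length >= min_len]
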