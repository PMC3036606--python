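"""Flanking-primer selection for SSR loci and marker ID assignment.

Candidate windows in both flanks are enumerated exhaustively and filtered
by hard constraints (length 20-25 nt, Tm 50-60 degC, GC 40-60 %, a single
G/C clamp at the 3' terminus, product 100-200 bp spanning the whole SSR).
Among passing pairs the one minimising a simple additive penalty around
the optima (22 nt, 55 degC, 50 % GC, 150 bp product) is returned.

The melting-temperature formula and penalty weights are this package's
own (documented, configurable) choices: primer screening here is a
constraint filter, not a thermodynamic model — no duplex dG, hairpin or
self-complementarity screening is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .contig import Contig, gc_percent, revcomp, validate_nucleotides
from .mining import SsrLocus

__all__ = [
    "PrimerParams",
    "PrimerPair",
    "MarkerDefinition",
    "melting_temperature",
    "design_primers",
    "assign_marker_ids",
]


@dataclass(frozen=True)
class PrimerParams:
    """Constraint ranges and optima for primer selection."""

    primer_len_range: tuple[int, int] = (20, 25)
    primer_len_opt: int = 22
    product_range: tuple[int, int] = (100, 200)
    product_opt: int = 150
    tm_range: tuple[float, float] = (50.0, 60.0)
    tm_opt: float = 55.0
    gc_range: tuple[float, float] = (40.0, 60.0)
    gc_opt: float = 50.0
    gc_clamp: int = 1
    max_candidates: int | None = None

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (*self.primer_len_range, "primer_len_range"),
            (*self.product_range, "product_range"),
            (*self.tm_range, "tm_range"),
            (*self.gc_range, "gc_range"),
        ):
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if not self.primer_len_range[0] <= self.primer_len_opt <= self.primer_len_range[1]:
            raise ValueError("primer_len_opt outside primer_len_range")
        if not self.tm_range[0] <= self.tm_opt <= self.tm_range[1]:
            raise ValueError("tm_opt outside tm_range")
        if not self.gc_range[0] <= self.gc_opt <= self.gc_range[1]:
            raise ValueError("gc_opt outside gc_range")
        if self.gc_clamp < 0:
            raise ValueError("gc_clamp must be >= 0")


@dataclass(frozen=True)
class PrimerPair:
    """A designed primer pair.

    ``reverse`` is given 5'->3' on the antisense strand.  ``forward_start``
    and ``reverse_end`` are 0-based sense-strand coordinates of the
    amplified product, so ``product_size == reverse_end - forward_start``.
    """

    forward: str
    reverse: str
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size: int
    penalty: float
    forward_start: int
    reverse_end: int


@dataclass(frozen=True)
class MarkerDefinition:
    """An SSR locus with its primer pair under a serial ASSR marker ID."""

    marker_id: str
    locus: SsrLocus
    primers: PrimerPair

    @property
    def expected_size(self) -> int:
        return self.primers.product_size


def melting_temperature(primer: str) -> float:
    """Primer Tm in degC.

    Wallace rule 2(A+T) + 4(G+C) for primers shorter than 14 nt, else the
    GC-fraction formula 64.9 + 41 x (GC - 16.4) / length.
    """
    if len(primer) < 8:
        raise ValueError("primer must be at least 8 nt")
    validate_nucleotides(primer, allow_n=False)
    gc = primer.count("G") + primer.count("C")
    if len(primer) < 14:
        return 2.0 * (len(primer) - gc) + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(primer)


def _primer_penalty(length: int, tm: float, gc: float, p: PrimerParams) -> float:
    return abs(length - p.primer_len_opt) + abs(tm - p.tm_opt) + 0.5 * abs(gc - p.gc_opt)


def _passes(length: int, tm: float, gc: float, p: PrimerParams) -> bool:
    return (
        p.primer_len_range[0] <= length <= p.primer_len_range[1]
        and p.tm_range[0] <= tm <= p.tm_range[1]
        and p.gc_range[0] <= gc <= p.gc_range[1]
    )


def _clamp_ok(primer: str, p: PrimerParams) -> bool:
    # "gc_clamp = c": the c 3'-terminal bases must all be G or C.
    if p.gc_clamp == 0:
        return True
    tail = primer[-p.gc_clamp :]
    return len(tail) == p.gc_clamp and all(b in "GC" for b in tail)


def design_primers(
    contig: Contig,
    locus: SsrLocus,
    params: PrimerParams | None = None,
) -> PrimerPair | None:
    """Choose the best-scoring primer pair flanking *locus*, or ``None``
    when the flanks admit no pair (too short, or no window satisfies the
    constraints).

    Ties on penalty are broken by the leftmost forward primer, then the
    smallest product.
    """
    params = params or PrimerParams()
    seq = contig.sequence
    if not (0 <= locus.start and locus.end <= len(seq)):
        raise ValueError(
            f"locus [{locus.start}, {locus.end}) outside contig {contig.id!r} "
            f"of length {len(seq)}"
        )

    lmin, lmax = params.primer_len_range

    # Forward candidates live entirely in the 5' flank [0, locus.start).
    fwd: list[tuple[float, int, int]] = []  # (penalty, start, length)
    for flen in range(lmin, lmax + 1):
        for fstart in range(0, locus.start - flen + 1):
            window = seq[fstart : fstart + flen]
            if "N" in window or not _clamp_ok(window, params):
                continue
            tm = melting_temperature(window)
            gc = gc_percent(window)
            if _passes(flen, tm, gc, params):
                fwd.append((_primer_penalty(flen, tm, gc, params), fstart, flen))
    if not fwd:
        return None

    # Reverse candidates live in the 3' flank [locus.end, len); the primer
    # itself is the reverse complement of the sense window, so its 3' end
    # sits at the window start.
    rev_by_end: dict[int, list[tuple[float, int, int]]] = {}
    n_rev = 0
    for rlen in range(lmin, lmax + 1):
        for rstart in range(locus.end, len(seq) - rlen + 1):
            window = seq[rstart : rstart + rlen]
            if "N" in window:
                continue
            primer = revcomp(window)
            if not _clamp_ok(primer, params):
                continue
            tm = melting_temperature(primer)
            gc = gc_percent(primer)
            if _passes(rlen, tm, gc, params):
                rev_by_end.setdefault(rstart + rlen, []).append(
                    (_primer_penalty(rlen, tm, gc, params), rstart, rlen)
                )
                n_rev += 1
    if not n_rev:
        return None

    if params.max_candidates is not None:
        fwd = sorted(fwd)[: params.max_candidates]
        flat = sorted(
            (cand, end) for end, cands in rev_by_end.items() for cand in cands
        )[: params.max_candidates]
        rev_by_end = {}
        for cand, end in flat:
            rev_by_end.setdefault(end, []).append(cand)

    plo, phi = params.product_range
    best: tuple[float, int, int] | None = None  # (penalty, fstart, product)
    best_detail: tuple | None = None
    for fpen, fstart, flen in sorted(fwd, key=lambda c: c[1]):
        for rend in range(max(fstart + plo, locus.end + lmin), min(fstart + phi, len(seq)) + 1):
            for rpen, rstart, rlen in rev_by_end.get(rend, ()):
                product = rend - fstart
                pen = fpen + rpen + 0.02 * abs(product - params.product_opt)
                key = (pen, fstart, product)
                if best is None or key < best:
                    best = key
                    best_detail = (fstart, flen, rstart, rlen, product, pen)

    if best_detail is None:
        return None
    fstart, flen, rstart, rlen, product, pen = best_detail
    fprimer = seq[fstart : fstart + flen]
    rprimer = revcomp(seq[rstart : rstart + rlen])
    return PrimerPair(
        forward=fprimer,
        reverse=rprimer,
        tm_f=melting_temperature(fprimer),
        tm_r=melting_temperature(rprimer),
        gc_f=gc_percent(fprimer),
        gc_r=gc_percent(rprimer),
        product_size=product,
        penalty=pen,
        forward_start=fstart,
        reverse_end=rstart + rlen,
    )


def assign_marker_ids(
    designed: Sequence[tuple[SsrLocus, PrimerPair]], prefix: str = "ASSR"
) -> list[MarkerDefinition]:
    """Assign dense serial marker IDs (``ASSR1``, ``ASSR2``, ...) in the
    given locus discovery order."""
    return [
        MarkerDefinition(marker_id=f"{prefix}{i}", locus=locus, primers=pair)
        for i, (locus, pair) in enumerate(designed, start=1)
    ]
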