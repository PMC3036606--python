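"""Synthetic transcript contigs, variety pairs and genotype panels with
planted ground truth.

The generator emulates the statistical structure of a deep-transcriptome
genic-SSR survey: unigene contigs of which ~7.6 % carry one perfect SSR,
with a di:tri:tetra:penta:hexa motif-class mix of roughly 60:35:2:1:3,
repeat counts decaying geometrically over 5..22 reiterations, and SSR
placement split across 5'-UTR / CDS / 3'-UTR of a planted ORF.  Each
contig is built as ``5'UTR + (ATG + codons + stop) + 3'UTR`` and the
ground truth is *certified*: flank bases are re-drawn until default-
parameter mining recovers the planted run at its exact coordinates with
no other threshold-passing run within 10 bp, and a contig is re-generated
if a chance competing ORF would beat the planted one, so region labels
are unambiguous by construction.

CDS-planted SSRs use frame-safe insertion: only motifs whose length is a
multiple of 3 (tri- and hexanucleotide), inserted at codon boundaries
with no in-frame stop.  Other motif classes go to UTRs unless explicitly
allowed.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    classify_ssr_region,
    find_longest_orf,
)
from .contig import Contig
from .mining import MiningParams, find_perfect_repeats, is_primitive

__all__ = [
    "GeneratorConfig",
    "PlantedLocus",
    "VarietyPairTruth",
    "generate_contig_set",
    "generate_variety_pair",
    "generate_allele_matrix",
    "generate_f2_genotypes",
    "write_truth_table",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(
    [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
)

# Default motif-class weights by unit length (di..hexa), matching the
# observed frequency mix of a legume transcriptome SSR survey.
_DEFAULT_CLASS_WEIGHTS: dict[int, float] = {
    2: 0.6041,
    3: 0.3452,
    4: 0.0167,
    5: 0.0076,
    6: 0.0264,
}
# Region placement: 5'-UTR / CDS / 3'-UTR shares of validated markers.
_DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    REGION_5UTR: 87 / 550,
    REGION_CDS: 339 / 550,
    REGION_3UTR: 124 / 550,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic contig generator.

    ``ssr_probability`` is the fraction of contigs carrying one planted
    SSR; ``repeat_count_ratio`` is the decay ratio of the truncated
    geometric distribution over ``repeat_count_range`` reiterations.
    All weight sets must sum to 1 (+- 1e-9).
    """

    n_contigs: int = 500
    contig_length_range: tuple[int, int] = (300, 1500)
    ssr_probability: float = 0.076
    motif_class_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_WEIGHTS)
    )
    repeat_count_range: tuple[int, int] = (5, 22)
    repeat_count_ratio: float = 0.55
    repeat_count_distribution: Mapping[int, float] | None = None
    region_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_WEIGHTS)
    )
    gc_content: float = 0.45
    cds_fraction: float = 0.5
    min_cds_len: int = 150
    allow_cds_non_trinucleotide: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.contig_length_range
        if not 0 < lo <= hi:
            raise ValueError("contig_length_range must be a positive interval")
        if lo < self.min_cds_len + 80:
            raise ValueError(
                "contig_length_range too short to host the minimum CDS plus UTRs"
            )
        for unit in self.motif_class_weights:
            if not 2 <= unit <= 6:
                raise ValueError(f"motif unit length {unit} outside 2-6")
        if not 0.0 <= self.ssr_probability <= 1.0:
            raise ValueError("ssr_probability must be in [0, 1]")
        for name, weights in (
            ("motif_class_weights", self.motif_class_weights.values()),
            ("region_weights", self.region_weights.values()),
        ):
            total = float(sum(weights))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sum to {total}, expected 1")
        if self.repeat_count_distribution is not None:
            total = float(sum(self.repeat_count_distribution.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError("repeat_count_distribution must sum to 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if set(self.region_weights) != {REGION_5UTR, REGION_CDS, REGION_3UTR}:
            raise ValueError("region_weights must cover 5'-UTR, CDS and 3'-UTR")

    def repeat_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """(repeat counts, probabilities) of the planted-repeat-count law."""
        if self.repeat_count_distribution is not None:
            items = sorted(self.repeat_count_distribution.items())
            return np.array([k for k, _ in items]), np.array([v for _, v in items])
        lo, hi = self.repeat_count_range
        counts = np.arange(lo, hi + 1)
        probs = self.repeat_count_ratio ** (counts - lo)
        return counts, probs / probs.sum()


@dataclass(frozen=True)
class PlantedLocus:
    """Ground truth for one planted SSR run (0-based coordinates)."""

    contig_id: str
    motif: str
    repeat_count: int
    start: int
    region: str

    @property
    def length(self) -> int:
        return len(self.motif) * self.repeat_count

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class VarietyPairTruth:
    """Ground truth for one shared locus between two varieties' contigs."""

    contig_id_a: str
    contig_id_b: str
    shared: bool
    locus_a: PlantedLocus
    locus_b: PlantedLocus

    @property
    def allele_length_difference(self) -> int:
        """Signed length difference in bp (B minus A); a multiple of the
        motif length."""
        return self.locus_b.length - self.locus_a.length


# Mining settings used internally to certify planted truth: see every
# threshold-passing run, including compound-adjacent ones.
_SCAN_PARAMS = MiningParams(exclude_compound=False)
_SCRUB_MARGIN = 10  # bp around a planted run kept free of other runs
_CERTIFY_ORF_MIN = 150  # bp; matches the default annotation threshold


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _scrub_atg(utr: str, rng: np.random.Generator) -> str:
    """Remove every ATG triplet from a 5'-UTR so no upstream start codon
    competes with the planted ORF."""
    while True:
        i = utr.find("ATG")
        if i < 0:
            return utr
        utr = utr[: i + 2] + str(rng.choice(np.array(list("ACT")))) + utr[i + 3 :]


def _draw_motif(rng: np.random.Generator, unit: int, for_cds: bool) -> str:
    while True:
        motif = "".join(rng.choice(_BASES, size=unit))
        if not is_primitive(motif):
            continue
        if for_cds and unit % 3 == 0 and any(
            motif[i : i + 3] in _STOPS for i in range(0, unit, 3)
        ):
            continue
        return motif


def _planted_matches(locus, planted: PlantedLocus) -> bool:
    return (
        locus.start == planted.start
        and locus.motif == planted.motif
        and locus.repeat_count == planted.repeat_count
    )


def _certify_flanks(
    seq: str,
    planted: PlantedLocus,
    cds_interval: tuple[int, int],
    rng: np.random.Generator,
) -> str | None:
    """Mutate flank bases until the planted run is recovered exactly by
    the miner and no other threshold-passing run lies within the scrub
    margin (which would shift its coordinates or trigger the compound
    rule).  Returns the certified sequence, or ``None`` if the scrub did
    not converge (caller re-generates the contig)."""
    cds_start, cds_end = cds_interval
    for _ in range(300):
        loci = find_perfect_repeats(seq, _SCAN_PARAMS)
        site_ok = any(_planted_matches(l, planted) for l in loci)
        conflicts = [
            l
            for l in loci
            if not _planted_matches(l, planted)
            and l.start < planted.end + _SCRUB_MARGIN
            and l.end > planted.start - _SCRUB_MARGIN
        ]
        if site_ok and not conflicts:
            return seq
        target = conflicts[0]
        positions = [
            p
            for p in range(target.start, target.end)
            if not planted.start <= p < planted.end
            # never touch the planted ORF's start or stop codon
            and not (cds_start <= p < cds_start + 3)
            and not (cds_end - 3 <= p < cds_end)
        ]
        if not positions:
            return None
        pos = int(positions[rng.integers(len(positions))])
        for base in rng.permutation(_BASES):
            if base == seq[pos]:
                continue
            candidate = seq[:pos] + str(base) + seq[pos + 1 :]
            if cds_start <= pos < cds_end:
                codon_start = cds_start + 3 * ((pos - cds_start) // 3)
                if candidate[codon_start : codon_start + 3] in _STOPS:
                    continue
            seq = candidate
            break
    return None


def _attempt_contig(
    config: GeneratorConfig,
    rng: np.random.Generator,
    contig_id: str,
    force_ssr: bool,
) -> tuple[Contig, PlantedLocus | None, tuple[int, int]]:
    lo, hi = config.contig_length_range
    length = int(rng.integers(lo, hi + 1))
    cds_len = min(
        max(config.min_cds_len, int(round(length * config.cds_fraction))),
        length - 60,
    )
    cds_len -= cds_len % 3
    n_body = cds_len // 3 - 2
    # UTRs of >= 35 bp keep every planted run at least 30 bp from the
    # contig ends, so 25 bp polymorphism anchors always fit in the flanks.
    utr5_len = int(rng.integers(35, length - cds_len - 35 + 1))
    utr3_len = length - cds_len - utr5_len

    utr5 = _scrub_atg(_random_bases(rng, utr5_len, config.gc_content), rng)
    body = "".join(rng.choice(_CODONS, size=n_body))
    stop = str(rng.choice(np.array(sorted(_STOPS))))
    utr3 = _random_bases(rng, utr3_len, config.gc_content)

    plant = force_ssr or (rng.random() < config.ssr_probability)
    if not plant:
        seq = utr5 + "ATG" + body + stop + utr3
        return Contig(contig_id, seq), None, (utr5_len, utr5_len + cds_len)

    units = sorted(config.motif_class_weights)
    unit_probs = np.array([config.motif_class_weights[u] for u in units])
    unit = int(rng.choice(units, p=unit_probs))

    region_names = [REGION_5UTR, REGION_CDS, REGION_3UTR]
    region_probs = np.array([config.region_weights[r] for r in region_names])
    frame_safe = unit % 3 == 0
    if not frame_safe and not config.allow_cds_non_trinucleotide:
        # CDS weight is redistributed over the UTRs for frame-breaking units.
        region_probs = np.array([region_probs[0], 0.0, region_probs[2]])
        region_probs = region_probs / region_probs.sum()
    region = str(rng.choice(region_names, p=region_probs))

    motif = _draw_motif(rng, unit, for_cds=(region == REGION_CDS and frame_safe))
    counts, probs = config.repeat_probabilities()
    n_rep = int(rng.choice(counts, p=probs))
    run = motif * n_rep

    if region == REGION_CDS:
        j = int(rng.integers(1, max(2, n_body)))  # codon boundary inside body
        start = utr5_len + 3 + 3 * j
        seq = utr5 + "ATG" + body[: 3 * j] + run + body[3 * j :] + stop + utr3
        cds_interval = (utr5_len, utr5_len + cds_len + len(run))
    elif region == REGION_5UTR:
        off = int(rng.integers(30, max(31, utr5_len - 2)))
        start = off
        seq = utr5[:off] + run + utr5[off:] + "ATG" + body + stop + utr3
        cds_interval = (utr5_len + len(run), utr5_len + len(run) + cds_len)
    else:
        off = int(rng.integers(3, max(4, utr3_len - 29)))
        start = utr5_len + cds_len + off
        seq = utr5 + "ATG" + body + stop + utr3[:off] + run + utr3[off:]
        cds_interval = (utr5_len, utr5_len + cds_len)

    planted = PlantedLocus(
        contig_id=contig_id, motif=motif, repeat_count=n_rep, start=start, region=region
    )
    certified = _certify_flanks(seq, planted, cds_interval, rng)
    if certified is None:
        return _attempt_contig(config, rng, contig_id, force_ssr)
    return Contig(contig_id, certified), planted, cds_interval


def _make_contig(
    config: GeneratorConfig,
    rng: np.random.Generator,
    contig_id: str,
    force_ssr: bool = False,
) -> tuple[Contig, PlantedLocus | None]:
    """Generate one contig; SSR-bearing contigs are certified so that the
    planted ORF is the longest one and the planted region label is the
    one a longest-ORF classifier recovers."""
    for _ in range(60):
        contig, planted, cds_interval = _attempt_contig(config, rng, contig_id, force_ssr)
        if planted is None:
            return contig, None
        orf = find_longest_orf(contig.sequence, _CERTIFY_ORF_MIN, contig_id)
        if (
            orf is not None
            and orf.strand == "+"
            and (orf.cds_start, orf.cds_end) == cds_interval
            and classify_ssr_region(planted, orf) == planted.region
        ):
            return contig, planted
    raise RuntimeError(f"could not certify contig {contig_id} in 60 attempts")


def generate_contig_set(
    config: GeneratorConfig,
) -> tuple[list[Contig], list[PlantedLocus]]:
    """Generate a contig set with planted, certified SSR ground truth.

    Every SSR-bearing contig carries exactly one planted run that
    default-parameter mining recovers at its exact coordinates, with no
    other threshold-passing run within 10 bp; accidental runs farther
    away may exist, as in real sequence.  Deterministic under the seed.
    """
    rng = np.random.default_rng(config.seed)
    contigs: list[Contig] = []
    truth: list[PlantedLocus] = []
    for i in range(config.n_contigs):
        contig, planted = _make_contig(config, rng, f"CTG{i + 1:05d}")
        contigs.append(contig)
        if planted is not None:
            truth.append(planted)
    return contigs, truth


def generate_variety_pair(
    config: GeneratorConfig,
    n_shared: int,
    n_polymorphic: int,
    diff_range: tuple[int, int] = (2, 15),
) -> tuple[list[Contig], list[Contig], list[VarietyPairTruth]]:
    """Two varieties' contig sets with planted SSR length differences.

    ``n_shared`` contigs are common to both varieties (identical outside
    the SSR) and each carries one planted SSR; exactly ``n_polymorphic``
    of them differ in repeat count, with absolute length differences
    drawn from ``diff_range`` as whole motif units (a locus whose motif
    cannot realise a whole-unit difference inside ``diff_range`` is never
    selected, so fractional-unit differences cannot occur).  Each variety
    additionally receives ``config.n_contigs`` private contigs.  Returns
    ``(contigs_a, contigs_b, truth)``.
    """
    if not 0 <= n_polymorphic <= n_shared:
        raise ValueError("require 0 <= n_polymorphic <= n_shared")
    lo, hi = diff_range
    if not 1 <= lo <= hi:
        raise ValueError("diff_range must be a positive bp interval")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    shared: list[tuple[Contig, PlantedLocus]] = []
    for i in range(n_shared):
        shared.append(_make_contig(config, rng, f"SH{i + 1:05d}", force_ssr=True))

    def unit_steps(k: int) -> list[int]:
        return [u for u in range(1, hi // k + 1) if lo <= k * u <= hi]

    eligible = [i for i, (_, p) in enumerate(shared) if unit_steps(len(p.motif))]
    if len(eligible) < n_polymorphic:
        raise ValueError(
            f"only {len(eligible)} shared loci can realise a whole-unit "
            f"difference in {diff_range}"
        )
    poly_idx = set(
        rng.choice(np.array(eligible), size=n_polymorphic, replace=False).tolist()
    ) if n_polymorphic else set()

    contigs_a: list[Contig] = []
    contigs_b: list[Contig] = []
    truth: list[VarietyPairTruth] = []
    for i, (contig, planted) in enumerate(shared):
        id_a, id_b = f"A_{contig.id}", f"B_{contig.id}"
        locus_a = replace(planted, contig_id=id_a)
        contigs_a.append(Contig(id_a, contig.sequence))
        if i in poly_idx:
            k = len(planted.motif)
            u = int(rng.choice(unit_steps(k)))
            signs = [+1] + ([-1] if planted.repeat_count - u >= 5 else [])
            sign = int(rng.choice(np.array(signs)))
            n_b = planted.repeat_count + sign * u
            seq_b = (
                contig.sequence[: planted.start]
                + planted.motif * n_b
                + contig.sequence[planted.end :]
            )
            locus_b = replace(planted, contig_id=id_b, repeat_count=n_b)
        else:
            seq_b = contig.sequence
            locus_b = replace(planted, contig_id=id_b)
        contigs_b.append(Contig(id_b, seq_b))
        truth.append(
            VarietyPairTruth(
                contig_id_a=id_a,
                contig_id_b=id_b,
                shared=True,
                locus_a=locus_a,
                locus_b=locus_b,
            )
        )

    rng_a = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    rng_b = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    for i in range(config.n_contigs):
        contig, _ = _make_contig(config, rng_a, f"A_U{i + 1:05d}")
        contigs_a.append(contig)
        contig, _ = _make_contig(config, rng_b, f"B_U{i + 1:05d}")
        contigs_b.append(contig)
    return contigs_a, contigs_b, truth


def generate_allele_matrix(
    n_loci: int,
    n_genotypes: int,
    allele_freq_spec: Sequence[Sequence[float]] | Sequence[float],
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a genotype x locus allele matrix under an inbred (homozygous,
    one allele per genotype per locus) model.

    ``allele_freq_spec`` is either one frequency vector applied to every
    locus, or one vector per locus.  Allele size codes are ``100 + 2i``
    bp for the i-th allele of a locus.  Missing entries are ``pd.NA`` —
    a dedicated sentinel, distinct from any allele code and from band
    absence.
    """
    if n_loci < 0 or n_genotypes < 0:
        raise ValueError("n_loci and n_genotypes must be non-negative")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    spec = list(allele_freq_spec)
    if spec and np.isscalar(spec[0]):
        spec = [list(allele_freq_spec)] * n_loci
    if len(spec) != n_loci:
        raise ValueError(f"expected {n_loci} frequency vectors, got {len(spec)}")
    vectors = []
    for vec in spec:
        v = np.asarray(vec, dtype=float)
        if (v < 0).any():
            raise ValueError("allele frequency vectors must be non-negative")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("each allele frequency vector must sum to 1")
        vectors.append(v)

    rng = np.random.default_rng(seed)
    data = {}
    for j, v in enumerate(vectors):
        codes = 100 + 2 * np.arange(v.size)
        draws = rng.choice(codes, size=n_genotypes, p=v)
        col = pd.array(draws, dtype="Int64")
        if missing_rate > 0:
            col[rng.random(n_genotypes) < missing_rate] = pd.NA
        data[f"L{j + 1:02d}"] = col
    index = [f"G{i + 1:02d}" for i in range(n_genotypes)]
    return pd.DataFrame(data, index=index, dtype="Int64")


def generate_f2_genotypes(
    n: int, seed: int = 0, exact: bool = False
) -> tuple[int, int, int]:
    """Counts (AA, Aa, aa) for an F2 panel segregating 1:2:1.

    ``exact`` returns the rounded expectation instead of a multinomial
    draw (useful for worked examples); counts always sum to *n*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if exact:
        quarter = n // 4
        return quarter, n - 2 * quarter, quarter
    rng = np.random.default_rng(seed)
    aa, het, bb = rng.multinomial(n, [0.25, 0.5, 0.25])
    return int(aa), int(het), int(bb)


def write_truth_table(planted: Sequence[PlantedLocus], path) -> None:
    """Write planted-locus ground truth as TSV (1-based start coordinates)."""
    df = pd.DataFrame(
        {
            "contig_id": [p.contig_id for p in planted],
            "start": [p.start + 1 for p in planted],
            "motif": [p.motif for p in planted],
            "repeats": [p.repeat_count for p in planted],
            "region": [p.region for p in planted],
        }
    )
    df.to_csv(path, sep="\t", index=False)
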