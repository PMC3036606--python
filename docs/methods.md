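# Methods

This note documents the models and procedures implemented in
`genicssr`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and known limitations.

## SSR mining

A perfect SSR is a maximal run of a **primitive** repeat unit (one that
is not itself a tandem repeat of a shorter unit: `AT`, never `ATAT`).
Detection is per unit length *k* = 2..6: positions where
`seq[i] == seq[i+k]` define maximal periodic stretches; each stretch is
reported once, at its leftmost start, with the repeat count truncated to
**complete reiterations** — so a locus of motif length *k* and count *n*
spans exactly *k·n* bp, matching how survey tables print SSR lengths
(10, 12, 15, 18 … bp).  A trailing partial unit extends neither the
count nor the coordinates; `N` never participates in a repeat.

Defaults follow the standard genic-SSR screening thresholds: minimum 5
reiterations, minimum 10 bp, mononucleotide runs excluded.  The
**compound rule** removes every member of any cluster of
threshold-passing runs closer together than `compound_gap` (default
10 bp); published surveys exclude "complex" SSRs without defining the
gap, so it is configurable and recorded in the run manifest via the
config hash.  Coordinates are 0-based half-open internally and 1-based
inclusive in written tables.

The motif **canonical class** is the lexicographically smaller of the
motif and its reverse complement (`TC → GA`).  Cyclic rotations are
deliberately *not* collapsed — frequency tables in the EST-SSR
literature count `TC/GA` and `AG/CT` as distinct classes.  One
consequence, exercised in the tests: mining the reverse complement of a
contig returns the same runs at mirrored coordinates, but when a run
carries a partial trailing unit the reported motif on the other strand
may be a cyclic rotation with a *different* class key, and the start may
shift by less than one unit length.  Class keys are strand-invariant
only up to rotation.

Correctness is established against a brute-force oracle that enumerates
every (start, unit, count) triple and keeps maximal, primitive,
threshold-passing runs; the vectorised miner must agree exactly on
thousands of adversarial random sequences.

## Primer design

Primer screening is a constraint filter with an additive preference
penalty, not a thermodynamic model.  Hard constraints: length 20–25 nt,
Tm 50–60 °C, GC 40–60 %, a G/C clamp of one 3'-terminal base on both
primers, product 100–200 bp containing the whole SSR.  The reverse
primer is reported 5'→3' on the antisense strand, so its 3' end sits at
the sense-strand window start.

Melting temperature: Wallace rule `2(A+T) + 4(G+C)` below 14 nt, else
`64.9 + 41(GC − 16.4)/len`.  Both the Tm formula and the penalty

```
|len−22| + |Tm−55| + 0.5·|GC−50|   (per primer)   + 0.02·|product−150|
```

are this package's own documented choices — marker surveys typically
delegate primer scoring to batch primer-design software whose internal
thermodynamics are not reproduced here — so per-marker Tm values are
comparable within a run but not to published primer tables.  Ties are broken by the leftmost forward primer, then the
smallest product, making selection deterministic; minimality is verified
against exhaustive enumeration in the tests.  No hairpin,
self-complementarity or duplex ΔG screening is performed.  Marker IDs
(`ASSR1…`) are dense serials in locus discovery order.

## Gene-region annotation

Ab initio gene prediction is replaced by a **longest-ORF heuristic**:
the longest ATG→stop frame (stop codon included, ≥ `min_orf_len`,
default 150 bp) over all six frames, ties to the plus strand then the
smallest start.  An SSR overlapping the CDS interval at all is labelled
CDS (one label per locus, boundary inclusive); otherwise its side on the
oriented contig decides 5'- vs 3'-UTR; contigs with no qualifying ORF
yield "unknown".  On real data this heuristic will disagree with a
trained gene finder on some transcripts, so region percentages computed
on real assemblies are approximations; on synthetic data the ORF is
planted and certified, so labels are exact.

## In silico polymorphism calling

The published procedure — co-assembling two varieties and inspecting
alignments manually — is replaced by deterministic **unique-anchor
matching**: the `anchor_len` (default 25) bases immediately flanking an
A-variety SSR must each occur exactly once in the whole B set (both
strands searched; reverse-orientation matches are mirrored back to
forward coordinates), on the same contig and strand, in order, and the
bracketed gap must be a perfect run of the same motif.  Any ambiguity
(multi-hit or absent anchors, anchors off the contig end, a gap that is
not the expected run) produces a logged skip, never a call.  The signed
difference is B minus A.  Downstream filters keep type I loci (both
alleles ≥ 20 bp) with |diff| ≥ 4 bp, the conventional threshold for
resolution on agarose gels.  Swapping the two varieties negates every
difference and preserves the retained set (tested).

Wet-lab validation rates (PCR failure, null alleles) are outside the
model: a retained call is a sequence-level prediction only.

## Diversity statistics

Genotypes are **homozygous inbreds**: one allele per genotype per locus,
which is how varietal SSR panels are scored from gel band sizes.
Missing observations are a dedicated NA sentinel, never conflated with
band absence: they are excluded from allele-frequency denominators
(hence from PIC), and contribute all-zero rows to a locus's band columns
with a separate missing mask.

* `PIC = 1 − Σ p_i²` (Botstein's definition as used for inbred panels).
* Jaccard similarity on the genotype × (locus, allele) 0/1 band matrix;
  an empty union returns 1.0 by convention (documented, degenerate).
* UPGMA clusters on distance `1 − J` — SAHN-style packages that cluster
  on similarity yield the same topology with mirrored heights.
  Merges happen at height d/2; new distances are member-count-weighted
  means; ties break on the lexicographically smallest cluster labels (a
  cluster is labelled by its smallest leaf), so output is deterministic.
  Newick branch lengths are parent minus child height.  Agreement with
  SciPy's average-linkage cophenetic distances and exact recovery of
  ultrametric inputs are asserted in the tests.
* F2 segregation: Pearson chi-square against 1:2:1 on 2 df; its type I
  error calibration (5 % ± 1 % at α = 0.05, n = 100, 10,000 panels) is
  an acceptance test.

Reports round PIC to 2 d.p., matching survey-table convention; internal
arithmetic is full precision.

## Synthetic data generator

Each contig is assembled as `5'UTR + (ATG + non-stop codons + stop) +
3'UTR`.  Defaults state the world the generator emulates:

| parameter | default | rationale |
|---|---|---|
| `ssr_probability` | 0.076 | share of unigene contigs carrying an SSR in a deep legume transcriptome survey |
| `motif_class_weights` | di .6041, tri .3452, tetra .0167, penta .0076, hexa .0264 | observed motif-class mix of the same survey |
| `repeat_count_range`, `ratio` | 5–22, geometric ratio 0.55 | reiteration counts observed to decay sharply ("inverse relationship"); 5 is the mining threshold, 22 the observed maximum |
| `region_weights` | 5'UTR 87/550, CDS 339/550, 3'UTR 124/550 | region placement of validated markers |
| `contig_length_range` | 300–1500 bp | plausible unigene contig sizes (~31.6 Mbp / 43k contigs ≈ 730 bp mean) |
| `gc_content` | 0.45 | typical plant transcript GC |
| `cds_fraction` | 0.5 | CDS roughly half a transcript contig, leaving UTRs large enough to host SSRs and primer anchors |

**Certified ground truth.**  The generator does not merely plant a run;
it *certifies* it: (1) flank bases are re-drawn until default-parameter
mining recovers the planted locus at its exact coordinates and no other
threshold-passing run lies within 10 bp (which would shift the detected
phase or trigger compound exclusion); (2) a contig is re-generated if a
chance ORF would out-compete the planted one, so the planted region
label is exactly what the longest-ORF classifier returns.  Accidental
SSRs *far* from planted sites are left in place — real sequence has
them, and recovery statistics are asserted at planted sites only.
UTRs are at least 35 bp and planted runs at least 30 bp from contig
ends, so 25 bp polymorphism anchors always exist.

**Frame safety.**  CDS-planted SSRs use motifs whose length is a
multiple of 3 (tri- *and* hexanucleotide — both insert whole codons at a
codon boundary) with no in-frame stop.  Frame-breaking unit lengths (2,
4, 5) are redirected to the UTRs, redistributing the CDS region weight
over them, unless `allow_cds_non_trinucleotide` is set (in which case
frames are knowingly broken).  Real transcriptomes do contain
frame-breaking SSRs in annotated CDS; unambiguous truth was prioritised
over that realism.  A consequence: the *realized* overall CDS share of
planted loci is ≈ 0.37 × 0.62 ≈ 23 %, not the 62 % seen for validated
markers in real surveys — per-class placement, not the marginal share,
is the controlled quantity.

Variety pairs share `n_shared` contigs that are byte-identical outside
the SSR; exactly `n_polymorphic` differ in repeat count, by whole motif
units drawn from `diff_range` (default 2–15 bp), with the B-side count
kept ≥ 5 so the allele remains a mineable SSR.  A locus whose motif
cannot realise any whole-unit difference inside `diff_range` is never
selected, so fractional-unit differences cannot occur.

**What a green test establishes — and does not.**  Synthetic contigs
are i.i.d. nucleotides around planted structure: no codon-usage bias,
splice variants, chimeric contigs, assembly errors, sequencing error,
paralogy or shared repeat families between "varieties".  Anchor
uniqueness is therefore nearly guaranteed here, whereas real assemblies
have duplicated genes and shared low-complexity regions; perfect
precision/recall on planted truth validates the *logic*, not
performance on real data.  F2 panels are drawn directly from the 1:2:1
multinomial (no segregation distortion or genotyping error).

## Numerical and degenerate-input conventions

* Zero mined loci → abundance reported as NaN, not an error.
* Empty frequency tables, empty contig sets and `n_contigs=0` are valid.
* UPGMA requires a labelled, symmetric (tolerance 1e-9), zero-diagonal,
  non-negative matrix with ≥ 2 labels.
* Allele frequency vectors must sum to 1 within 1e-9 (generator inputs)
  or 1e-6 (PIC inputs, allowing accumulated float error).
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit config fields; fixed seed ⇒ byte-identical outputs.

## Known limitations

* Primer Tm and penalty are simplified; no thermodynamic screening.
* The longest-ORF heuristic ignores splice structure and homology.
* One planted SSR per synthetic contig (real surveys find 2–4 loci in
  ~9 % of SSR-bearing contigs); multiplicity is exercised only via
  accidental runs.
* Heterozygotes are out of scope throughout the diversity module.
* The bundled marker survey tables reproduce printed, 2-decimal values;
  their column means are asserted at printed precision.
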