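# genicssr

A Python toolkit for **genic (EST/transcriptome-derived) SSR marker
development and analysis**, built for the workflow used to turn deep
transcriptome assemblies of crop plants — the motivating system is
pigeonpea (*Cajanus cajan*) — into validated, mappable microsatellite
markers:

1. **SSR mining** — detect perfect microsatellites in unigene contigs:
   primitive repeat units of 2–6 nt with ≥ 5 reiterations (≥ 10 bp),
   excluding homopolymer runs and compound (closely clustered) repeats;
   summarize motif-class, repeat-number and length frequency tables and
   overall abundance (kbp of sequence per SSR).
2. **Primer design** — exhaustively screen flanking windows under the
   classic constraint set (20–25 nt, optimum 22; Tm 50–60 °C, optimum
   55; GC 40–60 %, one 3'-terminal G/C clamp; product 100–200 bp
   spanning the SSR) and assign serial `ASSR` marker IDs.
3. **Gene-region annotation** — longest-ORF gene models (six frames,
   ATG→stop, ≥ 150 bp) and classification of each SSR as 5'-UTR, CDS
   or 3'-UTR.
4. **In silico polymorphism calling** — match SSR loci between two
   varieties' assemblies by unique 25 bp flanking anchors and call
   allele length differences, keeping type I loci (≥ 20 bp) with
   differences ≥ 4 bp (resolvable on agarose gels).
5. **Diversity statistics** — allele frequencies and polymorphism
   information content (PIC), Jaccard similarity on binary band
   profiles, UPGMA (SAHN) dendrograms with Newick export, and 1:2:1
   chi-square segregation tests for F2 families.
6. **Synthetic data** — a generator that plants SSRs, ORFs, variety
   pairs with known length differences, allele matrices and F2 panels
   with *certified* ground truth, so every stage is testable end to end
   without downloading real assemblies.

## The statistics at the core

For a locus with allele frequencies $p_1,\dots,p_k$ in a genotype set,

$$\mathrm{PIC} = 1 - \sum_i p_i^2,$$

bounded by $1 - 1/k$ (uniform frequencies).  Genetic similarity between
genotypes $a, b$ with binary band profiles is Jaccard's coefficient
$J = |a \wedge b| / |a \vee b|$; genotypes are clustered by UPGMA on
$d = 1 - J$, merging the closest clusters at height $d/2$ with
member-count-weighted distance updates.  Codominant F2 segregation is
tested against 1:2:1 with a Pearson chi-square on 2 df.

## Worked example

```python
from genicssr import (GeneratorConfig, generate_variety_pair,
                      mine_contigs, pic, allele_frequencies)
from genicssr.polymorphism import match_shared_loci, filter_calls

cfg = GeneratorConfig(n_contigs=80, seed=4)
A, B, truth = generate_variety_pair(cfg, n_shared=120, n_polymorphic=50)
loci = mine_contigs(A)
calls, skipped = match_shared_loci(A, loci, B)
retained = filter_calls(calls, min_len=20, min_diff=4)
print(len(loci), len(calls), len(retained))
```

prints `128 121 7`: 128 SSR loci mined from variety A, 121 matched into
variety B by unique anchors (the rest sit on private contigs or too
close to a contig end), and 7 retained as type I loci with a ≥ 4 bp
length difference — exactly the 7 planted type I differences ≥ 4 bp, as
`examples/04_call_polymorphisms.py` verifies.  A biallelic marker scored
5/3 across eight varieties gives `pic((0.625, 0.375)) = 0.46875 → 0.47`.

The `examples/` directory holds one short narrative script per
capability (mining, primer design, region classification, polymorphism
calling, diversity analysis, the full pipeline); each prints the numbers
it computes and a line on what they mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

builds small eight-variety allele panels, recomputes the headline PIC
statistics for biallelic marker configurations from allele frequencies
estimated off those panels, and writes them as JSON keyed by target ID.

## Layout

```
src/genicssr/     library (mining, primers, annotation, polymorphism,
                  diversity, synthetic, tables, io, pipeline)
examples/         narrative example scripts
tests/            pytest suite incl. brute-force oracles and
                  planted-truth acceptance checks
docs/methods.md   models, parameter choices, and limitations
```
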