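"""Marker-based diversity analysis of a genotype panel.

Simulates a 30-genotype panel (cultivated and wild groups) scored at 20
multi-allelic loci, then computes per-marker allele counts and PIC,
pairwise Jaccard similarities of the binary band profiles, a UPGMA
dendrogram, and a 1:2:1 chi-square segregation test for an F2 family.
"""

import numpy as np

from genicssr import (
    binary_band_matrix,
    chi_square_segregation,
    diversity_report,
    generate_allele_matrix,
    generate_f2_genotypes,
    jaccard_similarity_matrix,
    upgma,
)

rng = np.random.default_rng(5)
freqs = [list(v / v.sum()) for v in (rng.dirichlet(np.ones(k) * 2) for k in rng.integers(4, 9, 20))
         for v in [np.asarray(v)]]
matrix = generate_allele_matrix(20, 30, freqs, missing_rate=0.02, seed=5)
groups = {g: ("cultivar" if i < 22 else "wild") for i, g in enumerate(matrix.index)}

report = diversity_report(matrix, groups)
avg = report.loc["Average"]
print(f"mean alleles/locus: {avg['n_alleles_total']:.2f}; mean PIC: {avg['pic_total']:.2f}")
print(report[["n_alleles_total", "pic_total"]].head(5).round(2).to_string())

bands, _ = binary_band_matrix(matrix)
sim = jaccard_similarity_matrix(bands)
tree = upgma(1.0 - sim)
print(f"\nUPGMA root height (1 - Jaccard distance / 2): {tree.height:.3f}")
print("newick:", tree.to_newick()[:90], "...")

counts = generate_f2_genotypes(100, seed=5)
stat, df, p = chi_square_segregation(counts)
print(f"\nF2 counts AA/Aa/aa = {counts}; chi-square({df}) = {stat:.2f}, p = {p:.3f}")
print("p > 0.05: consistent with codominant 1:2:1 Mendelian segregation")
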