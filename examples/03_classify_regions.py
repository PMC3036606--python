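"""Locate SSRs relative to the predicted ORF of each transcript.

Each contig's longest ATG-to-stop open reading frame (>= 150 bp, six
frames) stands in for the gene model; an SSR overlapping it is CDS,
otherwise it is 5'- or 3'-UTR.  The summary table reports each region's
share of loci, mirroring how marker surveys report UTR vs coding
placement.
"""

from genicssr import (
    GeneratorConfig,
    classify_ssr_region,
    find_longest_orf,
    generate_contig_set,
    region_polymorphism_summary,
)

contigs, truth = generate_contig_set(GeneratorConfig(n_contigs=300, ssr_probability=1.0, seed=3))
cmap = {c.id: c for c in contigs}

labels = []
for planted in truth:
    orf = find_longest_orf(cmap[planted.contig_id].sequence, 150, planted.contig_id)
    labels.append(classify_ssr_region(planted, orf))

# no polymorphism data here, so flags are all False; the table still
# gives the per-region share of loci
summary = region_polymorphism_summary(labels, [False] * len(labels))
print(summary[["n", "percent_of_total"]].to_string())
agree = sum(l == p.region for l, p in zip(labels, truth))
print(f"\nclassifier agrees with the planted region for {agree}/{len(truth)} loci")
# Region shares track the generator's defaults (~62% CDS, ~16% 5'-UTR,
# ~22% 3'-UTR placement of validated markers).
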