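"""Call in silico SSR length polymorphisms between two varieties.

Two transcript sets share 120 contigs, 50 of which carry a planted
repeat-count difference (2-15 bp in whole motif units).  Each A-variety
locus is matched into B by unique 25 bp flanking anchors; matches are
then filtered to type I loci (both alleles >= 20 bp) with >= 4 bp size
difference — the calls worth genotyping on agarose gels.
"""

from genicssr import GeneratorConfig, generate_variety_pair, mine_contigs
from genicssr.polymorphism import filter_calls, match_shared_loci

config = GeneratorConfig(n_contigs=80, seed=4)
contigs_a, contigs_b, truth = generate_variety_pair(config, n_shared=120, n_polymorphic=50)

loci_a = mine_contigs(contigs_a)
calls, skipped = match_shared_loci(contigs_a, loci_a, contigs_b)
retained = filter_calls(calls, min_len=20, min_diff=4)

n_poly = sum(1 for c in calls if c.diff != 0)
print(f"A loci mined: {len(loci_a)}; matched into B: {len(calls)} "
      f"({len(skipped)} unmatched, mostly private contigs)")
print(f"length-polymorphic matches: {n_poly}")
print(f"retained after type I (>=20 bp) and >=4 bp filters: {len(retained)}")
for call in retained[:5]:
    print(f"  {call.locus_a.contig_id}: ({call.locus_a.motif}) "
          f"{call.locus_a.length} bp vs {call.locus_b.length} bp, diff {call.diff:+d} bp")

planted = sum(1 for t in truth if abs(t.allele_length_difference) >= 4
              and t.locus_a.length >= 20 and t.locus_b.length >= 20)
print(f"\nplanted type I differences >= 4 bp: {planted} (all recovered: "
      f"{planted == len(retained)})")
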