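"""Design flanking primer pairs for mined SSR loci.

Primers must be 20-25 nt (optimum 22), Tm 50-60 degC (optimum 55), GC
40-60% with a single G/C clamp at the 3' end, and amplify a 100-200 bp
product spanning the whole SSR.  Loci whose flanks admit no such pair
are reported as undesignable, and designable loci receive serial ASSR
marker IDs.
"""

from genicssr import (
    GeneratorConfig,
    assign_marker_ids,
    design_primers,
    generate_contig_set,
    mine_contigs,
)

contigs, _ = generate_contig_set(GeneratorConfig(n_contigs=60, ssr_probability=1.0, seed=2))
loci = mine_contigs(contigs)
by_id = {c.id: c for c in contigs}

designed = []
for locus in loci:
    pair = design_primers(by_id[locus.contig_id], locus)
    if pair is not None:
        designed.append((locus, pair))
markers = assign_marker_ids(designed)

print(f"{len(loci)} loci mined; primers designed for {len(markers)}, "
      f"{len(loci) - len(markers)} undesignable (flanks too short or unsuitable)")
m = markers[0]
print(f"\n{m.marker_id}: ({m.locus.motif}){m.locus.repeat_count} on {m.locus.contig_id}")
print(f"  forward  5'-{m.primers.forward}-3'  Tm {m.primers.tm_f:.1f} degC, GC {m.primers.gc_f:.0f}%")
print(f"  reverse  5'-{m.primers.reverse}-3'  Tm {m.primers.tm_r:.1f} degC, GC {m.primers.gc_r:.0f}%")
print(f"  expected product: {m.expected_size} bp (contains the SSR)")
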