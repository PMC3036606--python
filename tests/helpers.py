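"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (nested loops
over candidate solutions) so they stay independent of the vectorised /
pruned implementations they check.
"""

from __future__ import annotations

from genicssr.contig import revcomp
from genicssr.mining import MiningParams


def brute_force_ssrs(seq: str, params: MiningParams = MiningParams()):
    """Enumerate every (start, unit, count) triple, keep maximal primitive
    threshold-passing runs, then apply the compound rule."""
    seq = seq.upper()
    found: list[tuple[int, int, str, int]] = []
    min_unit = max(params.min_unit, 2) if params.exclude_mononucleotide else params.min_unit
    for k in range(min_unit, params.max_unit + 1):
        for i in range(len(seq) - k + 1):
            # i must start the periodic stretch (left-maximality)
            if i > 0 and i - 1 + k < len(seq):
                a, b = seq[i - 1], seq[i - 1 + k]
                if a == b and a in "ACGT":
                    continue
            motif = seq[i : i + k]
            if any(ch not in "ACGT" for ch in motif):
                continue
            if any(
                k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
            ):
                continue  # not primitive
            n = 1
            while seq[i + n * k : i + (n + 1) * k] == motif:
                n += 1
            if n < params.min_repeats or k * n < params.min_length:
                continue
            found.append((i, i + k * n, motif, n))
    found.sort(key=lambda t: (t[0], t[1], t[2]))
    if params.exclude_compound:
        kept: list[tuple[int, int, str, int]] = []
        cluster: list[tuple[int, int, str, int]] = []
        cend = None
        for f in found:
            if cluster and f[0] - cend < params.compound_gap:
                cluster.append(f)
                cend = max(cend, f[1])
            else:
                if len(cluster) == 1:
                    kept.append(cluster[0])
                cluster = [f]
                cend = f[1]
        if len(cluster) == 1:
            kept.append(cluster[0])
        found = kept
    return found


def brute_force_best_primer_pair(seq: str, locus_start: int, locus_end: int, params):
    """Exhaustive search over all forward/reverse windows; returns the
    minimal (penalty, forward_start, product) key or None."""
    from genicssr.contig import gc_percent
    from genicssr.primers import melting_temperature

    lmin, lmax = params.primer_len_range
    best = None
    for flen in range(lmin, lmax + 1):
        for fs in range(0, locus_start - flen + 1):
            f = seq[fs : fs + flen]
            if "N" in f or f[-1] not in "GC":
                continue
            tf, gf = melting_temperature(f), gc_percent(f)
            if not (params.tm_range[0] <= tf <= params.tm_range[1]):
                continue
            if not (params.gc_range[0] <= gf <= params.gc_range[1]):
                continue
            for rlen in range(lmin, lmax + 1):
                for rs in range(locus_end, len(seq) - rlen + 1):
                    r = revcomp(seq[rs : rs + rlen])
                    if "N" in r or r[-1] not in "GC":
                        continue
                    product = rs + rlen - fs
                    if not (params.product_range[0] <= product <= params.product_range[1]):
                        continue
                    tr, gr = melting_temperature(r), gc_percent(r)
                    if not (params.tm_range[0] <= tr <= params.tm_range[1]):
                        continue
                    if not (params.gc_range[0] <= gr <= params.gc_range[1]):
                        continue
                    pen = (
                        abs(flen - params.primer_len_opt)
                        + abs(tf - params.tm_opt)
                        + 0.5 * abs(gf - params.gc_opt)
                        + abs(rlen - params.primer_len_opt)
                        + abs(tr - params.tm_opt)
                        + 0.5 * abs(gr - params.gc_opt)
                        + 0.02 * abs(product - params.product_opt)
                    )
                    key = (pen, fs, product)
                    if best is None or key < best:
                        best = key
    return best
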