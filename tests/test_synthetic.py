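"""Synthetic-data generator: determinism, planted-truth certification,
class mixes, variety pairs, allele matrices, F2 panels."""

import numpy as np
import pandas as pd
import pytest

from genicssr.mining import find_perfect_repeats, mine_contigs
from genicssr.synthetic import (
    GeneratorConfig,
    generate_allele_matrix,
    generate_contig_set,
    generate_f2_genotypes,
    generate_variety_pair,
    write_truth_table,
)
from genicssr.io import write_fasta


def _recovered_exactly(contigs, truth):
    mined = mine_contigs(contigs)
    by_contig = {}
    for l in mined:
        by_contig.setdefault(l.contig_id, []).append(l)
    for p in truth:
        at_site = [
            l
            for l in by_contig.get(p.contig_id, [])
            if l.start < p.end + 10 and l.end > p.start - 10
        ]
        if len(at_site) != 1:
            return False
        l = at_site[0]
        if (l.start, l.motif, l.repeat_count) != (p.start, p.motif, p.repeat_count):
            return False
    return True


def test_empty_config():
    contigs, truth = generate_contig_set(GeneratorConfig(n_contigs=0))
    assert contigs == [] and truth == []


def test_determinism_byte_identical(tmp_path):
    config = GeneratorConfig(n_contigs=25, ssr_probability=0.5, seed=7)
    a_contigs, a_truth = generate_contig_set(config)
    b_contigs, b_truth = generate_contig_set(config)
    assert a_truth == b_truth
    write_fasta(a_contigs, tmp_path / "a.fasta")
    write_fasta(b_contigs, tmp_path / "b.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


def test_invalid_weights_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(motif_class_weights={1: 0.5, 2: 0.5})
    with pytest.raises(ValueError):
        GeneratorConfig(motif_class_weights={7: 1.0})
    with pytest.raises(ValueError):
        GeneratorConfig(motif_class_weights={2: 0.7, 3: 0.7})


def test_mining_recovers_planted_truth_many_seeds():
    """Planted loci are recovered exactly, with no spurious run at the
    planted sites, across many generator seeds."""
    for seed in range(25):
        config = GeneratorConfig(n_contigs=25, ssr_probability=1.0, seed=seed)
        contigs, truth = generate_contig_set(config)
        assert len(truth) == 25
        assert _recovered_exactly(contigs, truth)


def test_planted_class_fractions_within_3_sigma():
    weights = {2: 0.60, 3: 0.35, 4: 0.015, 5: 0.005, 6: 0.03}
    config = GeneratorConfig(
        n_contigs=2000, ssr_probability=1.0, motif_class_weights=weights, seed=13
    )
    _, truth = generate_contig_set(config)
    n = len(truth)
    assert n == 2000
    observed = pd.Series([len(p.motif) for p in truth]).value_counts(normalize=True)
    for unit, w in weights.items():
        se = (w * (1 - w) / n) ** 0.5
        assert abs(observed.get(unit, 0.0) - w) <= 3 * se


def test_repeat_counts_decrease_in_frequency():
    config = GeneratorConfig(n_contigs=1500, ssr_probability=1.0, seed=21)
    _, truth = generate_contig_set(config)
    counts = pd.Series([p.repeat_count for p in truth]).value_counts()
    # the minimum reiteration number is the most abundant and frequency
    # decays with repeat number (inverse relationship)
    assert counts.idxmax() == 5
    assert counts[5] > counts.get(8, 0) > counts.get(12, 0)


def test_cds_planting_preserves_reading_frame(small_contig_set):
    """CDS-planted runs keep the planted ORF intact: frame-safe motif
    lengths only, and no in-frame stop introduced."""
    contigs, truth = small_contig_set
    cmap = {c.id: c.sequence for c in contigs}
    cds_planted = [p for p in truth if p.region == "CDS"]
    assert cds_planted, "expected some CDS-planted loci"
    for p in cds_planted:
        assert len(p.motif) % 3 == 0
        codons = [p.motif[i : i + 3] for i in range(0, len(p.motif), 3)]
        assert not set(codons) & {"TAA", "TAG", "TGA"}
        seq = cmap[p.contig_id]
        assert seq[p.start : p.end] == p.motif * p.repeat_count


def test_truth_table_roundtrip(tmp_path):
    config = GeneratorConfig(n_contigs=10, ssr_probability=1.0, seed=2)
    _, truth = generate_contig_set(config)
    path = tmp_path / "truth.tsv"
    write_truth_table(truth, path)
    df = pd.read_csv(path, sep="\t")
    assert len(df) == 10
    assert (df["start"] == [p.start + 1 for p in truth]).all()  # 1-based


class TestVarietyPair:
    def test_no_polymorphism(self):
        config = GeneratorConfig(n_contigs=5, seed=1)
        A, B, truth = generate_variety_pair(config, n_shared=10, n_polymorphic=0)
        assert all(t.allele_length_difference == 0 for t in truth)

    def test_differences_are_whole_units_in_range(self):
        config = GeneratorConfig(n_contigs=5, seed=4)
        A, B, truth = generate_variety_pair(config, 40, 25, diff_range=(2, 15))
        diffs = [t for t in truth if t.allele_length_difference != 0]
        assert len(diffs) == 25
        for t in diffs:
            d = abs(t.allele_length_difference)
            assert 2 <= d <= 15
            assert d % len(t.locus_a.motif) == 0

    def test_fifteen_bp_on_trinucleotide_is_five_units(self):
        config = GeneratorConfig(
            n_contigs=0, seed=9, motif_class_weights={3: 1.0}
        )
        A, B, truth = generate_variety_pair(config, 10, 10, diff_range=(15, 15))
        for t in truth:
            assert abs(t.allele_length_difference) == 15
            assert abs(t.locus_b.repeat_count - t.locus_a.repeat_count) == 5

    def test_shared_contigs_identical_outside_ssr(self):
        config = GeneratorConfig(n_contigs=0, seed=6)
        A, B, truth = generate_variety_pair(config, 12, 6)
        amap = {c.id: c.sequence for c in A}
        bmap = {c.id: c.sequence for c in B}
        for t in truth:
            sa, sb = amap[t.contig_id_a], bmap[t.contig_id_b]
            assert sa[: t.locus_a.start] == sb[: t.locus_b.start]
            assert sa[t.locus_a.end :] == sb[t.locus_b.end :]

    def test_infeasible_request_raises(self):
        config = GeneratorConfig(n_contigs=0, seed=6)
        with pytest.raises(ValueError):
            generate_variety_pair(config, 5, 6)


class TestAlleleMatrix:
    def test_monomorphic(self):
        m = generate_allele_matrix(1, 8, [1.0], seed=0)
        assert m["L01"].nunique() == 1

    def test_seed_determinism(self):
        a = generate_allele_matrix(4, 10, [0.5, 0.5], missing_rate=0.2, seed=5)
        b = generate_allele_matrix(4, 10, [0.5, 0.5], missing_rate=0.2, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_expected_counts_large_sample(self):
        m = generate_allele_matrix(1, 10000, [0.5, 0.5], seed=8)
        frac = (m["L01"] == 100).mean()
        assert abs(frac - 0.5) <= 3 * (0.25 / 10000) ** 0.5

    def test_missing_is_na_not_a_code(self):
        m = generate_allele_matrix(1, 50, [0.5, 0.5], missing_rate=0.3, seed=2)
        assert m["L01"].isna().sum() > 0
        assert set(m["L01"].dropna().unique()) <= {100, 102}

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            generate_allele_matrix(1, 5, [1.5, -0.5])

    def test_per_locus_spec(self):
        m = generate_allele_matrix(2, 6, [[1.0], [0.5, 0.5]], seed=1)
        assert m["L01"].nunique() == 1


class TestF2:
    def test_exact_mode(self):
        assert generate_f2_genotypes(4, exact=True) == (1, 2, 1)
        assert generate_f2_genotypes(100, exact=True) == (25, 50, 25)

    def test_counts_sum_to_n(self):
        for seed in range(20):
            counts = generate_f2_genotypes(37, seed=seed)
            assert sum(counts) == 37

    def test_het_fraction_large_sample(self):
        _, het, _ = generate_f2_genotypes(10000, seed=3)
        assert abs(het / 10000 - 0.5) <= 3 * (0.25 / 10000) ** 0.5

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_f2_genotypes(0)
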