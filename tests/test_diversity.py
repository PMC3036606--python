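"""Marker statistics: allele frequencies, PIC, Jaccard, UPGMA, chi-square."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from genicssr.diversity import (
    allele_frequencies,
    binary_band_matrix,
    chi_square_segregation,
    cophenetic_distances,
    diversity_report,
    jaccard,
    jaccard_similarity_matrix,
    pic,
    upgma,
)
from genicssr.synthetic import generate_allele_matrix


def _matrix(values):
    df = pd.DataFrame({"L1": values}, index=[f"G{i}" for i in range(len(values))])
    return df.astype("Int64")


class TestAlleleFrequencies:
    def test_even_split(self):
        m = _matrix([100] * 4 + [102] * 4)
        assert allele_frequencies(m, "L1").tolist() == [0.5, 0.5]

    def test_five_three(self):
        m = _matrix([100] * 5 + [102] * 3)
        assert allele_frequencies(m, "L1").tolist() == [0.625, 0.375]

    def test_missing_excluded_from_denominator(self):
        m = _matrix([100] * 3 + [102] * 3 + [None, None])
        assert allele_frequencies(m, "L1").tolist() == [0.5, 0.5]

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            allele_frequencies(_matrix([None, None]), "L1")

    def test_unknown_locus(self):
        with pytest.raises(KeyError):
            allele_frequencies(_matrix([100]), "L9")


class TestPic:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.5, 0.5), 0.5),
            ((1.0,), 0.0),
            ((0.625, 0.375), 0.46875),
            ((0.25, 0.25, 0.25, 0.25), 0.75),
        ],
    )
    def test_worked_examples(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    def test_bounds(self, weights):
        p = np.array(weights) / np.sum(weights)
        value = pic(p)
        k = len(p)
        assert -1e-12 <= value <= 1 - 1 / k + 1e-12

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.floats(0.0, 1.0),
    )
    def test_balancing_two_frequencies_never_decreases_pic(self, weights, t):
        """Moving two allele frequencies toward their mean (a Robin Hood
        transfer) increases heterozygosity."""
        p = np.array(weights) / np.sum(weights)
        q = p.copy()
        mean = (p[0] + p[1]) / 2
        q[0] = p[0] + t * (mean - p[0])
        q[1] = p[0] + p[1] - q[0]
        assert pic(q) >= pic(p) - 1e-12

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            pic([0.5, 0.4])
        with pytest.raises(ValueError):
            pic([1.5, -0.5])


class TestBandMatrix:
    def test_monomorphic_locus_single_all_one_column(self):
        m = _matrix([100] * 5)
        bands, mask = binary_band_matrix(m)
        assert bands.shape == (5, 1)
        assert bands[("L1", 100)].tolist() == [1] * 5
        assert not mask.any().any()

    def test_biallelic_column_sums(self):
        m = _matrix([100] * 5 + [102] * 3)
        bands, _ = binary_band_matrix(m)
        assert bands[("L1", 100)].sum() == 5
        assert bands[("L1", 102)].sum() == 3

    def test_missing_scores_zero_but_is_masked(self):
        m = _matrix([100, 102, None])
        bands, mask = binary_band_matrix(m)
        assert bands.loc["G2"].tolist() == [0, 0]
        assert mask.loc["G2", "L1"]

    def test_empty(self):
        bands, _ = binary_band_matrix(pd.DataFrame())
        assert bands.empty


class TestJaccard:
    def test_examples(self):
        assert jaccard([1, 1, 0], [1, 1, 0]) == 1.0
        assert jaccard([1, 0, 0], [0, 1, 1]) == 0.0
        assert jaccard([1, 1, 0], [1, 0, 1]) == pytest.approx(1 / 3)
        assert jaccard([0, 0], [0, 0]) == 1.0  # empty-union convention

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jaccard([1], [1, 0])

    @given(
        st.integers(1, 30).flatmap(
            lambda n: st.tuples(
                st.lists(st.booleans(), min_size=n, max_size=n),
                st.lists(st.booleans(), min_size=n, max_size=n),
                st.lists(st.booleans(), min_size=n, max_size=n),
            )
        )
    )
    def test_metric_properties_vs_sets(self, abc):
        """Jaccard agrees with the set formula; 1 - J satisfies the
        triangle inequality."""
        a, b, c = (np.array(x, dtype=bool) for x in abc)

        def set_jaccard(x, y):
            xs = {i for i, v in enumerate(x) if v}
            ys = {i for i, v in enumerate(y) if v}
            if not xs | ys:
                return 1.0
            return len(xs & ys) / len(xs | ys)

        assert jaccard(a, b) == pytest.approx(set_jaccard(a, b))
        assert jaccard(a, b) == pytest.approx(jaccard(b, a))
        dab, dbc, dac = 1 - jaccard(a, b), 1 - jaccard(b, c), 1 - jaccard(a, c)
        assert dac <= dab + dbc + 1e-12


class TestUpgma:
    def test_two_leaves(self):
        dm = pd.DataFrame([[0.0, 4.0], [4.0, 0.0]], index=list("AB"), columns=list("AB"))
        root = upgma(dm)
        assert root.height == 2.0
        assert root.to_newick() == "(A:2,B:2);"

    def test_three_leaves_hand_executed(self):
        dm = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        assert upgma(dm).to_newick() == "((A:1,B:1):2,C:3);"

    def test_matches_scipy_average_linkage(self, rng):
        for _ in range(40):
            n = 6
            condensed = rng.random(n * (n - 1) // 2) + 0.05
            labels = [f"L{i}" for i in range(n)]
            dm = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
            ours = cophenetic_distances(upgma(dm)).loc[labels, labels].to_numpy()
            ref = squareform(cophenet(linkage(condensed, method="average")))
            assert np.allclose(ours, ref)

    def test_ultrametric_input_recovered_exactly(self, rng):
        condensed = rng.random(15) + 0.05
        labels = [f"L{i}" for i in range(6)]
        dm = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
        ultra = cophenetic_distances(upgma(dm))
        again = cophenetic_distances(upgma(ultra)).loc[ultra.index, ultra.columns]
        assert np.allclose(ultra.to_numpy(), again.to_numpy())

    def test_heights_non_decreasing(self, rng):
        condensed = rng.random(28) + 0.05
        labels = [f"L{i}" for i in range(8)]
        root = upgma(pd.DataFrame(squareform(condensed), index=labels, columns=labels))

        def check(node):
            if node.children is None:
                assert node.height == 0.0
                return
            for child in node.children:
                assert child.height <= node.height + 1e-12
                check(child)

        check(root)

    def test_input_validation(self):
        bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            upgma(bad)
        with pytest.raises(ValueError):
            upgma(pd.DataFrame([[0.0]], index=["A"], columns=["A"]))


class TestChiSquareSegregation:
    def test_perfect_ratio(self):
        stat, df, p = chi_square_segregation((25, 50, 25))
        assert stat == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_hand_computed(self):
        stat, df, _ = chi_square_segregation((30, 50, 20))
        assert stat == pytest.approx(2.0) and df == 2

    def test_extreme(self):
        stat, _, p = chi_square_segregation((0, 0, 4))
        assert stat == pytest.approx(12.0)
        assert p < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_square_segregation((-1, 2, 1))


class TestDiversityReport:
    def test_single_marker_single_group(self):
        m = _matrix([100] * 5 + [102] * 3)
        report = diversity_report(m, {g: "all" for g in m.index})
        assert report.loc["L1", "n_alleles_total"] == 2
        assert report.loc["L1", "pic_total"] == pytest.approx(pic([0.625, 0.375]))
        assert report.loc["Average", "pic_total"] == report.loc["L1", "pic_total"]

    def test_groupwise_counts(self):
        m = _matrix([100, 100, 102, 104])
        groups = {"G0": "cult", "G1": "cult", "G2": "wild", "G3": "wild"}
        report = diversity_report(m, groups)
        assert report.loc["L1", "n_alleles_cult"] == 1
        assert report.loc["L1", "n_alleles_wild"] == 2
        assert report.loc["L1", "n_alleles_total"] == 3
        assert report.loc["L1", "pic_cult"] == 0.0

    def test_unknown_genotype_raises(self):
        m = _matrix([100, 102])
        with pytest.raises(ValueError):
            diversity_report(m, {"G0": "x"})


def test_pic_parameter_recovery():
    """PIC estimated from a large simulated panel approaches the planted
    value within binomial sampling error."""
    planted = [0.4, 0.35, 0.25]
    true_pic = pic(planted)
    m = generate_allele_matrix(1, 4000, planted, seed=99)
    est = pic(allele_frequencies(m, "L01"))
    # each frequency has s.e. ~ sqrt(p(1-p)/n) ~ 0.008; PIC error is of
    # the same order
    assert est == pytest.approx(true_pic, abs=0.03)


def test_similarity_matrix_properties():
    m = generate_allele_matrix(6, 8, [0.5, 0.3, 0.2], seed=3)
    bands, _ = binary_band_matrix(m)
    sim = jaccard_similarity_matrix(bands)
    assert np.allclose(np.diag(sim), 1.0)
    assert np.allclose(sim, sim.T)
    root = upgma(1.0 - sim)
    assert sorted(root.leaves()) == sorted(m.index)
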