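"""Marker scoring statistics: allele frequencies, PIC, Jaccard similarity,
UPGMA clustering and F2 segregation testing.

Genotypes are treated as homozygous inbreds — one allele (band size) per
genotype per locus, which matches how varietal SSR panels are scored from
gels.  Missing observations are a dedicated sentinel (NA), never
conflated with band absence.

PIC follows Botstein's definition ``PIC = 1 - sum(p_i^2)``.  Pairwise
genetic similarity is Jaccard's coefficient on the binary band matrix;
clustering uses UPGMA on ``1 - J`` distances (similarity and distance
orderings are equivalent for the dendrogram topology).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlleleMatrix",
    "DendrogramNode",
    "allele_frequencies",
    "pic",
    "binary_band_matrix",
    "jaccard",
    "jaccard_similarity_matrix",
    "upgma",
    "cophenetic_distances",
    "chi_square_segregation",
    "diversity_report",
]

#: An allele matrix is a pandas DataFrame: genotypes as rows, loci as
#: columns, integer allele size codes as values, ``pd.NA``/``NaN`` missing.
AlleleMatrix = pd.DataFrame


def allele_frequencies(matrix: AlleleMatrix, locus: str) -> pd.Series:
    """Allele frequencies at *locus*, indexed by ascending allele code.

    Missing observations are excluded from the denominator.  Raises on an
    unknown or all-missing locus.
    """
    if locus not in matrix.columns:
        raise KeyError(f"locus {locus!r} not in matrix")
    col = matrix[locus].dropna()
    if col.empty:
        raise ValueError(f"locus {locus!r} has no non-missing observations")
    counts = col.value_counts().sort_index()
    freqs = counts / counts.sum()
    freqs.name = locus
    return freqs


def pic(freqs: Iterable[float]) -> float:
    """Polymorphism information content, ``1 - sum(p_i^2)``.

    Bounded by ``1 - 1/k`` for k alleles, attained at uniform
    frequencies; 0 for a monomorphic locus.
    """
    p = np.asarray(list(freqs), dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))


def binary_band_matrix(matrix: AlleleMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand an allele matrix into genotype x band presence/absence.

    Returns ``(bands, missing_mask)``: *bands* has one 0/1 column per
    (locus, allele) pair (MultiIndex columns); a genotype missing at a
    locus scores 0 in all that locus's columns and is flagged True in
    *missing_mask* (genotype x locus) so the zeros are not mistaken for
    true band absence.
    """
    cols: dict[tuple[str, object], pd.Series] = {}
    for locus in matrix.columns:
        col = matrix[locus]
        for allele in sorted(col.dropna().unique()):
            cols[(locus, allele)] = (col == allele).fillna(False).astype(int)
    if cols:
        bands = pd.DataFrame(cols, index=matrix.index)
        bands.columns = pd.MultiIndex.from_tuples(bands.columns, names=["locus", "allele"])
    else:
        bands = pd.DataFrame(
            index=matrix.index,
            columns=pd.MultiIndex.from_tuples([], names=["locus", "allele"]),
        )
    missing_mask = matrix.isna()
    return bands, missing_mask


def jaccard(profile_a: Sequence[int], profile_b: Sequence[int]) -> float:
    """Jaccard similarity of two 0/1 band profiles.

    Shared bands over union bands; positions absent in both are ignored.
    An empty union returns 1.0 by convention (two bandless profiles are
    indistinguishable).
    """
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def jaccard_similarity_matrix(bands: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard similarity between all genotypes (rows) of a
    binary band matrix."""
    labels = list(bands.index)
    arr = bands.to_numpy(dtype=bool)
    n = len(labels)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jaccard(arr[i], arr[j])
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass(frozen=True)
class DendrogramNode:
    """Node of a UPGMA dendrogram.

    Leaves carry a label at height 0; internal nodes merge exactly two
    children at non-decreasing heights (half the inter-cluster distance).
    """

    height: float
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def count(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.count for c in self.children)

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [l for c in self.children for l in c.leaves()]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""

        def fmt(node: "DendrogramNode", parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{blen:g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{blen:g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(dist: pd.DataFrame) -> DendrogramNode:
    """UPGMA (average-linkage, SAHN) agglomerative clustering.

    *dist* is a labelled symmetric distance matrix with zero diagonal.
    At each step the closest cluster pair merges at height ``d/2``; the
    new cluster's distance to the rest is the member-count-weighted mean
    (the arithmetic mean over all cross pairs).  Ties are broken by the
    lexicographically smallest pair of cluster labels, a cluster being
    labelled by its smallest leaf.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels to cluster")
    if list(dist.columns) != labels:
        raise ValueError("distance matrix rows and columns must share labels")
    arr = dist.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("distances must be non-negative")
    if np.abs(np.diag(arr)).max() > 1e-9:
        raise ValueError("distance matrix diagonal must be zero")
    if np.abs(arr - arr.T).max() > 1e-9:
        raise ValueError("distance matrix must be symmetric")

    clusters: dict[str, DendrogramNode] = {
        lab: DendrogramNode(height=0.0, label=lab) for lab in labels
    }
    d: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            d[frozenset((a, labels[j]))] = arr[i, j]

    while len(clusters) > 1:
        best_pair: tuple[str, str] | None = None
        best_dist = np.inf
        for pair_key, dist_ij in d.items():
            a, b = sorted(pair_key)
            if dist_ij < best_dist or (dist_ij == best_dist and (a, b) < best_pair):
                best_dist = dist_ij
                best_pair = (a, b)
        a, b = best_pair
        node_a, node_b = clusters.pop(a), clusters.pop(b)
        merged = DendrogramNode(height=best_dist / 2.0, children=(node_a, node_b))
        na, nb = node_a.count, node_b.count
        new_label = a  # a < b, so the smallest leaf label survives
        for other in clusters:
            key = frozenset((new_label, other))
            d[key] = (
                na * d.pop(frozenset((a, other))) + nb * d.pop(frozenset((b, other)))
            ) / (na + nb)
        del d[frozenset((a, b))]
        clusters[new_label] = merged

    return next(iter(clusters.values()))


def cophenetic_distances(root: DendrogramNode) -> pd.DataFrame:
    """Cophenetic distance matrix implied by a dendrogram: twice the
    height of the smallest cluster joining each leaf pair."""
    labels = sorted(root.leaves())
    out = pd.DataFrame(0.0, index=labels, columns=labels)

    def walk(node: DendrogramNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        left = walk(node.children[0])
        right = walk(node.children[1])
        for a in left:
            for b in right:
                out.loc[a, b] = out.loc[b, a] = 2.0 * node.height
        return left + right

    walk(root)
    return out


def chi_square_segregation(
    counts: Sequence[int], ratio: Sequence[float] = (1, 2, 1)
) -> tuple[float, int, float]:
    """Pearson chi-square goodness-of-fit of observed genotype class
    counts against an expected segregation ratio (default codominant F2
    1:2:1).  Returns ``(statistic, df, p_value)``."""
    obs = np.asarray(counts, dtype=float)
    if (obs < 0).any():
        raise ValueError("negative counts")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    ratio = np.asarray(ratio, dtype=float)
    if len(ratio) != len(obs):
        raise ValueError("ratio and counts differ in length")
    expected = total * ratio / ratio.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = len(obs) - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def diversity_report(
    matrix: AlleleMatrix, group_labels: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-marker allele counts and PIC, overall and per genotype group.

    *group_labels* maps every genotype (row label) to a group name (e.g.
    cultivated vs wild).  The returned table has one row per locus plus a
    bottom ``Average`` row of arithmetic means, with columns
    ``n_alleles_<group>``, ``pic_<group>``, ``n_alleles_total``,
    ``pic_total``.  A group with no scorable observations at a locus gets
    NaN there.
    """
    groups = pd.Series(group_labels)
    unknown = set(matrix.index) - set(groups.index)
    if unknown:
        raise ValueError(f"genotypes without a group label: {sorted(unknown)}")
    group_names = sorted(groups.loc[list(matrix.index)].unique())

    rows = {}
    for locus in matrix.columns:
        row: dict[str, float] = {}
        for name in group_names:
            members = [g for g in matrix.index if groups[g] == name]
            col = matrix.loc[members, locus].dropna()
            if col.empty:
                row[f"n_alleles_{name}"] = np.nan
                row[f"pic_{name}"] = np.nan
            else:
                row[f"n_alleles_{name}"] = col.nunique()
                row[f"pic_{name}"] = pic(col.value_counts(normalize=True))
        col = matrix[locus].dropna()
        row["n_alleles_total"] = col.nunique() if not col.empty else np.nan
        row["pic_total"] = pic(col.value_counts(normalize=True)) if not col.empty else np.nan
        rows[locus] = row

    report = pd.DataFrame.from_dict(rows, orient="index")
    report.loc["Average"] = report.mean()
    report.index.name = "marker"
    return report
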