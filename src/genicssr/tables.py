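"""Published genic-SSR marker survey panels for pigeonpea (ASSR series).

Two screening panels are bundled as plain data, for use as worked
examples and as reference inputs for aggregate marker statistics:

* :func:`polymorphic_marker_survey` — the 71 ASSR markers found
  polymorphic when 550 validated markers were screened on eight
  pigeonpea varieties (agarose gels): motif, repeat count, product size,
  allele count and PIC per marker.
* :func:`diversity_marker_survey` — the 20 highly polymorphic ASSR
  markers used for diversity analysis of 30 genotypes (22 cultivars and
  8 wild *Cajanus* relatives): allele counts and PIC for the cultivated,
  wild and combined panels.

Values are as printed in the source survey; PIC values are rounded to
2 d.p. there, so column aggregates can differ from full-precision
arithmetic in the last digit.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["polymorphic_marker_survey", "diversity_marker_survey"]

# marker_id, motif, repeats, product_size_bp, n_alleles, pic
_EIGHT_VARIETY_PANEL = [
    ("ASSR1", "GA", 10, 100, 2, 0.47),
    ("ASSR3", "AGAAAG", 5, 145, 2, 0.47),
    ("ASSR5", "AAATT", 6, 130, 2, 0.36),
    ("ASSR8", "AGA", 9, 140, 2, 0.50),
    ("ASSR9", "AGA", 8, 150, 2, 0.23),
    ("ASSR11", "CTC", 7, 140, 2, 0.23),
    ("ASSR12", "AACAC", 6, 165, 2, 0.38),
    ("ASSR13", "ATTAG", 5, 160, 2, 0.37),
    ("ASSR15", "CAA", 8, 150, 2, 0.38),
    ("ASSR16", "GTT", 9, 150, 2, 0.23),
    ("ASSR17", "CCTTCT", 6, 180, 2, 0.38),
    ("ASSR19", "TGTTCA", 5, 160, 2, 0.38),
    ("ASSR20", "AT", 11, 140, 2, 0.23),
    ("ASSR23", "CCTTCT", 5, 150, 2, 0.47),
    ("ASSR48", "AAGAGG", 6, 150, 2, 0.30),
    ("ASSR66", "CT", 12, 180, 2, 0.44),
    ("ASSR70", "GGTAGA", 6, 170, 2, 0.45),
    ("ASSR77", "CT", 10, 140, 2, 0.41),
    ("ASSR93", "CATTTG", 5, 170, 2, 0.47),
    ("ASSR97", "ATGGAC", 8, 150, 3, 0.66),
    ("ASSR100", "GGT", 7, 150, 2, 0.23),
    ("ASSR108", "GAT", 7, 150, 2, 0.23),
    ("ASSR109", "GAA", 10, 140, 2, 0.38),
    ("ASSR120", "CTT", 7, 160, 2, 0.38),
    ("ASSR148", "CAA", 7, 110, 2, 0.50),
    ("ASSR153", "GAG", 8, 150, 2, 0.23),
    ("ASSR155", "TGGACA", 5, 130, 2, 0.23),
    ("ASSR169", "TCA", 7, 160, 2, 0.23),
    ("ASSR182", "ATT", 7, 220, 2, 0.38),
    ("ASSR205", "ATGAAG", 11, 170, 2, 0.38),
    ("ASSR206", "GTAATA", 6, 150, 2, 0.47),
    ("ASSR207", "ATCT", 5, 190, 2, 0.23),
    ("ASSR221", "TCG", 8, 165, 2, 0.23),
    ("ASSR228", "CTAAGG", 5, 140, 3, 0.53),
    ("ASSR229", "TAAGGG", 5, 160, 3, 0.53),
    ("ASSR230", "GAGCAT", 9, 170, 2, 0.38),
    ("ASSR236", "ACTAGC", 10, 230, 2, 0.23),
    ("ASSR237", "GGTGAA", 7, 180, 2, 0.23),
    ("ASSR247", "CACCAA", 6, 180, 2, 0.38),
    ("ASSR253", "CCCAAG", 6, 150, 2, 0.23),
    ("ASSR258", "CCATA", 5, 140, 2, 0.23),
    ("ASSR277", "TCCTGT", 5, 130, 2, 0.50),
    ("ASSR280", "TGGCAT", 5, 170, 2, 0.23),
    ("ASSR281", "CAAATG", 6, 220, 5, 0.83),
    ("ASSR286", "TGTTCA", 5, 160, 2, 0.38),
    ("ASSR293", "AGA", 7, 130, 2, 0.38),
    ("ASSR295", "ATA", 8, 140, 2, 0.38),
    ("ASSR297", "GCCACC", 5, 180, 2, 0.38),
    ("ASSR304", "GTT", 7, 110, 2, 0.50),
    ("ASSR317", "GAGCAT", 9, 150, 2, 0.47),
    ("ASSR352", "TTTAA", 6, 130, 2, 0.47),
    ("ASSR363", "GCATCA", 5, 190, 2, 0.50),
    ("ASSR366", "CGT", 8, 140, 2, 0.47),
    ("ASSR379", "TTCATG", 5, 140, 2, 0.47),
    ("ASSR380", "TTTC", 5, 170, 2, 0.23),
    ("ASSR390", "GAGCAA", 6, 190, 2, 0.50),
    ("ASSR408", "CAC", 6, 190, 2, 0.37),
    ("ASSR416", "TGA", 6, 210, 2, 0.37),
    ("ASSR427", "CT", 9, 170, 2, 0.37),
    ("ASSR495", "CT", 9, 200, 2, 0.50),
    ("ASSR610", "GTG", 6, 150, 2, 0.50),
    ("ASSR613", "CCA", 6, 150, 2, 0.21),
    ("ASSR895", "ATT", 6, 150, 2, 0.22),
    ("ASSR911", "AAT", 6, 140, 2, 0.47),
    ("ASSR980", "AAC", 6, 150, 2, 0.37),
    ("ASSR1193", "CA", 9, 180, 2, 0.47),
    ("ASSR1432", "TTC", 6, 140, 2, 0.47),
    ("ASSR1486", "TTG", 6, 140, 2, 0.37),
    ("ASSR1689", "AAT", 6, 140, 2, 0.37),
    ("ASSR1737", "TA", 9, 150, 2, 0.50),
    ("ASSR1848", "CAT", 6, 150, 3, 0.59),
]

# marker_id, allele_size_range, n_alleles (cultivars, wild, total),
# pic (cultivars, wild, total)
_THIRTY_GENOTYPE_PANEL = [
    ("ASSR1", "75-120", 3, 4, 7, 0.46, 0.67, 0.65),
    ("ASSR3", "125-150", 3, 3, 4, 0.43, 0.85, 0.69),
    ("ASSR8", "130-150", 5, 4, 5, 0.68, 0.72, 0.69),
    ("ASSR23", "130-170", 4, 4, 5, 0.40, 0.55, 0.62),
    ("ASSR66", "170-210", 2, 6, 8, 0.35, 0.82, 0.68),
    ("ASSR70", "150-190", 4, 3, 7, 0.23, 0.78, 0.48),
    ("ASSR93", "140-170", 4, 4, 6, 0.48, 0.50, 0.56),
    ("ASSR97", "90-150", 3, 7, 10, 0.29, 0.86, 0.56),
    ("ASSR148", "90-120", 5, 3, 5, 0.59, 0.82, 0.71),
    ("ASSR206", "115-155", 2, 2, 6, 0.63, 0.77, 0.69),
    ("ASSR228", "130-150", 5, 2, 5, 0.68, 0.83, 0.71),
    ("ASSR277", "90-145", 2, 7, 8, 0.30, 0.61, 0.53),
    ("ASSR281", "210-245", 5, 3, 5, 0.69, 0.67, 0.72),
    ("ASSR304", "90-120", 6, 6, 9, 0.35, 0.82, 0.64),
    ("ASSR317", "13-170", 5, 5, 8, 0.65, 0.85, 0.72),
    ("ASSR352", "110-145", 3, 3, 5, 0.77, 0.69, 0.65),
    ("ASSR363", "170-195", 4, 5, 5, 0.48, 0.78, 0.66),
    ("ASSR366", "135-150", 3, 5, 6, 0.33, 0.63, 0.52),
    ("ASSR379", "120-140", 4, 2, 5, 0.73, 0.47, 0.72),
    ("ASSR390", "160-195", 3, 4, 6, 0.41, 0.72, 0.46),
]


def polymorphic_marker_survey() -> pd.DataFrame:
    """The 71 polymorphic ASSR markers from the eight-variety screen."""
    return pd.DataFrame(
        _EIGHT_VARIETY_PANEL,
        columns=["marker_id", "motif", "repeats", "product_size_bp",
                 "n_alleles", "pic"],
    ).set_index("marker_id")


def diversity_marker_survey() -> pd.DataFrame:
    """The 20 highly polymorphic ASSR markers scored on 30 genotypes."""
    return pd.DataFrame(
        _THIRTY_GENOTYPE_PANEL,
        columns=["marker_id", "allele_size_range", "n_alleles_cultivars",
                 "n_alleles_wild", "n_alleles_total", "pic_cultivars",
                 "pic_wild", "pic_total"],
    ).set_index("marker_id")
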