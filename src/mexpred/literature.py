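"""Bundled reference set of literature-supported functional microexons.

Nineteen human microexons with experimentally characterized functional
roles, curated from published case studies, together with the
functional probability assigned to each by the TCA+SVM route of this
model (hg19 coordinates, 0-based starts). The set serves as a
regression fixture for threshold behaviour: because every member has
literature support for function, the fraction called functional at a
given probability threshold is a direct accuracy estimate.
"""

from __future__ import annotations

import pandas as pd

from .model import PredictionRecord

#: gene, chrom, 0-based start, length (nt), assigned functional probability
_CASES: tuple[tuple[str, str, int, int, float], ...] = (
    ("ROBO1", "chr3", 78_696_778, 27, 0.739),
    ("ANK2", "chr4", 114_158_754, 24, 0.744),
    ("CR1", "chr1", 207_795_317, 24, 0.402),
    ("PICALM", "chr11", 85_689_112, 24, 0.844),
    ("FERMT2", "chr14", 53_327_731, 21, 0.745),
    ("ITSN1", "chr21", 35_174_733, 15, 0.631),
    ("ZFYVE27", "chr10", 99_512_613, 21, 0.116),
    ("L1CAM", "chrX", 153_141_083, 21, 0.811),
    ("DTNA", "chr18", 32_401_063, 9, 0.581),
    ("SHANK2", "chr11", 70_788_698, 12, 0.711),
    ("APBB1", "chr11", 6_423_206, 6, 0.776),
    ("APBB2", "chr4", 40_824_046, 21, 0.802),
    ("APBB3", "chr5", 139_941_428, 6, 0.717),
    ("TRAPPC9", "chr8", 141_436_713, 27, 0.865),
    ("RAB3GAP1", "chr2", 135_809_868, 27, 0.731),
    ("Bin1", "chr2", 127_810_997, 24, 0.740),
    ("DOCK9", "chr13", 99_461_376, 6, 0.663),
    ("MEF2D", "chr1", 156_446_285, 21, 0.120),
    ("KDM1A", "chr1", 23_385_839, 12, 0.717),
)


def literature_catalog() -> pd.DataFrame:
    """The 19 reference cases as a DataFrame.

    Columns: gene, chrom, start (0-based), length, probability.
    """
    return pd.DataFrame(
        list(_CASES), columns=["gene", "chrom", "start", "length", "probability"]
    )


def literature_predictions(threshold: float = 0.5) -> list[PredictionRecord]:
    """The reference cases as prediction records at a given threshold."""
    return [
        PredictionRecord(gene, probability, threshold, "tca_svm")
        for gene, _, _, _, probability in _CASES
    ]
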