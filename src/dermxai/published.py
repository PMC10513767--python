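"""Reference agreement counts from the dermatologist reader study.

The reader study behind this pipeline had two dermatologists grade 100
melanoma dermoscopy images and the corresponding saliency maps of five
explanation techniques (2 graders x 100 lesions = denominator 200 per
criterion; 10 border pairs were NA, leaving 190).  Its published agreement
table is kept here as input data: the counts are re-aggregated through
:mod:`dermxai.agreement` to validate the statistic's arithmetic end to end,
and the printed percentages are cross-checked against the recomputed ones.

One printed percentage is internally inconsistent with its own count
(LIME / border / no agreement: 32 of 190 is 16.84%, printed 6.84%); the
counts sum correctly, so the percentage is treated as a typographical
erratum and flagged by :func:`check_published_percentages`.
"""

from __future__ import annotations

import pandas as pd

from .agreement import aggregate_table, records_from_counts, table_percentage

__all__ = [
    "PUBLISHED_COUNTS",
    "PUBLISHED_PERCENTAGES",
    "KNOWN_ERRATA",
    "published_records",
    "published_table",
    "check_published_percentages",
]

#: (technique, criterion) -> (total, partial, none) counts.
PUBLISHED_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("eigen_cam", "asymmetry"): (52, 96, 52),
    ("grad_cam", "asymmetry"): (105, 83, 12),
    ("grad_cam_pp", "asymmetry"): (101, 93, 6),
    ("lime", "asymmetry"): (115, 80, 5),
    ("score_cam", "asymmetry"): (76, 100, 24),
    ("eigen_cam", "border"): (62, 104, 24),
    ("grad_cam", "border"): (62, 110, 18),
    ("grad_cam_pp", "border"): (74, 78, 38),
    ("lime", "border"): (66, 92, 32),
    ("score_cam", "border"): (70, 80, 40),
    ("eigen_cam", "color"): (75, 121, 4),
    ("grad_cam", "color"): (69, 123, 8),
    ("grad_cam_pp", "color"): (41, 132, 27),
    ("lime", "color"): (29, 148, 23),
    ("score_cam", "color"): (32, 141, 27),
}

#: (technique, criterion) -> (total%, partial%, none%) as printed.
PUBLISHED_PERCENTAGES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("eigen_cam", "asymmetry"): (26.00, 48.00, 26.00),
    ("grad_cam", "asymmetry"): (52.50, 41.50, 6.00),
    ("grad_cam_pp", "asymmetry"): (50.50, 46.50, 3.00),
    ("lime", "asymmetry"): (57.50, 40.00, 2.50),
    ("score_cam", "asymmetry"): (38.00, 50.00, 12.00),
    ("eigen_cam", "border"): (32.63, 54.74, 12.63),
    ("grad_cam", "border"): (32.63, 57.89, 9.47),
    ("grad_cam_pp", "border"): (38.95, 41.05, 20.00),
    ("lime", "border"): (34.74, 48.42, 6.84),  # none% is a known erratum
    ("score_cam", "border"): (36.84, 42.11, 21.05),
    ("eigen_cam", "color"): (37.50, 60.50, 2.00),
    ("grad_cam", "color"): (34.50, 61.50, 4.00),
    ("grad_cam_pp", "color"): (20.50, 66.00, 13.50),
    ("lime", "color"): (14.50, 74.00, 11.50),
    ("score_cam", "color"): (16.00, 70.50, 13.50),
    ("eigen_cam", "TOTAL"): (32.03, 54.41, 13.56),
    ("grad_cam", "TOTAL"): (40.00, 53.56, 6.44),
    ("grad_cam_pp", "TOTAL"): (36.61, 51.36, 12.03),
    ("lime", "TOTAL"): (35.59, 54.24, 10.17),
    ("score_cam", "TOTAL"): (30.17, 54.41, 15.42),
}

#: Cells whose printed percentage disagrees with the printed count.
KNOWN_ERRATA: tuple[tuple[str, str, str], ...] = (("lime", "border", "none"),)


def published_records() -> pd.DataFrame:
    """The published counts expanded into agreement records."""
    return records_from_counts(PUBLISHED_COUNTS)


def published_table() -> pd.DataFrame:
    """Agreement table recomputed from the published counts."""
    return aggregate_table(published_records())


def check_published_percentages(table: pd.DataFrame | None = None) -> list[dict]:
    """Compare recomputed percentages against the printed ones.

    Returns one flag dict per mismatching cell (at the printed 2-decimal
    precision); with consistent source data the only flag is the known
    LIME / border / none erratum.
    """
    if table is None:
        table = published_table()
    flags = []
    for (technique, criterion), printed in PUBLISHED_PERCENTAGES.items():
        for cls, printed_pct in zip(("total", "partial", "none"), printed):
            computed = table_percentage(table, criterion, technique, cls)
            if abs(computed - printed_pct) > 0.005:
                flags.append(
                    {
                        "technique": technique,
                        "criterion": criterion,
                        "class": cls,
                        "printed_pct": printed_pct,
                        "computed_pct": computed,
                        "known_erratum": (technique, criterion, cls) in KNOWN_ERRATA,
                    }
                )
    return flags
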