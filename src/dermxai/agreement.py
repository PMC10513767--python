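"""Total/partial/no-agreement statistic between clinical and map grades.

A clinical grade and a map grade (each 0/1/2 ordinal) agree *totally* when
their difference is 0, *partially* when it is 1, and *not at all* when it is
2.  Pairs where either side is NA (border off-canvas) are excluded, which
shrinks that criterion's denominator.  Per technique and criterion the pairs
are tallied into a 3x3 confusion matrix (diagonal = total agreement) and an
agreement table with counts, percentages, per-criterion denominators, and a
TOTAL block summed over the three criteria.  Techniques are ranked by the
combined total+partial rate over the TOTAL block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clinical import CRITERIA
from .errors import InputError
from .saliency import TECHNIQUES

__all__ = [
    "classify_agreement",
    "make_records",
    "records_from_counts",
    "build_confusion",
    "aggregate_table",
    "combined_rate",
    "rank_techniques",
    "table_percentage",
]

AGREEMENT_CLASSES = ("total", "partial", "none")
_VALID_GRADES = (0, 1, 2)

RECORD_COLUMNS = [
    "lesion_id",
    "grader_id",
    "technique",
    "criterion",
    "clinical",
    "map",
    "agreement",
]


def _norm_grade(g) -> int | None:
    if g is None:
        return None
    if isinstance(g, float) and np.isnan(g):
        return None
    gi = int(g)
    if gi not in _VALID_GRADES:
        raise InputError(f"grade must be 0, 1, 2 or NA; got {g!r}")
    return gi


def classify_agreement(clinical, map_grade) -> str:
    """'total' | 'partial' | 'none' by |clinical - map|; 'excluded' on NA."""
    c = _norm_grade(clinical)
    m = _norm_grade(map_grade)
    if c is None or m is None:
        return "excluded"
    return AGREEMENT_CLASSES[abs(c - m)]


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build an agreement-record frame; fills the agreement column."""
    df = pd.DataFrame(rows)
    missing = set(RECORD_COLUMNS) - {"agreement"} - set(df.columns)
    if missing:
        raise InputError(f"records missing columns: {sorted(missing)}")
    df["agreement"] = [
        classify_agreement(c, m) for c, m in zip(df["clinical"], df["map"])
    ]
    return df[RECORD_COLUMNS]


def records_from_counts(counts: dict) -> pd.DataFrame:
    """Expand a per-(technique, criterion) count table into records.

    ``counts`` maps (technique, criterion) -> (n_total, n_partial, n_none).
    The expansion uses representative grade pairs (0,0), (0,1), (0,2);
    aggregation only depends on the agreement class, so the table built from
    these records carries exactly the given counts.
    """
    rows = []
    lesion = 0
    for (technique, criterion), (nt, npart, nn) in counts.items():
        for n, (c, m) in ((nt, (0, 0)), (npart, (0, 1)), (nn, (0, 2))):
            for _ in range(int(n)):
                rows.append(
                    {
                        "lesion_id": f"L{lesion:05d}",
                        "grader_id": 1,
                        "technique": technique,
                        "criterion": criterion,
                        "clinical": c,
                        "map": m,
                    }
                )
                lesion += 1
    return make_records(rows)


def build_confusion(records: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """3x3 clinical-by-map count matrix per (technique, criterion).

    Excluded (NA) records are dropped; the matrix diagonal counts total
    agreement, off-diagonals one/two steps away partial/no agreement.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    kept = records[records["agreement"] != "excluded"]
    for (technique, criterion), grp in kept.groupby(["technique", "criterion"]):
        m = np.zeros((3, 3), dtype=int)
        for c, g in zip(grp["clinical"].astype(int), grp["map"].astype(int)):
            m[c, g] += 1
        out[(technique, criterion)] = m
    return out


def aggregate_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-technique, per-criterion agreement counts and percentages.

    Returns a tidy frame indexed by (criterion, technique) with columns
    ``total, partial, none`` (counts), ``total_pct, partial_pct, none_pct``
    (percentages of the criterion denominator, full precision), and ``n``
    (the denominator).  A ``TOTAL`` criterion block sums counts across the
    three criteria.
    """
    if records.empty:
        raise InputError("no records to aggregate")
    kept = records[records["agreement"] != "excluded"]
    rows = []
    techniques = sorted(kept["technique"].unique())
    criteria = [c for c in CRITERIA if c in set(kept["criterion"])]
    for criterion in criteria:
        for technique in techniques:
            grp = kept[(kept["criterion"] == criterion) & (kept["technique"] == technique)]
            n = len(grp)
            counts = {
                cls: int((grp["agreement"] == cls).sum()) for cls in AGREEMENT_CLASSES
            }
            rows.append({"criterion": criterion, "technique": technique, "n": n, **counts})
    for technique in techniques:
        sub = [r for r in rows if r["technique"] == technique]
        rows.append(
            {
                "criterion": "TOTAL",
                "technique": technique,
                "n": sum(r["n"] for r in sub),
                **{cls: sum(r[cls] for r in sub) for cls in AGREEMENT_CLASSES},
            }
        )
    table = pd.DataFrame(rows).set_index(["criterion", "technique"])
    for cls in AGREEMENT_CLASSES:
        with np.errstate(invalid="ignore"):
            table[f"{cls}_pct"] = np.where(
                table["n"] > 0, table[cls] / table["n"] * 100.0, 0.0
            )
    return table


def table_percentage(table: pd.DataFrame, criterion: str, technique: str, cls: str) -> float:
    """Percentage for one cell, rendered at 2 decimals (table style)."""
    return round(float(table.loc[(criterion, technique), f"{cls}_pct"]), 2)


def combined_rate(table: pd.DataFrame, technique: str) -> float:
    """Total+partial agreement rate over the TOTAL block, one decimal."""
    try:
        row = table.loc[("TOTAL", technique)]
    except KeyError:
        raise InputError(f"technique {technique!r} not present in table") from None
    return round(float((row["total"] + row["partial"]) / row["n"] * 100.0), 1)


def rank_techniques(table: pd.DataFrame) -> list[str]:
    """Techniques in descending combined-rate order.

    Ties break by total-agreement rate (descending), then name (ascending).
    """
    techniques = sorted({t for (_, t) in table.index})
    if len(techniques) < 1:
        raise InputError("table contains no techniques")

    def key(t: str):
        row = table.loc[("TOTAL", t)]
        combined = (row["total"] + row["partial"]) / row["n"]
        total_rate = row["total"] / row["n"]
        return (-combined, -total_rate, t)

    return sorted(techniques, key=key)
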