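"""Agreement statistic: pair classification, confusion tallies, table
aggregation, and the published reader-study arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermxai.agreement import (
    aggregate_table,
    build_confusion,
    classify_agreement,
    combined_rate,
    make_records,
    rank_techniques,
    records_from_counts,
    table_percentage,
)
from dermxai.errors import InputError
from dermxai.published import (
    KNOWN_ERRATA,
    PUBLISHED_COUNTS,
    PUBLISHED_PERCENTAGES,
    check_published_percentages,
    published_table,
)

GRADES = [0, 1, 2, None]


class TestClassifyAgreement:
    @pytest.mark.parametrize("clinical,map_grade,expected", [
        (0, 0, "total"), (1, 1, "total"), (2, 2, "total"),
        (0, 1, "partial"), (2, 1, "partial"),
        (0, 2, "none"), (2, 0, "none"),
        (None, 1, "excluded"), (1, None, "excluded"), (None, None, "excluded"),
    ])
    def test_difference_rule(self, clinical, map_grade, expected):
        assert classify_agreement(clinical, map_grade) == expected

    def test_invalid_grade_raises(self):
        with pytest.raises(InputError):
            classify_agreement(3, 0)

    @settings(max_examples=64, deadline=None, derandomize=True)
    @given(a=st.sampled_from(GRADES), b=st.sampled_from(GRADES))
    def test_symmetric_in_its_arguments(self, a, b):
        assert classify_agreement(a, b) == classify_agreement(b, a)


def _records(pairs, technique="grad_cam", criterion="asymmetry"):
    return make_records(
        [
            {
                "lesion_id": f"L{i}",
                "grader_id": 1,
                "technique": technique,
                "criterion": criterion,
                "clinical": c,
                "map": m,
            }
            for i, (c, m) in enumerate(pairs)
        ]
    )


class TestBuildConfusion:
    def test_single_cell_when_all_pairs_identical(self):
        conf = build_confusion(_records([(0, 0)] * 5))
        m = conf[("grad_cam", "asymmetry")]
        assert m[0, 0] == 5 and m.sum() == 5

    def test_random_pairs_tally_matches_direct_count(self):
        rng = np.random.default_rng(0)
        pairs = [(int(rng.integers(3)), int(rng.integers(3))) for _ in range(60)]
        pairs += [(None, 1), (2, None)]
        conf = build_confusion(_records(pairs))[("grad_cam", "asymmetry")]
        assert conf.sum() == 60
        for c in range(3):
            for g in range(3):
                assert conf[c, g] == sum(1 for a, b in pairs if a == c and b == g)

    def test_empty_input_gives_no_matrices(self):
        empty = _records([]) if False else pd.DataFrame(
            columns=["lesion_id", "grader_id", "technique", "criterion",
                     "clinical", "map", "agreement"]
        )
        assert build_confusion(empty) == {}

    def test_off_diagonal_totals_match_agreement_classes(self):
        pairs = [(0, 0), (0, 1), (1, 2), (0, 2), (2, 0)]
        records = _records(pairs)
        m = build_confusion(records)[("grad_cam", "asymmetry")]
        assert np.trace(m) == (records["agreement"] == "total").sum()
        one_step = m[0, 1] + m[1, 0] + m[1, 2] + m[2, 1]
        assert one_step == (records["agreement"] == "partial").sum()


class TestAggregateTable:
    def test_all_total_records(self):
        table = aggregate_table(_records([(1, 1)] * 4))
        assert table_percentage(table, "asymmetry", "grad_cam", "total") == 100.0
        assert table_percentage(table, "asymmetry", "grad_cam", "none") == 0.0

    def test_half_and_half(self):
        table = aggregate_table(_records([(0, 0), (0, 1)]))
        assert table_percentage(table, "asymmetry", "grad_cam", "total") == 50.0
        assert table_percentage(table, "asymmetry", "grad_cam", "partial") == 50.0

    def test_na_pairs_shrink_denominator(self):
        pairs = [(0, 0)] * 8 + [(None, 0)] * 2
        table = aggregate_table(_records(pairs, criterion="border"))
        assert int(table.loc[("border", "grad_cam"), "n"]) == 8

    def test_counts_round_trip_through_records(self):
        counts = {("lime", "asymmetry"): (3, 2, 1), ("lime", "border"): (4, 0, 2)}
        table = aggregate_table(records_from_counts(counts))
        assert tuple(table.loc[("asymmetry", "lime"), ["total", "partial", "none"]]) == (3, 2, 1)
        assert tuple(table.loc[("border", "lime"), ["total", "partial", "none"]]) == (4, 0, 2)
        assert tuple(table.loc[("TOTAL", "lime"), ["total", "partial", "none"]]) == (7, 2, 3)


class TestCombinedRateAndRanking:
    def test_all_none_records_rate_zero(self):
        table = aggregate_table(_records([(0, 2)] * 3))
        assert combined_rate(table, "grad_cam") == 0.0

    def test_unknown_technique_raises(self):
        table = aggregate_table(_records([(0, 0)]))
        with pytest.raises(InputError):
            combined_rate(table, "sam")

    def test_single_technique_ranking(self):
        table = aggregate_table(_records([(0, 0)]))
        assert rank_techniques(table) == ["grad_cam"]

    def test_tied_techniques_rank_alphabetically(self):
        rows = []
        for tech in ("score_cam", "eigen_cam"):
            rows.extend(
                {
                    "lesion_id": f"L{i}", "grader_id": 1, "technique": tech,
                    "criterion": "color", "clinical": 0, "map": m,
                }
                for i, m in enumerate([0, 1, 2])
            )
        table = aggregate_table(make_records(rows))
        assert rank_techniques(table) == ["eigen_cam", "score_cam"]


class TestPublishedArithmetic:
    def test_denominators_recovered_as_column_sums(self):
        table = published_table()
        for technique in ("grad_cam", "lime", "eigen_cam", "grad_cam_pp", "score_cam"):
            assert int(table.loc[("asymmetry", technique), "n"]) == 200
            assert int(table.loc[("border", technique), "n"]) == 190
            assert int(table.loc[("color", technique), "n"]) == 200
            total = table.loc[("TOTAL", technique)]
            assert int(total["n"]) == 590
            for cls in ("total", "partial", "none"):
                col_sum = sum(
                    int(table.loc[(c, technique), cls])
                    for c in ("asymmetry", "border", "color")
                )
                assert int(total[cls]) == col_sum

    def test_reproduces_printed_percentages_except_erratum(self):
        table = published_table()
        for (technique, criterion), printed in PUBLISHED_PERCENTAGES.items():
            for cls, pct in zip(("total", "partial", "none"), printed):
                if (technique, criterion, cls) in KNOWN_ERRATA:
                    continue
                assert table_percentage(table, criterion, technique, cls) == pct

    def test_erratum_flagged_with_consistent_counts(self):
        flags = check_published_percentages()
        assert len(flags) == 1
        flag = flags[0]
        assert (flag["technique"], flag["criterion"], flag["class"]) == KNOWN_ERRATA[0]
        assert flag["known_erratum"]
        # the counts themselves are internally consistent
        nt, npart, nn = PUBLISHED_COUNTS[("lime", "border")]
        assert nt + npart + nn == 190
        assert flag["computed_pct"] == pytest.approx(round(32 / 190 * 100, 2))

    def test_combined_rates_and_ranking(self):
        table = published_table()
        expected = {
            "grad_cam": 93.6, "lime": 89.8, "grad_cam_pp": 88.0,
            "eigen_cam": 86.4, "score_cam": 84.6,
        }
        for technique, rate in expected.items():
            assert combined_rate(table, technique) == rate
        assert rank_techniques(table) == [
            "grad_cam", "lime", "grad_cam_pp", "eigen_cam", "score_cam",
        ]
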