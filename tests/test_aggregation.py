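"""Concordance tables, subgroup strata and report assembly."""

import pytest

from rapidmeta import (
    AlphaConfig,
    ComparisonResult,
    MetaAnalysisData,
    MethodSet,
    SubgroupSpec,
    build_report,
    concordance_table,
    event_rate,
    subgroup_by_event_rate,
    subgroup_by_i2,
    threshold_proportions,
)
from rapidmeta.aggregation import comparisons_to_frame, frame_to_comparisons
from rapidmeta.data_model import ValidationError

from conftest import make_trial


def ok_row(ma_id, bias, direction_change="concordant",
           significance_change="concordant", rate=0.05, i2=10.0,
           method="mh_fixed"):
    directions = {
        "concordant": ("beneficial", "beneficial"),
        "beneficial_to_harmful": ("harmful", "beneficial"),
        "harmful_to_beneficial": ("beneficial", "harmful"),
        "involves_null": ("null", "harmful"),
    }
    d_full, d_rapid = directions[direction_change]
    p_full, p_rapid = {
        "concordant": (0.2, 0.3),
        "sig_to_nonsig": (0.01, 0.5),
        "nonsig_to_sig": (0.5, 0.01),
    }[significance_change]
    return ComparisonResult(
        ma_id=ma_id, method=method, status="ok", k_full=8, k_rapid=5,
        registration_fraction=5 / 8, event_rate_full=rate, i2_full=i2,
        theta_full=0.8, theta_rapid=0.8 * (1 - bias), bias=bias,
        within_05=bias < 0.05, within_10=bias < 0.10,
        within_15=bias < 0.15, within_20=bias < 0.20,
        direction_full=d_full, direction_rapid=d_rapid,
        direction_change=direction_change,
        p_full=p_full, p_rapid=p_rapid,
        significance_change=significance_change,
    )


def failed_row(ma_id, status, method="mh_fixed"):
    return ComparisonResult(
        ma_id=ma_id, method=method, status=status, k_full=8,
        k_rapid=0 if status == "rapid_infeasible" else 4,
        registration_fraction=0.0 if status == "rapid_infeasible" else 0.5,
        event_rate_full=0.05, i2_full=None,
    )


def test_event_rate_arithmetic():
    trials = (make_trial("M", "T1", 10, 100, 5, 100),)
    assert event_rate(MetaAnalysisData(ma_id="M", trials=trials)) == 15 / 200
    two = trials + (make_trial("M", "T2", 0, 50, 0, 50),)
    assert event_rate(MetaAnalysisData(ma_id="M", trials=two)) == 15 / 300
    zeros = tuple(make_trial("M", f"T{i}", 0, 50, 0, 50) for i in range(2))
    assert event_rate(MetaAnalysisData(ma_id="M", trials=zeros)) == 0.0


def test_threshold_proportions_enumeration():
    rows = [ok_row(f"M{i}", b) for i, b in enumerate([0.01, 0.07, 0.12, 0.25])]
    props = threshold_proportions(rows, (0.05, 0.10, 0.15, 0.20))
    assert props == {0.05: 0.25, 0.10: 0.5, 0.15: 0.75, 0.20: 0.75}


def test_threshold_boundary_is_strict():
    rows = [ok_row("M1", 0.05)]
    props = threshold_proportions(rows, (0.05, 0.10))
    assert props[0.05] == 0.0  # bias exactly at the cutoff is not "within"
    assert props[0.10] == 1.0


def test_threshold_proportions_all_zero_bias():
    rows = [ok_row(f"M{i}", 0.0) for i in range(3)]
    assert set(threshold_proportions(rows, (0.05, 0.2)).values()) == {1.0}


def test_threshold_proportions_empty_is_error():
    with pytest.raises(ValidationError):
        threshold_proportions([], (0.05,))


def test_concordance_table_hand_tally():
    """20 hand-labelled rows, tallied independently by construction."""
    rows = (
        [ok_row(f"A{i}", 0.02) for i in range(8)]                      # within all
        + [ok_row(f"B{i}", 0.12) for i in range(4)]                    # within 15/20
        + [ok_row("C0", 0.30, "beneficial_to_harmful", "sig_to_nonsig")]
        + [ok_row("C1", 0.30, "beneficial_to_harmful", "nonsig_to_sig")]
        + [ok_row("C2", 0.30, "harmful_to_beneficial", "nonsig_to_sig")]
        + [failed_row(f"D{i}", "rapid_infeasible") for i in range(3)]
        + [failed_row(f"E{i}", "estimation_failed") for i in range(2)]
    )
    table = concordance_table(rows, "mh_fixed", AlphaConfig())
    assert table.n_evaluable == 15
    assert table.n_rapid_infeasible == 3
    assert table.n_estimation_failed == 2
    assert table.prop_within[0.05] == pytest.approx(8 / 15)
    assert table.prop_within[0.15] == pytest.approx(12 / 15)
    assert table.prop_direction_concordant == pytest.approx(12 / 15)
    assert table.discordant_beneficial_to_harmful == pytest.approx(2 / 3)
    assert table.discordant_harmful_to_beneficial == pytest.approx(1 / 3)
    assert table.prop_significance_concordant == pytest.approx(12 / 15)
    assert table.discordant_sig_to_nonsig == pytest.approx(1 / 3)
    assert table.discordant_nonsig_to_sig == pytest.approx(2 / 3)


def test_concordance_all_concordant_leaves_breakdown_absent():
    rows = [ok_row(f"M{i}", 0.01) for i in range(4)]
    table = concordance_table(rows, "mh_fixed")
    assert table.prop_direction_concordant == 1.0
    assert table.discordant_beneficial_to_harmful is None
    assert table.discordant_harmful_to_beneficial is None


def test_concordance_breakdown_half_half():
    rows = [
        ok_row("M1", 0.3, "beneficial_to_harmful"),
        ok_row("M2", 0.3, "harmful_to_beneficial"),
    ]
    table = concordance_table(rows, "mh_fixed")
    assert table.discordant_beneficial_to_harmful == 0.5
    assert table.discordant_harmful_to_beneficial == 0.5


def test_concordance_rejects_mixed_methods():
    rows = [ok_row("M1", 0.01), ok_row("M2", 0.01, method="peto")]
    with pytest.raises(ValidationError):
        concordance_table(rows, "mh_fixed")


def test_event_rate_quartile_split_and_conservation():
    rows = [ok_row(f"M{i}", 0.01, rate=r)
            for i, r in enumerate([0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08])]
    strata = subgroup_by_event_rate(rows, SubgroupSpec())
    counts = {lab: t.n_evaluable for lab, t in strata.items()}
    assert sum(counts.values()) == 8
    assert counts["<=P25"] == 2
    assert counts[">P75"] == 2


def test_event_rate_ties_fall_in_lowest_stratum():
    rows = [ok_row(f"M{i}", 0.01, rate=0.05) for i in range(4)]
    strata = subgroup_by_event_rate(rows, SubgroupSpec())
    assert strata["<=P25"].n_evaluable == 4
    assert strata[">P75"].n_evaluable == 0


def test_i2_boundary_inclusive_low():
    rows = [
        ok_row("M1", 0.01, i2=25.0),
        ok_row("M2", 0.01, i2=0.0),
        ok_row("M3", 0.01, i2=60.0),
        ok_row("M4", 0.01, i2=None),
    ]
    buckets = subgroup_by_i2(rows, SubgroupSpec())
    assert buckets["low"].n_evaluable == 2   # 25.0 is low (boundary inclusive)
    assert buckets["high"].n_evaluable == 1
    assert buckets["unclassified"].n_evaluable == 1


def test_build_report_deterministic_and_conserving():
    rows = (
        [ok_row(f"M{i}", b, rate=0.01 * (i + 1), i2=float(i * 7))
         for i, b in enumerate([0.01, 0.03, 0.08, 0.12, 0.22, 0.04])]
        + [failed_row("F1", "rapid_infeasible"), failed_row("F2", "estimation_failed")]
    )
    cfg = MethodSet(methods=("mh_fixed",))
    report = build_report(rows, cfg)
    table = report.overall["mh_fixed"]
    book = report.bookkeeping["mh_fixed"]
    assert (
        book["n_evaluable"] + book["n_rapid_infeasible"] + book["n_estimation_failed"]
        == book["total"] == 8
    )
    strata = report.by_event_rate["mh_fixed"]
    assert sum(t.n_evaluable for t in strata.values()) == table.n_evaluable
    i2_strata = report.by_i2["mh_fixed"]
    assert sum(t.n_evaluable for t in i2_strata.values()) == table.n_evaluable
    # proportions non-decreasing in threshold
    props = [p for _, p in sorted(table.prop_within.items())]
    assert props == sorted(props)
    # byte-identical regeneration
    assert build_report(rows, cfg).to_json() == report.to_json()


def test_build_report_empty_input():
    report = build_report([], MethodSet(methods=("mh_fixed",)))
    assert report.overall["mh_fixed"].n_evaluable == 0
    assert report.bookkeeping["mh_fixed"]["total"] == 0


def test_comparison_frame_round_trip():
    rows = [ok_row("M1", 0.02), failed_row("M2", "rapid_infeasible"),
            failed_row("M3", "estimation_failed")]
    frame = comparisons_to_frame(rows)
    back = frame_to_comparisons(frame)
    assert back == rows


def test_report_write_emits_expected_files(tmp_path):
    rows = [ok_row(f"M{i}", 0.01 * i) for i in range(6)]
    report = build_report(rows, MethodSet(methods=("mh_fixed",)))
    paths = report.write(tmp_path)
    names = {p.name for p in paths}
    assert names == {"report.json", "concordance_overall.csv",
                     "subgroup_event_rate.csv", "subgroup_i2.csv"}
    for p in paths:
        assert p.exists() and p.stat().st_size > 0
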