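"""ICSR reading, duplicate flagging, eligibility filter, cohort summary."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigisig import (
    CaseReport,
    CohortSummary,
    Provenance,
    ReportSet,
    ValidationError,
    filter_eligible,
    flag_duplicates,
    read_icsr_table,
    summarize_cohort,
    write_icsr_table,
)
from vigisig.ingest import REFERENCE_COHORT

from conftest import make_report


class TestReadIcsrTable:
    def test_multirow_report_folds_into_lists(self, tmp_path):
        f = tmp_path / "icsr.tsv"
        f.write_text(
            "report_id\tage_years\tsex\tdrug_name\tdrug_role\tevent_term\n"
            "r1\t60\tmale\timatinib\tsuspected\thypertension\n"
            "r1\t60\tmale\taspirin\tconcomitant\thypertension\n"
            "r1\t60\tmale\timatinib\tsuspected\t\n"
        )
        rs = read_icsr_table(f)
        assert len(rs) == 1
        r = rs.reports[0]
        assert r.drug_entries == [("imatinib", "suspected"), ("aspirin", "concomitant")]
        assert r.event_terms == ["hypertension"]
        assert rs.provenance.total_read == 1

    def test_empty_file_with_header(self, tmp_path):
        f = tmp_path / "icsr.tsv"
        f.write_text("report_id\tage_years\tsex\tdrug_name\tdrug_role\tevent_term\n")
        rs = read_icsr_table(f)
        assert len(rs) == 0 and rs.provenance.total_read == 0

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        f = tmp_path / "icsr.tsv"
        f.write_text("report_id\tdrug_name\nr1\timatinib\n")
        with pytest.raises(ValidationError, match="missing mandatory column"):
            read_icsr_table(f)

    def test_age_parse_contract(self, tmp_path):
        f = tmp_path / "icsr.tsv"
        f.write_text(
            "report_id\tage_years\tsex\tdrug_name\tdrug_role\tevent_term\n"
            "r1\t45\tmale\t\t\t\n"
            "r2\t\tmale\t\t\t\n"
            "r3\tx\tmale\t\t\t\n"
        )
        rs = read_icsr_table(f)
        ages = [r.age_years for r in rs.reports]
        assert ages == [45, None, None]

    def test_three_file_layout(self, tmp_path):
        (tmp_path / "reports.tsv").write_text(
            "report_id\tage_years\tsex\nr1\t60\tfemale\nr2\t\tmale\n"
        )
        (tmp_path / "drugs.tsv").write_text(
            "report_id\tdrug_name\tdrug_role\nr1\timatinib\tsuspected\n"
        )
        (tmp_path / "events.tsv").write_text(
            "report_id\tevent_term\nr1\thypertension\nr2\tshock\n"
        )
        rs = read_icsr_table(tmp_path)
        assert len(rs) == 2
        assert rs.reports[0].drug_entries == [("imatinib", "suspected")]
        assert rs.reports[1].event_terms == ["shock"]
        assert rs.reports[1].age_years is None

    def test_write_read_roundtrip(self, toy_reports, tmp_path):
        out = tmp_path / "rt.tsv"
        write_icsr_table(toy_reports, out)
        back = read_icsr_table(out)
        assert [r.report_id for r in back] == [r.report_id for r in toy_reports]
        assert [r.drug_entries for r in back] == [r.drug_entries for r in toy_reports]
        assert [r.event_terms for r in back] == [r.event_terms for r in toy_reports]


class TestFlagDuplicates:
    def test_identical_profiles_flagged(self):
        r1 = make_report("a", 50, "male", ["imatinib"], ["shock"])
        r2 = make_report("b", 50, "male", ["imatinib"], ["shock"])
        rs = flag_duplicates(ReportSet([r1, r2], Provenance(total_read=2)))
        assert len(rs) == 1
        assert rs.provenance.duplicates_flagged == 1
        assert rs.reports[0].report_id == "a"  # first kept

    def test_one_term_difference_retains_both(self):
        r1 = make_report("a", 50, "male", ["imatinib"], ["shock"])
        r2 = make_report("b", 50, "male", ["imatinib"], ["shock", "hypoxia"])
        rs = flag_duplicates(ReportSet([r1, r2], Provenance(total_read=2)))
        assert len(rs) == 2 and rs.provenance.duplicates_flagged == 0

    def test_drug_order_is_ignored(self):
        r1 = make_report("a", 50, "male", ["x", "y"], [])
        r2 = make_report("b", 50, "male", ["y", "x"], [])
        rs = flag_duplicates(ReportSet([r1, r2], Provenance(total_read=2)))
        assert len(rs) == 1

    def test_empty_set(self):
        rs = flag_duplicates(ReportSet([], Provenance()))
        assert len(rs) == 0 and rs.provenance.duplicates_flagged == 0


class TestFilterEligible:
    def test_counts(self):
        reports = [
            make_report("a", None, "male"),
            make_report("b", None, "female"),
            make_report("c", 40, None),
            make_report("d", 40, "male"),
            make_report("e", 70, "female"),
        ]
        rs = filter_eligible(ReportSet(reports, Provenance(total_read=5)))
        assert len(rs) == 2
        assert rs.provenance.excluded_missing_age_or_sex == 3
        assert rs.provenance.eligible == 2

    def test_identity_when_all_complete(self, toy_reports):
        rs = filter_eligible(toy_reports)
        assert len(rs) == len(toy_reports)
        assert rs.provenance.eligible == rs.provenance.total_read

    def test_filter_is_a_projection(self, toy_reports):
        once = filter_eligible(toy_reports)
        twice = filter_eligible(once)
        assert [r.report_id for r in twice] == [r.report_id for r in once]
        assert twice.provenance.to_dict() == once.provenance.to_dict()


class TestCohortSummary:
    def test_small_percentages(self):
        reports = [make_report(f"f{i}", 30, "female") for i in range(2)] + [
            make_report(f"m{i}", 70, "male") for i in range(3)
        ]
        s = summarize_cohort(ReportSet(reports, Provenance(total_read=5)))
        assert (s.n_female, s.n_male) == (2, 3)
        assert (s.pct_female, s.pct_male) == (40.0, 60.0)
        assert (s.n_younger, s.n_older) == (2, 3)

    def test_age_65_counts_as_older(self):
        s = summarize_cohort(
            ReportSet([make_report("r", 65, "male")], Provenance(total_read=1))
        )
        assert s.n_older == 1 and s.n_younger == 0

    def test_empty_cohort_percentages_undefined(self):
        s = summarize_cohort(ReportSet([], Provenance()))
        assert s.eligible == 0
        assert s.pct_female is None and s.pct_older is None

    def test_reference_cohort_percentages(self):
        """The published demographic counts reproduce the printed percentages."""
        s = CohortSummary.from_counts(
            REFERENCE_COHORT["n_female"],
            REFERENCE_COHORT["n_male"],
            REFERENCE_COHORT["n_younger"],
            REFERENCE_COHORT["n_older"],
        )
        assert (s.pct_female, s.pct_male) == (60.8, 39.2)
        assert (s.pct_younger, s.pct_older) == (72.5, 27.5)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(
            st.one_of(st.none(), st.integers(min_value=0, max_value=100)),
            st.one_of(st.none(), st.sampled_from(["female", "male"])),
            st.booleans(),  # duplicate the report?
        ),
        max_size=30,
    )
)
def test_provenance_counters_always_reconcile(spec):
    """total_read = duplicates + excluded + eligible after the full chain."""
    reports = []
    for i, (age, sex, dup) in enumerate(spec):
        reports.append(CaseReport(f"r{i}", age, sex, [(f"d{i}", "suspected")], []))
        if dup:
            reports.append(CaseReport(f"r{i}x", age, sex, [(f"d{i}", "suspected")], []))
    rs = ReportSet(reports, Provenance(total_read=len(reports)))
    out = filter_eligible(flag_duplicates(rs))
    p = out.provenance
    assert p.total_read == p.duplicates_flagged + p.excluded_missing_age_or_sex + p.eligible
    assert p.eligible == len(out)
    assert all(r.complete for r in out)
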