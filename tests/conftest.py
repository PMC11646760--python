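import pytest

from vigisig import (
    CaseReport,
    Provenance,
    ReportSet,
    load_drug_panel,
    load_outcome_groups,
)


@pytest.fixture(scope="session")
def panel():
    return load_drug_panel()


@pytest.fixture(scope="session")
def dictionary():
    return load_outcome_groups()


def make_report(rid, age=50, sex="female", drugs=(), events=()):
    entries = [(d, "suspected") if isinstance(d, str) else d for d in drugs]
    return CaseReport(rid, age, sex, entries, list(events))


@pytest.fixture
def toy_reports():
    """Six eligible reports: two with drug+event, one drug-only, one
    event-only, two with neither -> (a, b, c, d) = (2, 1, 1, 2) for
    (imatinib, Hypertension, all).  Exactly one of the drug+event reports
    is female."""
    reports = [
        make_report("r1", 40, "female", ["imatinib"], ["hypertension"]),
        make_report("r2", 70, "male", ["imatinib"], ["hypertension"]),
        make_report("r3", 55, "male", ["imatinib"], []),
        make_report("r4", 30, "female", [], ["hypertension"]),
        make_report("r5", 80, "female", [], []),
        make_report("r6", 25, "male", [], []),
    ]
    return ReportSet(reports, Provenance(total_read=len(reports)))
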