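"""Reading ICSR tables, duplicate flagging, eligibility filtering, cohort summary.

An individual case safety report (ICSR) is one spontaneous adverse-event
report: patient demographics plus the reported drugs (each with a role of
suspected / interacting / concomitant) and coded reaction terms.  The
analysis cohort is built in three steps, with every report accounted for in
the provenance counters:

1. read — fold the row-per-(report, drug, event) TSV into one
   :class:`CaseReport` per report id;
2. deduplicate — drop reports whose full profile (age, sex, sorted drugs,
   sorted events) repeats an earlier report.  Real pharmacovigilance
   databases use probabilistic record linkage for this; that algorithm is
   not publicly specified, so this module substitutes deterministic
   exact-profile matching (documented in docs/methods.md);
3. eligibility — drop reports missing age or sex.  Deduplication runs
   before the missing-data exclusion.

The module also carries the reference cohort sizes of the source database
snapshot (reports through December 2022), used to reproduce the published
eligibility arithmetic and cohort percentages.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ValidationError

log = logging.getLogger(__name__)

VALID_ROLES = ("suspected", "interacting", "concomitant")
VALID_SEXES = ("female", "male")

#: Age (in years) at or above which a patient counts as "older".
AGE_OLDER_MIN = 65
#: Ages outside this closed range are treated as unparseable (missing).
AGE_RANGE = (0, 130)

#: Reference cohort sizes of the source database snapshot (Dec 2022):
#: total reports, reports excluded for missing age/sex, and the Table-3
#: demographic counts of the eligible cohort.  These are published inputs,
#: used for arithmetic checks and to calibrate the simulator's marginals.
REFERENCE_COHORT = {
    "total_reports": 32_520_983,
    "excluded_missing_age_or_sex": 9_339_444,
    "n_female": 14_095_678,
    "n_male": 9_085_861,
    "n_younger": 16_800_356,
    "n_older": 6_381_183,
}

ICSR_COLUMNS = ("report_id", "age_years", "sex", "drug_name", "drug_role", "event_term")


@dataclass(slots=True)
class CaseReport:
    """One spontaneous report.

    ``drug_entries`` is a list of ``(drug_name, role)`` tuples; ``event_terms``
    a list of coded reaction strings.  ``age_years``/``sex`` are ``None`` when
    missing.
    """

    report_id: str
    age_years: int | None
    sex: str | None
    drug_entries: list[tuple[str, str]]
    event_terms: list[str]

    @property
    def complete(self) -> bool:
        return self.age_years is not None and self.sex is not None

    @property
    def older(self) -> bool | None:
        if self.age_years is None:
            return None
        return self.age_years >= AGE_OLDER_MIN

    def drug_names(self, roles: Iterable[str] | None = None) -> set[str]:
        """Lowercased drug names, optionally restricted to the given roles."""
        if roles is None:
            return {d.lower() for d, _ in self.drug_entries}
        allowed = set(roles)
        return {d.lower() for d, r in self.drug_entries if r in allowed}

    def profile_key(self) -> tuple:
        """Duplicate-detection key: demographics plus sorted drugs and events."""
        return (
            self.age_years,
            self.sex,
            tuple(sorted(d.lower() for d, _ in self.drug_entries)),
            tuple(sorted(t.lower() for t in self.event_terms)),
        )


@dataclass
class Provenance:
    """Counters reconciling every report read with its fate."""

    total_read: int = 0
    duplicates_flagged: int = 0
    excluded_missing_age_or_sex: int = 0

    @property
    def eligible(self) -> int:
        return self.total_read - self.duplicates_flagged - self.excluded_missing_age_or_sex

    def to_dict(self) -> dict[str, int]:
        return {
            "total_read": self.total_read,
            "duplicates_flagged": self.duplicates_flagged,
            "excluded_missing_age_or_sex": self.excluded_missing_age_or_sex,
            "eligible": self.eligible,
        }


@dataclass
class ReportSet:
    """A collection of reports plus the provenance of how it was assembled."""

    reports: list[CaseReport] = field(default_factory=list)
    provenance: Provenance = field(default_factory=Provenance)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


@dataclass(frozen=True)
class CohortSummary:
    """Sex and age-class counts of an eligible cohort, with printed-style
    percentages (one decimal, of the eligible total)."""

    n_female: int
    n_male: int
    n_younger: int
    n_older: int

    @property
    def eligible(self) -> int:
        return self.n_female + self.n_male

    @staticmethod
    def _pct(part: int, total: int) -> float | None:
        if total == 0:
            return None
        return round(100.0 * part / total, 1)

    @property
    def pct_female(self) -> float | None:
        return self._pct(self.n_female, self.eligible)

    @property
    def pct_male(self) -> float | None:
        return self._pct(self.n_male, self.eligible)

    @property
    def pct_younger(self) -> float | None:
        return self._pct(self.n_younger, self.n_younger + self.n_older)

    @property
    def pct_older(self) -> float | None:
        return self._pct(self.n_older, self.n_younger + self.n_older)

    @classmethod
    def from_counts(cls, n_female: int, n_male: int, n_younger: int, n_older: int) -> "CohortSummary":
        return cls(n_female, n_male, n_younger, n_older)

    def to_dict(self) -> dict:
        return {
            "n_female": self.n_female,
            "n_male": self.n_male,
            "n_younger": self.n_younger,
            "n_older": self.n_older,
            "pct_female": self.pct_female,
            "pct_male": self.pct_male,
            "pct_younger": self.pct_younger,
            "pct_older": self.pct_older,
        }


def _parse_age(raw: str, report_id: str) -> int | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        age = int(float(raw))
    except ValueError:
        log.warning("report %s: unparseable age %r treated as missing", report_id, raw)
        return None
    if not (AGE_RANGE[0] <= age <= AGE_RANGE[1]):
        log.warning("report %s: age %d outside %s treated as missing", report_id, age, AGE_RANGE)
        return None
    return age


def _parse_sex(raw: str, report_id: str) -> str | None:
    raw = raw.strip().lower()
    if not raw:
        return None
    if raw in VALID_SEXES:
        return raw
    log.warning("report %s: unrecognized sex %r treated as missing", report_id, raw)
    return None


def _read_rows(path: Path, required: tuple[str, ...]) -> tuple[list[dict], list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file without header")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise ValidationError(f"{path}: missing mandatory column(s): {missing}")
        return list(reader), list(reader.fieldnames)


def read_icsr_table(path: str | Path) -> ReportSet:
    """Read an ICSR table into a :class:`ReportSet`.

    ``path`` may be a single long-format TSV (columns ``report_id``,
    ``age_years``, ``sex``, ``drug_name``, ``drug_role``, ``event_term``;
    one row per (report, drug, event) combination; empty string = missing)
    or a directory holding the normalized three-file layout ``reports.tsv``
    / ``drugs.tsv`` / ``events.tsv`` keyed by ``report_id``.

    Rows for the same report id are folded into one report; repeated drugs
    or terms within a report are kept once, in first-seen order.  Rows that
    disagree on demographics keep the first value (logged).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input not found: {path}")

    order: list[str] = []
    demo: dict[str, tuple[int | None, str | None]] = {}
    drugs: dict[str, list[tuple[str, str]]] = {}
    events: dict[str, list[str]] = {}

    def note_demo(rid: str, age_raw: str, sex_raw: str) -> None:
        parsed = (_parse_age(age_raw, rid), _parse_sex(sex_raw, rid))
        if rid not in demo:
            order.append(rid)
            demo[rid] = parsed
            drugs[rid] = []
            events[rid] = []
        elif demo[rid] != parsed and (age_raw.strip() or sex_raw.strip()):
            if parsed != demo[rid]:
                log.warning("report %s: conflicting demographics; keeping first", rid)

    def note_drug(rid: str, name: str, role: str) -> None:
        name = name.strip()
        if not name:
            return
        role = role.strip().lower() or "suspected"
        if role not in VALID_ROLES:
            log.warning("report %s: unknown drug role %r treated as 'suspected'", rid, role)
            role = "suspected"
        entry = (name, role)
        if entry not in drugs[rid]:
            drugs[rid].append(entry)

    def note_event(rid: str, term: str) -> None:
        term = term.strip()
        if term and term not in events[rid]:
            events[rid].append(term)

    if path.is_dir():
        rrows, _ = _read_rows(path / "reports.tsv", ("report_id", "age_years", "sex"))
        for row in rrows:
            note_demo(row["report_id"], row.get("age_years") or "", row.get("sex") or "")
        drows, _ = _read_rows(path / "drugs.tsv", ("report_id", "drug_name"))
        for row in drows:
            rid = row["report_id"]
            if rid in demo:
                note_drug(rid, row.get("drug_name") or "", row.get("drug_role") or "")
            else:
                log.warning("drugs.tsv: report id %s absent from reports.tsv; row dropped", rid)
        erows, _ = _read_rows(path / "events.tsv", ("report_id", "event_term"))
        for row in erows:
            rid = row["report_id"]
            if rid in demo:
                note_event(rid, row.get("event_term") or "")
            else:
                log.warning("events.tsv: report id %s absent from reports.tsv; row dropped", rid)
    else:
        rows, _ = _read_rows(path, ICSR_COLUMNS[:3])
        for row in rows:
            rid = row["report_id"]
            note_demo(rid, row.get("age_years") or "", row.get("sex") or "")
            note_drug(rid, row.get("drug_name") or "", row.get("drug_role") or "")
            note_event(rid, row.get("event_term") or "")

    reports = [
        CaseReport(rid, demo[rid][0], demo[rid][1], drugs[rid], events[rid])
        for rid in order
    ]
    return ReportSet(reports, Provenance(total_read=len(reports)))


def flag_duplicates(rs: ReportSet) -> ReportSet:
    """Drop exact-profile duplicates, keeping the first occurrence.

    Two reports are duplicates when age, sex, the sorted drug-name list and
    the sorted event-term list all coincide; report ids are ignored.
    """
    seen: set[tuple] = set()
    kept: list[CaseReport] = []
    flagged = 0
    for r in rs.reports:
        key = r.profile_key()
        if key in seen:
            flagged += 1
        else:
            seen.add(key)
            kept.append(r)
    prov = Provenance(
        total_read=rs.provenance.total_read,
        duplicates_flagged=rs.provenance.duplicates_flagged + flagged,
        excluded_missing_age_or_sex=rs.provenance.excluded_missing_age_or_sex,
    )
    return ReportSet(kept, prov)


def filter_eligible(rs: ReportSet) -> ReportSet:
    """Retain reports with both age and sex present (idempotent projection)."""
    kept = [r for r in rs.reports if r.complete]
    prov = Provenance(
        total_read=rs.provenance.total_read,
        duplicates_flagged=rs.provenance.duplicates_flagged,
        excluded_missing_age_or_sex=rs.provenance.excluded_missing_age_or_sex
        + (len(rs.reports) - len(kept)),
    )
    return ReportSet(kept, prov)


def summarize_cohort(rs: ReportSet) -> CohortSummary:
    """Sex / age-class counts and percentages of an eligible-filtered set."""
    n_female = n_male = n_younger = n_older = 0
    for r in rs.reports:
        if not r.complete:
            raise ValidationError(
                "summarize_cohort expects an eligible-filtered ReportSet "
                f"(report {r.report_id} has missing demographics)"
            )
        if r.sex == "female":
            n_female += 1
        else:
            n_male += 1
        if r.older:
            n_older += 1
        else:
            n_younger += 1
    return CohortSummary(n_female, n_male, n_younger, n_older)


def write_icsr_table(rs: ReportSet, path: str | Path | None = None) -> str:
    """Serialize to the long-format TSV; returns the text (and writes it
    to ``path`` when given).  Re-reading yields the same reports."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(ICSR_COLUMNS)
    for r in rs.reports:
        age = "" if r.age_years is None else str(r.age_years)
        sex = r.sex or ""
        n_rows = max(len(r.drug_entries), len(r.event_terms), 1)
        for i in range(n_rows):
            drug, role = r.drug_entries[i] if i < len(r.drug_entries) else ("", "")
            term = r.event_terms[i] if i < len(r.event_terms) else ""
            writer.writerow([r.report_id, age, sex, drug, role, term])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
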