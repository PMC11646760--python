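"""Drug panel and outcome dictionary: loading, validation, and term mapping.

The package ships two versioned config files under ``vigisig/data``:

* ``tki_panel.tsv`` — the 35 FDA-approved tyrosine-kinase inhibitors under
  study, each assigned to one of eight target classes (EGFR, HER2, VEGFR,
  FGFR, BCR-ABL, ALK, JAK, BTK), with an optional synonym list and the
  reference report count used to calibrate simulated exposure frequencies.
* ``outcome_groups.json`` — 21 cardiovascular adverse-event groups, each a
  set of lowercase coded reaction terms.  MedDRA is licensed and cannot be
  redistributed, so the shipped term lists are synthetic stand-ins that
  preserve the group structure (see the file's own comment field).

Matching is deliberately dumb: case-insensitive exact match plus the explicit
synonym table.  No fuzzy matching, so every mapping decision is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ValidationError

log = logging.getLogger(__name__)

#: The eight kinase-target classes a panel entry may belong to.
DRUG_CLASSES: tuple[str, ...] = (
    "EGFR", "HER2", "VEGFR", "FGFR", "BCR-ABL", "ALK", "JAK", "BTK",
)


def _default_data(name: str):
    return resources.files("vigisig.data").joinpath(name)


@dataclass(frozen=True)
class DrugPanelEntry:
    """One drug in the panel.

    ``reference_reports`` is the number of reports mentioning the drug in the
    reference database snapshot; the simulator uses it to set realistic
    per-drug exposure marginals.  It plays no role in the statistics.
    """

    name: str
    drug_class: str
    reference_reports: int | None = None


@dataclass
class DrugPanel:
    """The validated drug panel plus its alias table."""

    entries: tuple[DrugPanelEntry, ...]
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise ValidationError(f"duplicate canonical drug name: {n!r}")
            seen.add(n)
        for e in self.entries:
            if e.drug_class not in DRUG_CLASSES:
                raise ValidationError(
                    f"unknown drug class {e.drug_class!r} for {e.name!r}; "
                    f"allowed: {', '.join(DRUG_CLASSES)}"
                )
        for alias, canon in self.synonyms.items():
            if canon not in seen:
                raise ValidationError(
                    f"synonym {alias!r} points at unknown canonical name {canon!r}"
                )
            if alias in seen:
                raise ValidationError(
                    f"synonym {alias!r} collides with a canonical name"
                )
        lookup = {e.name: e.name for e in self.entries}
        lookup.update(self.synonyms)
        self._lookup = lookup
        self._class_of = {e.name: e.drug_class for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: object) -> bool:
        return isinstance(name, str) and self.resolve(name) is not None

    @property
    def names(self) -> tuple[str, ...]:
        """Canonical drug names in panel (class-block) order."""
        return tuple(e.name for e in self.entries)

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct classes in order of first appearance."""
        out: list[str] = []
        for e in self.entries:
            if e.drug_class not in out:
                out.append(e.drug_class)
        return tuple(out)

    def resolve(self, name: str) -> str | None:
        """Map a raw drug string to its canonical name, or None."""
        return self._lookup.get(name.strip().lower())

    def class_of(self, name: str) -> str:
        canon = self.resolve(name)
        if canon is None:
            raise ValidationError(f"drug {name!r} not in panel")
        return self._class_of[canon]

    def exposure_marginals(self, total_reports: int) -> dict[str, float]:
        """Per-drug exposure probabilities proportional to the reference counts."""
        out: dict[str, float] = {}
        for e in self.entries:
            if e.reference_reports is None:
                raise ValidationError(
                    f"panel entry {e.name!r} has no reference report count"
                )
            out[e.name] = e.reference_reports / total_reports
        return out


@dataclass(frozen=True)
class OutcomeGroup:
    """One adverse-event group: an ordered, duplicate-free term tuple.

    The first term is the group's *primary* term (what the simulator emits);
    terms may be shared between groups, but the primary term should be unique
    to its group.
    """

    name: str
    terms: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError(f"outcome group {self.name!r} has an empty term set")
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError(f"outcome group {self.name!r} lists a term twice")

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.terms)


@dataclass
class OutcomeDictionary:
    """All outcome groups plus a reverse term -> groups index.

    A term may belong to several groups (e.g. intracranial bleeding sits in
    both the clinical-hemorrhage and cerebral-hemorrhage groups); mapping a
    report returns *every* matching group.
    """

    groups: tuple[OutcomeGroup, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if g.name in seen:
                raise ValidationError(f"duplicate outcome group name: {g.name!r}")
            seen.add(g.name)
        index: dict[str, tuple[str, ...]] = {}
        for g in self.groups:
            for t in g.terms:
                index[t] = index.get(t, ()) + (g.name,)
        self._term_index = index

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, name: object) -> bool:
        return any(g.name == name for g in self.groups)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    @property
    def term_index(self) -> Mapping[str, tuple[str, ...]]:
        return self._term_index

    def group(self, name: str) -> OutcomeGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise ValidationError(f"outcome group {name!r} not in dictionary")

    def map_terms(self, terms: Iterable[str]) -> set[str]:
        """Groups whose term set intersects ``terms``; unknown terms map nowhere."""
        hit: set[str] = set()
        unknown = 0
        for t in terms:
            groups = self._term_index.get(t.strip().lower())
            if groups is None:
                unknown += 1
            else:
                hit.update(groups)
        if unknown:
            log.debug("map_terms: %d term(s) matched no outcome group", unknown)
        return hit


def load_drug_panel(path: str | Path | None = None) -> DrugPanel:
    """Load and validate a drug panel TSV.

    Columns: ``canonical_name``, ``class``, ``synonyms`` (pipe-separated,
    may be empty), optional ``reference_reports``.  With ``path=None`` the
    shipped 35-drug panel is loaded.
    """
    src = _default_data("tki_panel.tsv") if path is None else Path(path)
    try:
        text = src.read_text(encoding="utf-8")
    except FileNotFoundError as e:
        raise ValidationError(f"panel file not found: {src}") from e

    lines = text.splitlines()
    if not lines:
        raise ValidationError(f"{src}: empty panel file")
    header = lines[0].rstrip("\n").split("\t")
    required = {"canonical_name", "class"}
    if not required.issubset(header):
        raise ValidationError(
            f"{src}: line 1: header must contain {sorted(required)}, got {header}"
        )
    col = {name: i for i, name in enumerate(header)}

    entries: list[DrugPanelEntry] = []
    synonyms: dict[str, str] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{src}: line {lineno}: expected tab-separated fields")
        try:
            name = parts[col["canonical_name"]].strip().lower()
            drug_class = parts[col["class"]].strip()
        except IndexError as e:
            raise ValidationError(f"{src}: line {lineno}: missing mandatory field") from e
        if not name:
            raise ValidationError(f"{src}: line {lineno}: empty canonical_name")
        ref: int | None = None
        if "reference_reports" in col and len(parts) > col["reference_reports"]:
            ref_raw = parts[col["reference_reports"]].strip().replace(",", "")
            if ref_raw:
                try:
                    ref = int(ref_raw)
                except ValueError as e:
                    raise ValidationError(
                        f"{src}: line {lineno}: bad reference_reports {ref_raw!r}"
                    ) from e
        entries.append(DrugPanelEntry(name, drug_class, ref))
        if "synonyms" in col and len(parts) > col["synonyms"]:
            for alias in parts[col["synonyms"]].split("|"):
                alias = alias.strip().lower()
                if alias:
                    synonyms[alias] = name
    return DrugPanel(tuple(entries), synonyms)


def load_outcome_groups(path: str | Path | None = None) -> OutcomeDictionary:
    """Load and validate an outcome dictionary JSON.

    Accepted layouts: ``{group: [terms...]}`` or
    ``{"groups": {group: {"terms": [...], "source": "..."}}}`` (the shipped
    file uses the latter).  With ``path=None`` the shipped 21-group mock
    dictionary is loaded.
    """
    src = _default_data("outcome_groups.json") if path is None else Path(path)
    try:
        payload = json.loads(src.read_text(encoding="utf-8"))
    except FileNotFoundError as e:
        raise ValidationError(f"outcome dictionary not found: {src}") from e
    except json.JSONDecodeError as e:
        raise ValidationError(f"{src}: invalid JSON: {e}") from e

    if "groups" in payload and isinstance(payload["groups"], dict):
        raw_groups = payload["groups"]
    else:
        raw_groups = {k: v for k, v in payload.items() if not k.startswith("_")}

    groups: list[OutcomeGroup] = []
    for name, spec in raw_groups.items():
        if isinstance(spec, dict):
            terms = spec.get("terms", [])
            source = spec.get("source", "")
        else:
            terms, source = spec, ""
        if not isinstance(terms, list):
            raise ValidationError(f"{src}: group {name!r}: terms must be a list")
        groups.append(
            OutcomeGroup(name, tuple(t.strip().lower() for t in terms), source)
        )
    return OutcomeDictionary(tuple(groups))


def map_report_events(report, dictionary: OutcomeDictionary) -> set[str]:
    """All outcome groups whose term set intersects the report's event terms.

    Unknown terms are ignored (tallied at debug log level).  The result only
    depends on the *set* of terms, so it is idempotent and order-independent.
    """
    return dictionary.map_terms(report.event_terms)
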