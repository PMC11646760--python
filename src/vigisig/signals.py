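"""Heatmap-style classification of per-cell statistics into signal categories.

Each (drug, group, stratum) cell receives exactly one ordinal category,
mirroring the published heatmap legend:

* ``NO_REPORTS`` ('-') — the drug has no reports at all in the stratum
  (a + b = 0);
* ``FEW_CASES`` (white) — fewer than ``n_min`` co-reports, too few to assess;
* red side (ROR > 1): ``ELEVATED_NS`` (light red, not significant),
  ``SIGNAL`` (dark red, P < 0.01) and ``STRONG_SIGNAL`` (darkest red,
  P < 0.001).  The two dark reds together are the *significant* signals;
  the 0.001 sub-boundary between them is cosmetic and configurable;
* green side (ROR <= 1): ``NULL_SIGNAL`` (dark green, P < 0.01 — enough
  cases, clearly no excess) and ``INSUFFICIENT`` (light green).

A drug is *significant* in a stratum when its aggregate-cardiotoxicity cell
(event = membership in any outcome group) is SIGNAL or STRONG_SIGNAL; an
any-group criterion is available as an alternative.  IC025 travels alongside
every cell as a confirmatory second channel but never gates the category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

from .contingency import AGGREGATE_GROUP, ContingencyTable
from .errors import ValidationError
from .stats import ICResult, RORResult
from .vocab import DrugPanel

log = logging.getLogger(__name__)


class Category(IntEnum):
    """Ordinal heatmap category; higher rank = stronger elevation."""

    NO_REPORTS = 0      # '-' : no reports of the drug in the stratum
    FEW_CASES = 1       # white : a < n_min co-reports
    INSUFFICIENT = 2    # light green
    NULL_SIGNAL = 3     # dark green : ROR <= 1, P < 0.01
    ELEVATED_NS = 4     # light red : ROR > 1, not significant
    SIGNAL = 5          # dark red : ROR > 1, P < 0.01
    STRONG_SIGNAL = 6   # darkest red : ROR > 1, P < 0.001


SIGNIFICANT_CATEGORIES = (Category.SIGNAL, Category.STRONG_SIGNAL)


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds.

    ``n_min`` is the minimum observed co-report count to attempt
    classification (the common pharmacovigilance screening minimum of 3);
    the P boundaries give the strong/significant/elevated split.
    """

    n_min: int = 3
    p_strong: float = 0.001
    p_signal: float = 0.01
    p_elevated: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p_strong <= self.p_signal <= self.p_elevated < 1):
            raise ValidationError("thresholds must satisfy 0 < strong <= signal <= elevated < 1")
        if self.n_min < 0:
            raise ValidationError("n_min must be non-negative")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class HeatmapCell:
    """One classified cell plus the counts/statistics that produced it."""

    drug: str
    group: str
    stratum: str
    category: Category
    a: int = 0
    ror: float = math.nan
    p_fisher: float = 1.0
    ic025: float = math.nan


def classify_cell(
    ror_result: RORResult,
    ic_result: ICResult | None,
    table: ContingencyTable,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> HeatmapCell:
    """Deterministic, total classification of one cell.

    Rule order: no reports -> few cases -> red side by P -> green side by P.
    An undefined ROR with enough cases (a zero comparator or complement
    cell) is classified by P alone on the red side, with a logged caveat.
    """
    p = ror_result.p_fisher
    ror = ror_result.ror
    ic025 = ic_result.ic025 if ic_result is not None else math.nan

    def cell(cat: Category) -> HeatmapCell:
        return HeatmapCell(
            drug=table.drug, group=table.group, stratum=table.stratum,
            category=cat, a=table.a, ror=ror, p_fisher=p, ic025=ic025,
        )

    if table.n_exposed == 0:
        return cell(Category.NO_REPORTS)
    if table.a < thresholds.n_min:
        return cell(Category.FEW_CASES)

    elevated = ror > 1.0
    if math.isnan(ror):
        log.warning(
            "cell (%s, %s, %s): undefined ROR with a=%d >= n_min; classifying by P alone",
            table.drug, table.group, table.stratum, table.a,
        )
        elevated = True
    if elevated:
        if p < thresholds.p_strong:
            return cell(Category.STRONG_SIGNAL)
        if p < thresholds.p_signal:
            return cell(Category.SIGNAL)
        return cell(Category.ELEVATED_NS)
    if p < thresholds.p_signal:
        return cell(Category.NULL_SIGNAL)
    return cell(Category.INSUFFICIENT)


@dataclass
class SignalTable:
    """All classified cells, addressable by (drug, group, stratum)."""

    cells: list[HeatmapCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str, str], HeatmapCell] = {
            (c.drug, c.group, c.stratum): c for c in self.cells
        }

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, drug: str, group: str, stratum: str) -> HeatmapCell | None:
        return self._index.get((drug, group, stratum))

    def drugs(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.cells:
            if c.drug not in out:
                out.append(c.drug)
        return tuple(out)

    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.cells:
            if c.group not in out:
                out.append(c.group)
        return tuple(out)

    def strata(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.cells:
            if c.stratum not in out:
                out.append(c.stratum)
        return tuple(out)


def build_signal_table(
    stats_frame,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> SignalTable:
    """Classify every row of an :func:`vigisig.stats.attach_statistics` frame."""
    cells = []
    for row in stats_frame.itertuples(index=False):
        t = ContingencyTable(
            a=int(row.a), b=int(row.b), c=int(row.c), d=int(row.d),
            drug=row.drug, group=row.group, stratum=row.stratum,
        )
        rr = RORResult(row.ror, getattr(row, "ci_low", math.nan),
                       getattr(row, "ci_high", math.nan), row.p_fisher)
        ic = ICResult(getattr(row, "ic", math.nan), getattr(row, "ic025", math.nan),
                      getattr(row, "expected", math.nan))
        cells.append(classify_cell(rr, ic, t, thresholds))
    return SignalTable(cells)


def detect_signals(
    st: SignalTable,
    stratum: str = "all",
    criterion: str = "aggregate",
    panel: DrugPanel | None = None,
) -> list[str]:
    """Drugs with a significant signal in the stratum, in panel order.

    ``criterion="aggregate"`` (default) looks only at the aggregate
    cardiotoxicity cell; ``criterion="any-group"`` flags a drug whose *any*
    outcome-group cell is significant.
    """
    if criterion not in ("aggregate", "any-group"):
        raise ValidationError(f"unknown signal criterion {criterion!r}")
    drugs = panel.names if panel is not None else st.drugs()
    out: list[str] = []
    for drug in drugs:
        if criterion == "aggregate":
            c = st.cell(drug, AGGREGATE_GROUP, stratum)
            hit = c is not None and c.category in SIGNIFICANT_CATEGORIES
        else:
            hit = any(
                c.category in SIGNIFICANT_CATEGORIES
                for c in st.cells
                if c.drug == drug and c.stratum == stratum and c.group != AGGREGATE_GROUP
            )
        if hit:
            out.append(drug)
    return out


@dataclass(frozen=True)
class Discordance:
    """A (drug, group) cell that is significant in one stratum but not the
    paired stratum."""

    drug: str
    group: str
    kind: str                 # "<stratum>-only" or "no reports in comparator"
    significant_in: str
    category_a: Category
    category_b: Category


def compare_strata(
    st: SignalTable,
    pair: tuple[str, str],
) -> list[Discordance]:
    """Signal discordances between two classified strata.

    Emits one record per (drug, group) where exactly one stratum shows a
    significant signal; when the non-significant side has no reports at all
    the kind is ``"no reports in comparator"``.
    """
    s_a, s_b = pair
    keys = sorted(
        {(c.drug, c.group) for c in st.cells if c.stratum in (s_a, s_b)}
    )
    out: list[Discordance] = []
    for drug, group in keys:
        ca = st.cell(drug, group, s_a)
        cb = st.cell(drug, group, s_b)
        if ca is None or cb is None:
            continue
        sig_a = ca.category in SIGNIFICANT_CATEGORIES
        sig_b = cb.category in SIGNIFICANT_CATEGORIES
        if sig_a == sig_b:
            continue
        hit, other = (s_a, cb) if sig_a else (s_b, ca)
        kind = (
            "no reports in comparator"
            if other.category is Category.NO_REPORTS
            else f"{hit}-only"
        )
        out.append(
            Discordance(
                drug=drug, group=group, kind=kind, significant_in=hit,
                category_a=ca.category, category_b=cb.category,
            )
        )
    return out


def signal_summary(
    st: SignalTable,
    panel: DrugPanel | None = None,
    criterion: str = "aggregate",
    pairs: Iterable[tuple[str, str]] = (("female", "male"), ("younger", "older")),
) -> Mapping:
    """JSON-ready summary: significant drugs per stratum plus discordances."""
    strata = st.strata()
    summary = {
        "significant_drugs": {
            s: detect_signals(st, s, criterion=criterion, panel=panel) for s in strata
        },
        "discordances": {},
    }
    for pair in pairs:
        if pair[0] in strata and pair[1] in strata:
            summary["discordances"]["/".join(pair)] = [
                {
                    "drug": d.drug, "group": d.group, "kind": d.kind,
                    "significant_in": d.significant_in,
                    "categories": [d.category_a.name, d.category_b.name],
                }
                for d in compare_strata(st, pair)
            ]
    return summary
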