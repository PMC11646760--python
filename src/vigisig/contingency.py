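"""Stratified 2x2 contingency tables for drug x outcome-group pairs.

For a drug D and outcome group G within a stratum, eligible reports are
cross-classified into the classic four cells:

    a — reports mentioning D with at least one term in G
    b — reports mentioning D without a term in G
    c — reports without D but with a term in G
    d — reports with neither

The unit of counting is the *report*: a report counts once no matter how many
matching drug entries or terms it lists.  The comparator (c, d) is every
other eligible report in the stratum, i.e. the full case/non-case background,
not a restriction to other panel drugs.

Five strata are shipped: all, female, male, younger (<65), older (>=65).
Because the sex pair and the age pair each partition the cohort, their cell
counts sum exactly to the all-stratum cells — a property the test suite
asserts on every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import UnknownDrugError, UnknownGroupError
from .ingest import AGE_OLDER_MIN, ReportSet
from .vocab import DrugPanel, OutcomeDictionary

#: Name of the synthetic aggregate outcome row: membership in ANY group.
AGGREGATE_GROUP = "Cardiotoxicity"


@dataclass(frozen=True)
class StratumSpec:
    """A demographic stratum: a sex filter and/or an age-class filter."""

    label: str
    sex_filter: str = "any"      # female | male | any
    age_filter: str = "any"      # younger | older | any

    def __post_init__(self) -> None:
        if self.sex_filter not in ("female", "male", "any"):
            raise ValueError(f"bad sex_filter {self.sex_filter!r}")
        if self.age_filter not in ("younger", "older", "any"):
            raise ValueError(f"bad age_filter {self.age_filter!r}")


STRATUM_ALL = StratumSpec("all")
STRATUM_FEMALE = StratumSpec("female", sex_filter="female")
STRATUM_MALE = StratumSpec("male", sex_filter="male")
STRATUM_YOUNGER = StratumSpec("younger", age_filter="younger")
STRATUM_OLDER = StratumSpec("older", age_filter="older")

DEFAULT_STRATA: tuple[StratumSpec, ...] = (
    STRATUM_ALL, STRATUM_FEMALE, STRATUM_MALE, STRATUM_YOUNGER, STRATUM_OLDER,
)


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d report counts for one (drug, group, stratum) cell."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    group: str = ""
    stratum: str = "all"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_events(self) -> int:
        return self.a + self.c

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


class CohortIndex:
    """Boolean indicator arrays over a report set, built once and queried per
    (drug, group, stratum).

    Drug names resolve through the panel (case-insensitive + synonyms) and
    may be restricted to a subset of drug roles; event terms resolve through
    the dictionary's term index.  Reports carrying unknown drugs or terms
    simply contribute nothing to those indicators.
    """

    def __init__(
        self,
        rs: ReportSet,
        panel: DrugPanel,
        dictionary: OutcomeDictionary,
        roles: Iterable[str] | None = None,
    ) -> None:
        self.panel = panel
        self.dictionary = dictionary
        n = len(rs.reports)
        self.n = n
        drug_pos = {name: i for i, name in enumerate(panel.names)}
        group_pos = {name: j for j, name in enumerate(dictionary.names)}
        self._drug_pos = drug_pos
        self._group_pos = group_pos

        D = np.zeros((n, len(drug_pos)), dtype=bool)
        G = np.zeros((n, len(group_pos)), dtype=bool)
        female = np.zeros(n, dtype=bool)
        older = np.zeros(n, dtype=bool)

        resolve = panel.resolve
        term_index = dictionary.term_index
        allowed = set(roles) if roles is not None else None
        for i, r in enumerate(rs.reports):
            for dname, role in r.drug_entries:
                if allowed is not None and role not in allowed:
                    continue
                canon = resolve(dname)
                if canon is not None:
                    D[i, drug_pos[canon]] = True
            for term in r.event_terms:
                hit = term_index.get(term.strip().lower())
                if hit:
                    for gname in hit:
                        G[i, group_pos[gname]] = True
            if r.sex == "female":
                female[i] = True
            if r.age_years is not None and r.age_years >= AGE_OLDER_MIN:
                older[i] = True

        self.D = D
        self.G = G
        self.any_group = G.any(axis=1)
        self.female = female
        self.older = older

    def stratum_mask(self, stratum: StratumSpec) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        if stratum.sex_filter == "female":
            mask &= self.female
        elif stratum.sex_filter == "male":
            mask &= ~self.female
        if stratum.age_filter == "older":
            mask &= self.older
        elif stratum.age_filter == "younger":
            mask &= ~self.older
        return mask

    def _group_col(self, group: str) -> np.ndarray:
        if group == AGGREGATE_GROUP:
            return self.any_group
        if group not in self._group_pos:
            raise UnknownGroupError(group)
        return self.G[:, self._group_pos[group]]

    def table(self, drug: str, group: str, stratum: StratumSpec) -> ContingencyTable:
        canon = self.panel.resolve(drug)
        if canon is None:
            raise UnknownDrugError(drug)
        de = self.D[:, self._drug_pos[canon]]
        ev = self._group_col(group)
        m = self.stratum_mask(stratum)
        a = int(np.count_nonzero(de & ev & m))
        ab = int(np.count_nonzero(de & m))
        ev_n = int(np.count_nonzero(ev & m))
        n = int(np.count_nonzero(m))
        return ContingencyTable(
            a=a, b=ab - a, c=ev_n - a, d=n - ab - ev_n + a,
            drug=canon, group=group, stratum=stratum.label,
        )


def build_2x2(
    rs: ReportSet,
    drug: str,
    group: str,
    stratum: StratumSpec,
    dictionary: OutcomeDictionary,
    panel: DrugPanel,
    roles: Iterable[str] | None = None,
) -> ContingencyTable:
    """Build a single stratified 2x2 table (convenience wrapper; for sweeps
    construct one :class:`CohortIndex` and query it repeatedly)."""
    return CohortIndex(rs, panel, dictionary, roles).table(drug, group, stratum)


def build_all(
    rs: ReportSet,
    panel: DrugPanel,
    dictionary: OutcomeDictionary,
    strata: Sequence[StratumSpec] = DEFAULT_STRATA,
    roles: Iterable[str] | None = None,
    include_aggregate: bool = False,
) -> list[ContingencyTable]:
    """All |panel| x |groups| x |strata| tables, in deterministic order
    (panel order, then dictionary order, then stratum order).

    With ``include_aggregate=True`` an extra aggregate outcome row (event =
    membership in any group) is prepended to each drug's group sweep.
    """
    index = CohortIndex(rs, panel, dictionary, roles)
    group_names = list(dictionary.names)
    if include_aggregate:
        group_names = [AGGREGATE_GROUP] + group_names

    # Count via matrix products per stratum instead of per-cell masking.
    Df = index.D.astype(np.int64)
    cols = [index._group_col(g) for g in group_names]
    Gf = np.column_stack(cols).astype(np.int64)

    out: list[ContingencyTable] = []
    per_stratum: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
    for stratum in strata:
        m = index.stratum_mask(stratum)
        Dm = Df[m]
        Gm = Gf[m]
        A = Dm.T @ Gm                         # co-report counts
        drug_n = Dm.sum(axis=0)
        ev_n = Gm.sum(axis=0)
        per_stratum[stratum.label] = (A, drug_n, ev_n, int(m.sum()))

    for i, drug in enumerate(panel.names):
        for j, group in enumerate(group_names):
            for stratum in strata:
                A, drug_n, ev_n, n = per_stratum[stratum.label]
                a = int(A[i, j])
                ab = int(drug_n[i])
                evn = int(ev_n[j])
                out.append(
                    ContingencyTable(
                        a=a, b=ab - a, c=evn - a, d=n - ab - evn + a,
                        drug=drug, group=group, stratum=stratum.label,
                    )
                )
    return out


def tables_to_frame(tables: Sequence[ContingencyTable], panel: DrugPanel | None = None):
    """Long-format DataFrame (drug, class, group, stratum, a, b, c, d)."""
    import pandas as pd

    rows = []
    for t in tables:
        rows.append(
            {
                "drug": t.drug,
                "class": panel.class_of(t.drug) if panel is not None else "",
                "group": t.group,
                "stratum": t.stratum,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            }
        )
    return pd.DataFrame(rows)
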