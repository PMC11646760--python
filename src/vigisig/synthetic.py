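"""Synthetic spontaneous-report generator with planted drug-event signals.

The real source database is fee-gated, so every pipeline stage is exercised
on simulated individual case safety reports with known ground truth.  The
generative model, per report:

* sex ~ Bernoulli(``sex_split`` female), age from a mixture of uniform
  integer blocks (defaults emulate the published cohort: 60.8% female,
  72.5% under 65);
* independent Bernoulli exposure to each panel drug at its marginal
  probability (defaults proportional to the published per-drug report
  counts), each exposure carrying a suspected/interacting/concomitant role;
* 1-3 background concomitant medications drawn from a large name pool and
  occasional unmapped reaction terms.  These high-cardinality fields keep
  report profiles near-unique, as in real data, so that exact-profile
  deduplication removes only true copies;
* per outcome group, an event indicator with baseline probability p0.  For
  a planted signal (drug, group, theta), exposed reports instead use
  p1 = theta' * odds0 / (1 + theta' * odds0) where odds0 = p0 / (1 - p0)
  and theta' is theta times any sex/age stratum modifiers — i.e. the
  planted theta IS the report-level odds ratio against the all-other-
  reports comparator, the exact estimand of the ROR;
* events serialize as the group's primary coded term; missingness masks and
  appended exact duplicates are applied last.

Ground truth carries the planted list plus closed-form expected a/b/c/d
cells per stratum, so parameter recovery is a sharp test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contingency import DEFAULT_STRATA, StratumSpec
from .errors import ValidationError
from .ingest import AGE_OLDER_MIN, CaseReport, Provenance, ReportSet
from .vocab import DrugPanel, OutcomeDictionary, load_drug_panel, load_outcome_groups

log = logging.getLogger(__name__)

#: Eligible-cohort size of the reference database snapshot; divides the
#: published per-drug report counts into exposure probabilities.
REFERENCE_ELIGIBLE = 23_181_539

#: Baseline per-report probability of each outcome group (the simulator's
#: stand-in for how often each cardiovascular event family appears in
#: spontaneous reports; chosen once as plausible screening-scale rates).
PAPER_LIKE_GROUP_RATES: Mapping[str, float] = {
    "Hypertension": 0.035,
    "Arterial embolism and thrombosis": 0.015,
    "Myocardial infarction": 0.015,
    "Central nervous system ischemia": 0.012,
    "Bradyarrhythmias": 0.010,
    "Endocardial disorders": 0.001,
    "Supraventricular tachyarrhythmias": 0.020,
    "Ventricular tachyarrhythmias": 0.008,
    "Cardiomyopathy": 0.012,
    "Respiratory failure": 0.020,
    "Heart failure": 0.030,
    "Shock": 0.010,
    "Myocarditis": 0.003,
    "Pericarditis": 0.005,
    "Venous embolism and thrombosis": 0.025,
    "Hemorrhage (clinical events)": 0.040,
    "Bleeding-related laboratory abnormalities": 0.008,
    "Cerebral hemorrhage": 0.010,
    "Pulmonary hypertension": 0.003,
    "Vasculitis": 0.002,
    "Temporal arteritis/Polymyalgia rheumatica": 0.002,
}


@dataclass(frozen=True)
class PlantedSignal:
    """One planted drug-event association.

    ``odds_ratio`` is the report-level odds ratio among exposed reports;
    ``stratum_modifiers`` multiplies it within demographic strata, keyed by
    any of female/male/younger/older (absent keys mean x1).
    """

    drug: str
    group: str
    odds_ratio: float
    stratum_modifiers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ValidationError(
                f"planted ({self.drug}, {self.group}): odds ratio must be > 0"
            )
        bad = set(self.stratum_modifiers) - {"female", "male", "younger", "older"}
        if bad:
            raise ValidationError(
                f"planted ({self.drug}, {self.group}): unknown stratum key(s) {sorted(bad)}"
            )
        if any(m <= 0 for m in self.stratum_modifiers.values()):
            raise ValidationError(
                f"planted ({self.drug}, {self.group}): modifiers must be > 0"
            )

    def modifier(self, sex: str, older: bool) -> float:
        m = self.stratum_modifiers.get(sex, 1.0)
        m *= self.stratum_modifiers.get("older" if older else "younger", 1.0)
        return m


@dataclass(frozen=True)
class AgeBlock:
    """A mixture component of the age distribution (closed integer range)."""

    proportion: float
    low: int
    high: int

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high <= 130):
            raise ValidationError(f"age block range [{self.low}, {self.high}] invalid")
        if self.proportion < 0:
            raise ValidationError("age block proportion must be >= 0")

    @property
    def frac_older(self) -> float:
        """Fraction of this block's (uniform) ages that are >= 65."""
        n = self.high - self.low + 1
        n_old = max(0, self.high - max(self.low, AGE_OLDER_MIN) + 1)
        return n_old / n


@dataclass
class SyntheticConfig:
    """Full parameterization of the report generator."""

    n_reports: int
    seed: int = 0
    sex_split: float = 0.608
    age_blocks: tuple[AgeBlock, ...] = (
        AgeBlock(0.725, 18, 64),
        AgeBlock(0.275, 65, 95),
    )
    missing_age_frac: float = 0.0
    missing_sex_frac: float = 0.0
    duplicate_frac: float = 0.0
    drug_marginals: Mapping[str, float] = field(default_factory=dict)
    group_marginals: Mapping[str, float] = field(default_factory=dict)
    planted: tuple[PlantedSignal, ...] = ()
    role_probs: tuple[float, float, float] = (0.85, 0.05, 0.10)
    background_drug_pool: int = 200_000
    background_drugs_min: int = 1
    background_drugs_max: int = 3
    background_term_pool: int = 2_000
    background_term_rate: float = 0.4

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValidationError("n_reports must be positive")
        for name, v in [
            ("sex_split", self.sex_split),
            ("missing_age_frac", self.missing_age_frac),
            ("missing_sex_frac", self.missing_sex_frac),
            ("duplicate_frac", self.duplicate_frac),
        ]:
            if not (0 <= v < 1):
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if abs(sum(b.proportion for b in self.age_blocks) - 1.0) > 1e-9:
            raise ValidationError("age block proportions must sum to 1")
        if abs(sum(self.role_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.role_probs):
            raise ValidationError("role_probs must be non-negative and sum to 1")
        for d, p in self.drug_marginals.items():
            if not (0 <= p < 1):
                raise ValidationError(f"exposure probability for {d!r} must be in [0, 1)")
        for g, p in self.group_marginals.items():
            if not (0 <= p < 1):
                raise ValidationError(f"group marginal for {g!r} must be in [0, 1)")
        planted_drugs = set(self.drug_marginals)
        for sig in self.planted:
            if sig.drug not in planted_drugs:
                raise ValidationError(
                    f"planted ({sig.drug}, {sig.group}): drug has no exposure marginal"
                )
            if sig.group not in self.group_marginals:
                raise ValidationError(
                    f"planted ({sig.drug}, {sig.group}): group has no marginal"
                )
            p0 = self.group_marginals[sig.group]
            if p0 <= 0:
                raise ValidationError(
                    f"planted ({sig.drug}, {sig.group}, {sig.odds_ratio}): "
                    "group has zero baseline rate, the signal is unrealizable"
                )
            max_theta = sig.odds_ratio * max(
                [1.0] + [sig.modifier(s, o) for s in ("female", "male") for o in (False, True)]
            )
            odds = p0 / (1 - p0) * max_theta
            if not np.isfinite(odds) or odds / (1 + odds) >= 1:
                raise ValidationError(
                    f"planted ({sig.drug}, {sig.group}, {sig.odds_ratio}): "
                    "implied event probability reaches 1"
                )


_NAME_POOLS: dict[tuple[str, int, int], list[str]] = {}
_ID_POOLS: dict[int, list[str]] = {}


def _name_pool(prefix: str, size: int, width: int) -> list[str]:
    key = (prefix, size, width)
    pool = _NAME_POOLS.get(key)
    if pool is None:
        pool = [f"{prefix}{i:0{width}d}" for i in range(size)]
        _NAME_POOLS[key] = pool
    return pool


def _report_ids(n: int) -> list[str]:
    ids = _ID_POOLS.get(n)
    if ids is None:
        _ID_POOLS.clear()          # keep at most one cached size
        ids = [f"R{i:08d}" for i in range(n)]
        _ID_POOLS[n] = ids
    return ids


@dataclass
class GroundTruth:
    """The planted list plus expected per-stratum cells, recomputable from
    the config (expectations ignore the rare chance collisions removed by
    exact-profile deduplication)."""

    config: SyntheticConfig
    planted: tuple[PlantedSignal, ...]
    expected_cells: dict[tuple[str, str, str], dict[str, float]]

    def expected_a(self, drug: str, group: str, stratum: str = "all") -> float:
        return self.expected_cells[(drug, group, stratum)]["a"]


def _joint_cells(cfg: SyntheticConfig) -> list[tuple[str, bool, float]]:
    """(sex, older, probability) for the four demographic cells."""
    p_older = sum(b.proportion * b.frac_older for b in cfg.age_blocks)
    out = []
    for sex, p_sex in (("female", cfg.sex_split), ("male", 1 - cfg.sex_split)):
        for older, p_age in ((False, 1 - p_older), (True, p_older)):
            out.append((sex, older, p_sex * p_age))
    return out


def _event_prob(cfg: SyntheticConfig, group: str, exposed: Mapping[str, bool],
                sex: str, older: bool) -> float:
    """P(event in group | exposure pattern, demographic cell)."""
    p0 = cfg.group_marginals[group]
    odds = p0 / (1 - p0)
    for sig in cfg.planted:
        if sig.group == group and exposed.get(sig.drug, False):
            odds *= sig.odds_ratio * sig.modifier(sex, older)
    return odds / (1 + odds)


def expected_cells(
    cfg: SyntheticConfig,
    strata: Sequence[StratumSpec] = DEFAULT_STRATA,
) -> dict[tuple[str, str, str], dict[str, float]]:
    """Closed-form expected (a, b, c, d) for every planted pair and stratum,
    among eligible (deduplicated, demographically complete) reports."""
    elig = cfg.n_reports * (1 - cfg.missing_age_frac) * (1 - cfg.missing_sex_frac)
    cells = _joint_cells(cfg)
    out: dict[tuple[str, str, str], dict[str, float]] = {}
    pairs = sorted({(s.drug, s.group) for s in cfg.planted})
    for drug, group in pairs:
        p_d = cfg.drug_marginals[drug]
        others = sorted({s.drug for s in cfg.planted if s.group == group and s.drug != drug})
        for stratum in strata:
            a = b = c = d = 0.0
            for sex, older, p_cell in cells:
                if stratum.sex_filter != "any" and stratum.sex_filter != sex:
                    continue
                if stratum.age_filter == "older" and not older:
                    continue
                if stratum.age_filter == "younger" and older:
                    continue
                n_cell = elig * p_cell
                # enumerate exposure patterns over the other drugs planted on
                # this group (independent Bernoulli exposures)
                for mask in range(2 ** len(others)):
                    pat = {o: bool(mask >> k & 1) for k, o in enumerate(others)}
                    p_pat = 1.0
                    for o in others:
                        p_pat *= cfg.drug_marginals[o] if pat[o] else 1 - cfg.drug_marginals[o]
                    p_ev_exposed = _event_prob(cfg, group, {drug: True, **pat}, sex, older)
                    p_ev_unexp = _event_prob(cfg, group, {drug: False, **pat}, sex, older)
                    a += n_cell * p_d * p_pat * p_ev_exposed
                    b += n_cell * p_d * p_pat * (1 - p_ev_exposed)
                    c += n_cell * (1 - p_d) * p_pat * p_ev_unexp
                    d += n_cell * (1 - p_d) * p_pat * (1 - p_ev_unexp)
            out[(drug, group, stratum.label)] = {"a": a, "b": b, "c": c, "d": d}
    return out


def generate_reports(
    cfg: SyntheticConfig,
    dictionary: OutcomeDictionary | None = None,
) -> tuple[ReportSet, GroundTruth]:
    """Draw a full synthetic report set; byte-identical for identical config
    and seed."""
    cfg.validate()
    if dictionary is None:
        dictionary = load_outcome_groups()
    for g in cfg.group_marginals:
        if g not in dictionary:
            raise ValidationError(f"group marginal for unknown group {g!r}")
    primary_term = {g.name: g.terms[0] for g in dictionary.groups}

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    female = rng.random(n) < cfg.sex_split
    props = np.array([b.proportion for b in cfg.age_blocks])
    block = rng.choice(len(cfg.age_blocks), size=n, p=props / props.sum())
    age = np.zeros(n, dtype=np.int64)
    for bi, blk in enumerate(cfg.age_blocks):
        m = block == bi
        age[m] = rng.integers(blk.low, blk.high + 1, size=int(m.sum()))
    older = age >= AGE_OLDER_MIN

    exposure: dict[str, np.ndarray] = {
        drug: rng.random(n) < p for drug, p in cfg.drug_marginals.items()
    }

    events: dict[str, np.ndarray] = {}
    for group, p0 in cfg.group_marginals.items():
        odds = np.full(n, p0 / (1 - p0))
        for sig in cfg.planted:
            if sig.group != group:
                continue
            mod = np.full(n, sig.odds_ratio)
            sm = sig.stratum_modifiers
            if "female" in sm or "male" in sm:
                mod *= np.where(female, sm.get("female", 1.0), sm.get("male", 1.0))
            if "younger" in sm or "older" in sm:
                mod *= np.where(older, sm.get("older", 1.0), sm.get("younger", 1.0))
            odds = np.where(exposure[sig.drug], odds * mod, odds)
        p = odds / (1 + odds)
        if np.any(p >= 1):
            raise ValidationError(f"group {group!r}: implied event probability reaches 1")
        events[group] = rng.random(n) < p

    # per-report drug entries: background conmeds first, panel exposures
    # appended (roles drawn per exposed entry)
    roles = np.array(["suspected", "interacting", "concomitant"])
    role_p = np.array(cfg.role_probs)
    role_draws = {}
    for drug, arr in exposure.items():
        idx = np.nonzero(arr)[0]
        role_draws[drug] = (
            idx, roles[rng.choice(3, size=idx.size, p=role_p)] if idx.size else None
        )
    n_bg = rng.integers(cfg.background_drugs_min, cfg.background_drugs_max + 1, size=n)
    bg_ids = rng.integers(0, cfg.background_drug_pool, size=int(n_bg.sum()))
    pool = _name_pool("conmed", cfg.background_drug_pool, 6)
    bg_entries = [(pool[i], "concomitant") for i in bg_ids.tolist()]
    off = np.concatenate(([0], np.cumsum(n_bg))).tolist()
    drug_lists: list[list[tuple[str, str]]] = [
        bg_entries[off[i]:off[i + 1]] for i in range(n)
    ]
    for drug, (idx, drawn) in role_draws.items():
        if drawn is not None:
            for i, ro in zip(idx.tolist(), drawn.tolist()):
                drug_lists[i].append((drug, ro))

    n_noise = rng.poisson(cfg.background_term_rate, size=n)
    noise_ids = rng.integers(0, cfg.background_term_pool, size=int(n_noise.sum()))
    tpool = _name_pool("unmapped reaction ", cfg.background_term_pool, 4)
    noise_terms = [tpool[i] for i in noise_ids.tolist()]
    offt = np.concatenate(([0], np.cumsum(n_noise))).tolist()
    event_lists: list[list[str]] = [
        noise_terms[offt[i]:offt[i + 1]] for i in range(n)
    ]
    for group, arr in events.items():
        term = primary_term[group]
        for i in np.nonzero(arr)[0].tolist():
            event_lists[i].append(term)

    miss_age = rng.random(n) < cfg.missing_age_frac
    miss_sex = rng.random(n) < cfg.missing_sex_frac

    sex_str = np.where(female, "female", "male").tolist()
    reports = [
        CaseReport(rid, None if ma else av, None if ms else sv, dl, el)
        for rid, ma, av, ms, sv, dl, el in zip(
            _report_ids(n), miss_age.tolist(), age.tolist(),
            miss_sex.tolist(), sex_str, drug_lists, event_lists,
        )
    ]

    n_dup = int(round(cfg.duplicate_frac * n))
    if n_dup:
        src = rng.integers(0, n, size=n_dup)
        for j, s in enumerate(src.tolist()):
            r = reports[s]
            reports.append(
                CaseReport(
                    report_id=f"D{j:08d}",
                    age_years=r.age_years,
                    sex=r.sex,
                    drug_entries=list(r.drug_entries),
                    event_terms=list(r.event_terms),
                )
            )

    truth = GroundTruth(
        config=cfg, planted=cfg.planted, expected_cells=expected_cells(cfg)
    )
    return ReportSet(reports, Provenance(total_read=len(reports))), truth


# --------------------------------------------------------------------------
# benchmark profiles

#: Planted associations of the paper-like benchmark.  Pairs without stratum
#: modifiers are the parameter-recovery set (grouped by theta); the two
#: modifier-carrying pairs emulate the published male-only and younger-only
#: subgroup findings.
PAPER_LIKE_PLANTED: tuple[PlantedSignal, ...] = (
    # theta = 5
    PlantedSignal("imatinib", "Venous embolism and thrombosis", 5.0),
    PlantedSignal("ibrutinib", "Supraventricular tachyarrhythmias", 5.0),
    # theta = 3
    PlantedSignal("imatinib", "Heart failure", 3.0),
    PlantedSignal("nilotinib", "Hypertension", 3.0),
    PlantedSignal("ruxolitinib", "Hemorrhage (clinical events)", 3.0),
    # theta = 2
    PlantedSignal("erlotinib", "Hemorrhage (clinical events)", 2.0),
    PlantedSignal("erlotinib", "Venous embolism and thrombosis", 2.0),
    PlantedSignal("dasatinib", "Heart failure", 2.0),
    PlantedSignal("dasatinib", "Supraventricular tachyarrhythmias", 2.0),
    PlantedSignal("ibrutinib", "Hypertension", 2.0),
    PlantedSignal("nilotinib", "Heart failure", 2.0),
    PlantedSignal("ruxolitinib", "Hypertension", 2.0),
    # theta = 1 (explicit nulls: registered estimands, no elevation)
    PlantedSignal("imatinib", "Hemorrhage (clinical events)", 1.0),
    PlantedSignal("imatinib", "Hypertension", 1.0),
    PlantedSignal("imatinib", "Respiratory failure", 1.0),
    PlantedSignal("ibrutinib", "Hemorrhage (clinical events)", 1.0),
    PlantedSignal("ibrutinib", "Heart failure", 1.0),
    PlantedSignal("ibrutinib", "Venous embolism and thrombosis", 1.0),
    PlantedSignal("erlotinib", "Hypertension", 1.0),
    PlantedSignal("dasatinib", "Hypertension", 1.0),
    PlantedSignal("nilotinib", "Hemorrhage (clinical events)", 1.0),
    PlantedSignal("ruxolitinib", "Heart failure", 1.0),
    # stratum-specific effects echoing the published subgroup findings
    PlantedSignal("lapatinib", "Cardiomyopathy", 1.0, {"male": 3.0}),
    PlantedSignal("gefitinib", "Pericarditis", 1.0, {"younger": 3.0}),
)


def recovery_pairs(
    planted: Iterable[PlantedSignal] = PAPER_LIKE_PLANTED,
) -> dict[float, list[tuple[str, str]]]:
    """Modifier-free planted pairs grouped by theta (the recovery estimands)."""
    out: dict[float, list[tuple[str, str]]] = {}
    for sig in planted:
        if not sig.stratum_modifiers:
            out.setdefault(sig.odds_ratio, []).append((sig.drug, sig.group))
    return out


def recover_planted_ror(
    n_replicates: int = 30,
    n_reports: int = 500_000,
    seed: int = 0,
    panel: DrugPanel | None = None,
    dictionary: OutcomeDictionary | None = None,
) -> dict[float, float]:
    """Parameter-recovery experiment: pooled ROR estimate per planted theta.

    Runs ``n_replicates`` independent paper-like benchmarks (sub-seeded from
    ``seed``), pushes each through deduplication, eligibility filtering and
    2x2 construction, and pools the recovery pairs' tables per theta with
    the Mantel-Haenszel estimator.  Under a correct pipeline the pooled
    estimate converges on the planted theta.
    """
    from .contingency import STRATUM_ALL, CohortIndex
    from .ingest import filter_eligible, flag_duplicates
    from .stats import pooled_ror

    if panel is None:
        panel = load_drug_panel()
    if dictionary is None:
        dictionary = load_outcome_groups()
    pairs = recovery_pairs()
    tables: dict[float, list] = {theta: [] for theta in pairs}
    ss = np.random.SeedSequence(seed)
    sub_seeds = [int(s) for s in ss.generate_state(n_replicates) >> 1]
    for rep_seed in sub_seeds:
        cfg = paper_like_config(n_reports, rep_seed, panel)
        rs, _ = generate_reports(cfg, dictionary)
        rs = filter_eligible(flag_duplicates(rs))
        index = CohortIndex(rs, panel, dictionary)
        for theta, pair_list in pairs.items():
            for drug, group in pair_list:
                tables[theta].append(index.table(drug, group, STRATUM_ALL))
    return {theta: pooled_ror(tabs) for theta, tabs in sorted(tables.items())}


def paper_like_config(
    n_reports: int = 500_000,
    seed: int = 0,
    panel: DrugPanel | None = None,
) -> SyntheticConfig:
    """The paper-like study conditions: published demographic marginals,
    Table-1-proportional exposure, published missing-data fraction split
    across age and sex, and the planted-signal set above."""
    if panel is None:
        panel = load_drug_panel()
    return SyntheticConfig(
        n_reports=n_reports,
        seed=seed,
        sex_split=0.608,
        missing_age_frac=0.20,
        missing_sex_frac=0.10,
        duplicate_frac=0.02,
        drug_marginals=panel.exposure_marginals(REFERENCE_ELIGIBLE),
        group_marginals=dict(PAPER_LIKE_GROUP_RATES),
        planted=PAPER_LIKE_PLANTED,
    )


def make_benchmark(
    profile: str,
    n_reports: int | None = None,
    seed: int = 0,
    panel: DrugPanel | None = None,
    dictionary: OutcomeDictionary | None = None,
) -> tuple[ReportSet, GroundTruth]:
    """Named benchmark datasets: ``paper-like``, ``null``, or ``stress``.

    * ``paper-like`` — full panel, planted signals, published marginals
      (default n = 500,000);
    * ``null`` — same marginals, nothing planted (default n = 50,000);
    * ``stress`` — small cohort with an unexposed drug (guaranteed
      no-reports strata), very rare groups, heavy missingness and
      duplication (default n = 20,000).
    """
    if panel is None:
        panel = load_drug_panel()
    if profile == "paper-like":
        cfg = paper_like_config(n_reports or 500_000, seed, panel)
    elif profile == "null":
        cfg = replace(
            paper_like_config(n_reports or 50_000, seed, panel), planted=()
        )
    elif profile == "stress":
        marg = panel.exposure_marginals(REFERENCE_ELIGIBLE)
        marg["futibatinib"] = 0.0          # a drug with no reports at all
        rates = dict(PAPER_LIKE_GROUP_RATES)
        rates["Endocardial disorders"] = 1e-4
        rates["Temporal arteritis/Polymyalgia rheumatica"] = 1e-4
        cfg = SyntheticConfig(
            n_reports=n_reports or 20_000,
            seed=seed,
            missing_age_frac=0.30,
            missing_sex_frac=0.20,
            duplicate_frac=0.05,
            drug_marginals=marg,
            group_marginals=rates,
            planted=(PlantedSignal("imatinib", "Heart failure", 4.0),),
        )
    else:
        raise ValidationError(f"unknown benchmark profile {profile!r}")
    return generate_reports(cfg, dictionary)
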