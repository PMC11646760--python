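"""Synthetic report generator: determinism, marginals, planted-signal recovery."""

import numpy as np
import pytest

from vigisig import (
    PlantedSignal,
    SyntheticConfig,
    ValidationError,
    build_signal_table,
    compute_ror,
    filter_eligible,
    flag_duplicates,
    generate_reports,
    make_benchmark,
    write_icsr_table,
)
from vigisig.contingency import STRATUM_ALL, STRATUM_FEMALE, STRATUM_MALE, CohortIndex
from vigisig.signals import Category
from vigisig.stats import attach_statistics
from vigisig.synthetic import paper_like_config, recovery_pairs


def _small_config(**kw):
    base = dict(
        n_reports=5_000,
        seed=42,
        drug_marginals={"imatinib": 0.05, "gefitinib": 0.02},
        group_marginals={"Hypertension": 0.03, "Heart failure": 0.02},
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerateReports:
    def test_deterministic_byte_identical(self):
        cfg = _small_config()
        rs1, _ = generate_reports(cfg)
        rs2, _ = generate_reports(cfg)
        assert write_icsr_table(rs1) == write_icsr_table(rs2)

    def test_seed_changes_output(self):
        rs1, _ = generate_reports(_small_config(seed=1))
        rs2, _ = generate_reports(_small_config(seed=2))
        assert write_icsr_table(rs1) != write_icsr_table(rs2)

    def test_missingness_exclusion_fraction(self):
        """Independent missing-age/sex masks exclude 1 - (1-ma)(1-ms)."""
        cfg = _small_config(
            n_reports=50_000, missing_age_frac=0.2, missing_sex_frac=0.1
        )
        rs, _ = generate_reports(cfg)
        rs = filter_eligible(rs)
        frac = rs.provenance.excluded_missing_age_or_sex / cfg.n_reports
        # 3.5 binomial sigmas around 0.28
        sigma = (0.28 * 0.72 / cfg.n_reports) ** 0.5
        assert abs(frac - 0.28) < 3.5 * sigma

    def test_demographic_marginals(self):
        cfg = _small_config(n_reports=40_000)
        rs, _ = generate_reports(cfg)
        female = sum(r.sex == "female" for r in rs)
        older = sum(r.older for r in rs)
        assert female / len(rs) == pytest.approx(0.608, abs=0.01)
        assert older / len(rs) == pytest.approx(0.275, abs=0.01)

    def test_duplicates_appended_and_flagged(self):
        cfg = _small_config(duplicate_frac=0.1)
        rs, _ = generate_reports(cfg)
        assert len(rs) == 5_500
        deduped = flag_duplicates(rs)
        assert deduped.provenance.duplicates_flagged >= 500

    def test_infeasible_config_names_the_tuple(self):
        cfg = _small_config(
            group_marginals={"Hypertension": 0.0},
            planted=(PlantedSignal("imatinib", "Hypertension", 3.0),),
        )
        with pytest.raises(ValidationError):
            cfg.validate()
        with pytest.raises(ValidationError, match=r"imatinib, Hyp"):
            SyntheticConfig(
                n_reports=10,
                drug_marginals={"imatinib": 0.5},
                group_marginals={"Hypertension": 0.5},
                planted=(PlantedSignal("imatinib", "Hyp", 3.0),),
            ).validate()

    def test_unknown_planted_drug_rejected(self):
        cfg = _small_config(planted=(PlantedSignal("aspirin", "Hypertension", 2.0),))
        with pytest.raises(ValidationError, match="aspirin"):
            cfg.validate()


class TestPlantedRecovery:
    def test_null_pairs_estimate_near_one(self, panel, dictionary):
        cfg = _small_config(n_reports=100_000, seed=5)
        rs, _ = generate_reports(cfg)
        idx = CohortIndex(rs, panel, dictionary)
        for drug in ("imatinib", "gefitinib"):
            t = idx.table(drug, "Hypertension", STRATUM_ALL)
            r = compute_ror(t)
            assert r.ci_low < 1.0 < r.ci_high or abs(np.log(r.ror)) < 0.5

    def test_planted_theta_recovered(self, panel, dictionary):
        """theta = 3 at comfortable cell sizes: estimate lands in a window
        +/- 5 Woolf sigmas wide around the planted value."""
        cfg = SyntheticConfig(
            n_reports=150_000,
            seed=7,
            drug_marginals={"imatinib": 0.05},
            group_marginals={"Hypertension": 0.02},
            planted=(PlantedSignal("imatinib", "Hypertension", 3.0),),
        )
        rs, truth = generate_reports(cfg)
        rs = filter_eligible(flag_duplicates(rs))
        t = CohortIndex(rs, panel, dictionary).table("imatinib", "Hypertension", STRATUM_ALL)
        assert truth.expected_a("imatinib", "Hypertension") == pytest.approx(
            150_000 * 0.05 * (3 * 0.02 / 0.98) / (1 + 3 * 0.02 / 0.98), rel=1e-6
        )
        r = compute_ror(t)
        assert 2.6 < r.ror < 3.5

    def test_expected_cells_match_empirical_counts(self, panel, dictionary):
        cfg = SyntheticConfig(
            n_reports=120_000,
            seed=11,
            missing_age_frac=0.1,
            missing_sex_frac=0.05,
            drug_marginals={"imatinib": 0.04, "dasatinib": 0.03},
            group_marginals={"Heart failure": 0.03},
            planted=(
                PlantedSignal("imatinib", "Heart failure", 4.0),
                PlantedSignal("dasatinib", "Heart failure", 1.0),
            ),
        )
        rs, truth = generate_reports(cfg)
        rs = filter_eligible(flag_duplicates(rs))
        idx = CohortIndex(rs, panel, dictionary)
        for drug in ("imatinib", "dasatinib"):
            t = idx.table(drug, "Heart failure", STRATUM_ALL)
            exp = truth.expected_cells[(drug, "Heart failure", "all")]
            for cell in "abcd":
                e = exp[cell]
                assert abs(getattr(t, cell) - e) < 4 * max(e, 10) ** 0.5 + 5

    def test_stratum_modifier_direction(self, panel, dictionary):
        """A male-only odds multiplier shows up as ROR(male) > ROR(female)."""
        cfg = SyntheticConfig(
            n_reports=120_000,
            seed=13,
            sex_split=0.5,
            drug_marginals={"lapatinib": 0.05},
            group_marginals={"Cardiomyopathy": 0.02},
            planted=(
                PlantedSignal("lapatinib", "Cardiomyopathy", 1.0, {"male": 3.0}),
            ),
        )
        rs, _ = generate_reports(cfg)
        idx = CohortIndex(rs, panel, dictionary)
        r_m = compute_ror(idx.table("lapatinib", "Cardiomyopathy", STRATUM_MALE))
        r_f = compute_ror(idx.table("lapatinib", "Cardiomyopathy", STRATUM_FEMALE))
        # windows are +/- 3.5 Woolf sigmas at the expected cell sizes
        assert r_m.ror > 1.6 * r_f.ror
        assert 2.2 < r_m.ror < 4.1
        assert 0.55 < r_f.ror < 1.8


class TestBenchmarkProfiles:
    def test_recovery_pairs_cover_all_thetas(self):
        pairs = recovery_pairs()
        assert set(pairs) == {1.0, 2.0, 3.0, 5.0}
        assert all(len(v) >= 2 for v in pairs.values())

    def test_paper_like_demographics(self, panel):
        cfg = paper_like_config(30_000, seed=3, panel=panel)
        rs, _ = generate_reports(cfg)
        rs = filter_eligible(flag_duplicates(rs))
        from vigisig import summarize_cohort

        s = summarize_cohort(rs)
        assert s.pct_female == pytest.approx(60.8, abs=1.5)
        assert s.pct_younger == pytest.approx(72.5, abs=1.5)

    def test_null_profile_plants_nothing(self):
        rs, truth = make_benchmark("null", n_reports=1_000, seed=1)
        assert truth.planted == ()

    def test_stress_profile_has_no_report_stratum(self, panel, dictionary):
        rs, _ = make_benchmark("stress", n_reports=5_000, seed=2)
        rs = filter_eligible(flag_duplicates(rs))
        from vigisig import build_all
        from vigisig.contingency import DEFAULT_STRATA

        tables = build_all(rs, panel, dictionary, DEFAULT_STRATA)
        stats_df = attach_statistics(tables, panel)
        st_table = build_signal_table(stats_df)
        cats = {
            (c.drug, c.stratum): c.category
            for c in st_table.cells
            if c.drug == "futibatinib"
        }
        assert all(cat is Category.NO_REPORTS for cat in cats.values())

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValidationError, match="profile"):
            make_benchmark("bogus")
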