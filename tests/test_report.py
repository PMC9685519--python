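"""Cohort aggregation: carrier and family rates, inheritance partition,
domain composition, rounding, and the end-to-end report files."""

from fractions import Fraction

import pytest

from sfscreen.errors import ConfigError, DataIntegrityError
from sfscreen.io import SubjectInfo, read_report
from sfscreen.model import (
    GenomicVariant,
    SubjectCall,
    TierAssignment,
    VariantKey,
)
from sfscreen.panel import default_panel
from sfscreen.report import (
    domain_composition,
    inheritance_partition,
    percent,
    round_half_up,
    run_pipeline,
    summarize,
)

PANEL = default_panel()


def subject(sid, fam=None):
    return SubjectInfo(sid, fam or f"fam-{sid}", "adult", "F", True, "unknown")


def variant(pos, gene):
    return GenomicVariant(chrom="1", pos=pos, ref="G", alt="A", gene=gene,
                          consequence="missense")


def call(sid, pos, fam=None):
    return SubjectCall(sid, fam or f"fam-{sid}", "1", pos, "G", "A", "het", 142, 0.5)


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (27, 383, 7.0),
            (23, 383, 6.0),
            (4, 383, 1.0),
            (22, 266, 8.3),
            (19, 266, 7.1),
            (12, 27, 44.4),
            (25, 10000, 0.3),  # exact half rounds up, not to even
        ],
    )
    def test_percentages_round_half_up(self, num, den, expected):
        assert percent(num, den) == expected

    def test_mean_rounding(self):
        assert round_half_up(Fraction(1213, 383), 1) == 3.2
        assert round_half_up(Fraction(1, 4), 1) == 0.3

    def test_zero_denominator_is_zero(self):
        assert percent(0, 0) == 0.0


class TestSummarize:
    def test_mixed_evidence_cohort(self):
        variants = {v.key: v for v in [variant(100, "ATP7B"), variant(200, "DSP"),
                                       variant(300, "ACTA2")]}
        assignments = {
            VariantKey("1", 100, "G", "A"): TierAssignment("I"),
            VariantKey("1", 200, "G", "A"): TierAssignment("II"),
            VariantKey("1", 300, "G", "A"): TierAssignment("III"),
        }
        subjects = {f"S{i}": subject(f"S{i}") for i in range(1, 6)}
        calls = [call("S1", 100), call("S2", 200), call("S3", 300), call("S1", 200)]
        summary = summarize(assignments, calls, subjects, PANEL, variants)
        assert summary.n_unique_sf == 3
        assert summary.n_sf_high == 2 and summary.n_sf_moderate == 1
        assert summary.n_subjects_with_sf == 3
        assert summary.n_subjects_high == 2
        assert summary.n_subjects_moderate_only == 1
        assert summary.sf_per_subject_max == 2  # S1 carries two findings
        assert summary.pct_subjects_with_sf == 60.0

    def test_subject_with_both_levels_counted_once(self):
        variants = {v.key: v for v in [variant(100, "ATP7B"), variant(300, "ACTA2")]}
        assignments = {
            VariantKey("1", 100, "G", "A"): TierAssignment("I"),
            VariantKey("1", 300, "G", "A"): TierAssignment("III"),
        }
        subjects = {"S1": subject("S1")}
        calls = [call("S1", 100), call("S1", 300)]
        summary = summarize(assignments, calls, subjects, PANEL, variants)
        assert summary.n_subjects_with_sf == 1
        assert summary.n_subjects_high == 1
        assert summary.n_subjects_moderate_only == 0
        assert summary.n_subjects_both_levels == 1

    def test_empty_assignments_give_zero_summary(self):
        subjects = {"S1": subject("S1")}
        summary = summarize({}, [], subjects, PANEL, {})
        assert summary.n_unique_sf == 0
        assert summary.n_subjects_with_sf == 0
        assert summary.pct_subjects_with_sf == 0.0

    def test_unknown_subject_rejected(self):
        with pytest.raises(DataIntegrityError):
            summarize({}, [call("ghost", 100)], {}, PANEL, {})


class TestInheritancePartition:
    def test_single_recessive_carrier(self):
        variants = {variant(100, "ATP7B").key: variant(100, "ATP7B")}
        assignments = {VariantKey("1", 100, "G", "A"): TierAssignment("I")}
        calls = [call("S1", 100)]
        assert inheritance_partition(assignments, calls, PANEL, variants) == (1, 0)

    def test_semidominant_counts_as_dominant(self):
        variants = {variant(100, "LDLR").key: variant(100, "LDLR")}
        assignments = {VariantKey("1", 100, "G", "A"): TierAssignment("I")}
        calls = [call("S1", 100)]
        assert inheritance_partition(assignments, calls, PANEL, variants) == (0, 1)

    def test_recessive_takes_precedence_within_a_subject(self):
        variants = {v.key: v for v in [variant(100, "ATP7B"), variant(200, "DSP")]}
        assignments = {
            VariantKey("1", 100, "G", "A"): TierAssignment("I"),
            VariantKey("1", 200, "G", "A"): TierAssignment("I"),
        }
        calls = [call("S1", 100), call("S1", 200)]
        assert inheritance_partition(assignments, calls, PANEL, variants) == (1, 0)


class TestDomainComposition:
    def test_unique_variant_basis(self):
        genes = ["LDLR", "LDLR", "DSP", "MUTYH"]
        variants = {variant(100 + i, g).key: variant(100 + i, g) for i, g in enumerate(genes)}
        assignments = {k: TierAssignment("I") for k in variants}
        shares = domain_composition(assignments, PANEL, "unique_variants", variants)
        assert shares["familial hypercholesterolemia"] == Fraction(2, 4)
        assert shares["cardiac disorders"] == Fraction(1, 4)
        assert sum(shares.values()) == 1

    def test_single_domain_is_unity(self):
        variants = {variant(100, "ATP7B").key: variant(100, "ATP7B")}
        assignments = {k: TierAssignment("III") for k in variants}
        shares = domain_composition(assignments, PANEL, "unique_variants", variants)
        assert shares == {"Wilson disease": Fraction(1)}

    def test_observation_basis_weighs_carriers(self):
        variants = {variant(100, "LDLR").key: variant(100, "LDLR"),
                    variant(200, "DSP").key: variant(200, "DSP")}
        assignments = {k: TierAssignment("I") for k in variants}
        calls = [call("S1", 100), call("S2", 100), call("S3", 200)]
        shares = domain_composition(assignments, PANEL, "observations", variants, calls)
        assert shares["familial hypercholesterolemia"] == Fraction(2, 3)

    def test_unknown_basis_rejected(self):
        with pytest.raises(ConfigError):
            domain_composition({}, PANEL, "genes")


class TestEndToEnd:
    def test_canonical_report_has_21_findings_and_round_trips(
        self, pipeline_result, canonical_cohort, tmp_path
    ):
        assert len(pipeline_result.records) == 21
        tiers = sorted(r.tier for r in pipeline_result.records)
        assert tiers.count("I") == 14 and tiers.count("II") == 3 and tiers.count("III") == 4
        # second run over the same inputs is byte-deterministic
        second = run_pipeline(
            canonical_cohort.vcf, canonical_cohort.annotations,
            canonical_cohort.evidence, canonical_cohort.panel,
            out_dir=tmp_path, subjects_path=canonical_cohort.subjects,
        )
        records, summary = read_report(tmp_path)
        assert records == pipeline_result.records
        assert summary == pipeline_result.summary.to_dict()

    def test_per_subject_finding_count_range(self, pipeline_result):
        assert pipeline_result.summary.sf_per_subject_min == 1
        assert pipeline_result.summary.sf_per_subject_max == 2

    def test_family_counts_never_exceed_subject_counts(self, pipeline_result):
        s = pipeline_result.summary
        assert s.n_families_with_sf <= s.n_subjects_with_sf
        assert s.n_unique_sf == s.n_sf_high + s.n_sf_moderate

    def test_high_and_moderate_carrier_sets_disjoint_in_canonical_cohort(
        self, pipeline_result
    ):
        s = pipeline_result.summary
        assert s.n_subjects_both_levels == 0
        assert s.n_subjects_with_sf == s.n_subjects_high + s.n_subjects_moderate_only
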