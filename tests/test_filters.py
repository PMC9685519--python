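"""Filter-cascade stages: printed thresholds are strict, the funnel is
idempotent, order-independent and monotone in its thresholds, and traces
record exactly one first failure per removed variant."""

from dataclasses import replace
from fractions import Fraction

import pytest

from sfscreen.errors import ModelError
from sfscreen.filters import (
    DEFAULT_FILTER_CONFIG,
    FilterConfig,
    cohort_recurrence_filter,
    noncoding_rule,
    population_frequency_filter,
    predictor_concordance,
    quality_filter,
    restrict_to_panel,
    run_cascade,
)
from sfscreen.model import (
    GenomicVariant,
    PopulationFrequencies,
    PredictionProfile,
    SubjectCall,
)
from sfscreen.panel import default_panel

PANEL = default_panel()


def variant(pos=100, gene="MUTYH", consequence="missense", offset=0, freqs=None,
            predictors=None, chrom="1"):
    return GenomicVariant(
        chrom=chrom, pos=pos, ref="G", alt="A", gene=gene,
        consequence=consequence, intron_offset=offset,
        frequencies=freqs or PopulationFrequencies(),
        predictors=predictors or PredictionProfile(),
    )


def call(subject="S1", pos=100, depth=142, fraction=0.48, chrom="1"):
    return SubjectCall(subject, f"fam-{subject}", chrom, pos, "G", "A", "het",
                       depth, fraction)


ALL_DELETERIOUS = PredictionProfile(
    cadd_phred=25, lrt="D", mutation_assessor="H", mutation_taster="D",
    polyphen2_hdiv="D", sift="D", fathmm="D",
)


class TestPanelRestriction:
    def test_panel_gene_retained_and_offpanel_removed(self):
        kept = restrict_to_panel([variant(gene="ATP7B"), variant(pos=200, gene="TTN")], PANEL)
        assert [v.gene for v in kept] == ["ATP7B"]

    def test_empty_input_allowed(self):
        assert restrict_to_panel([], PANEL) == []


class TestPopulationFrequency:
    def test_rare_published_frequency_passes(self):
        freqs = PopulationFrequencies(af_gnomad_exome=0.003027)
        assert population_frequency_filter(variant(freqs=freqs))[0]

    def test_two_percent_fails(self):
        freqs = PopulationFrequencies(af_gnomad_genome=0.02)
        assert not population_frequency_filter(variant(freqs=freqs))[0]

    def test_exactly_one_percent_fails_strictly(self):
        freqs = PopulationFrequencies(af_exac=0.01)
        assert not population_frequency_filter(variant(freqs=freqs))[0]

    def test_novel_allele_passes(self):
        assert population_frequency_filter(variant())[0]

    def test_maximum_over_databases_governs(self):
        freqs = PopulationFrequencies(af_gnomad_exome=0.001, af_1000g=0.05)
        assert not population_frequency_filter(variant(freqs=freqs))[0]


class TestCohortRecurrence:
    def _calls(self, n):
        return [call(subject=f"S{i}") for i in range(n)]

    def test_five_of_383_fails(self):
        ok, _ = cohort_recurrence_filter(variant(), self._calls(5), 383)
        assert not ok

    def test_three_of_383_passes(self):
        ok, _ = cohort_recurrence_filter(variant(), self._calls(3), 383)
        assert ok

    def test_four_of_383_is_just_above_one_percent(self):
        ok, _ = cohort_recurrence_filter(variant(), self._calls(4), 383)
        assert not ok

    def test_no_carriers_passes(self):
        assert cohort_recurrence_filter(variant(), [], 383)[0]

    def test_distinct_subjects_counted_once(self):
        calls = [call(subject="S1"), call(subject="S1"), call(subject="S2")]
        ok, reason = cohort_recurrence_filter(variant(), calls, 383)
        assert ok and "2/383" in reason


class TestCallQuality:
    def test_typical_passing_call(self):
        assert quality_filter(call(depth=142, fraction=0.48))[0]

    def test_depth_boundary_is_strict(self):
        assert not quality_filter(call(depth=20, fraction=0.5))[0]
        assert quality_filter(call(depth=21, fraction=0.5))[0]

    def test_alt_fraction_boundary_is_strict(self):
        assert not quality_filter(call(depth=100, fraction=0.25))[0]
        assert quality_filter(call(depth=100, fraction=0.26))[0]


class TestPredictorConcordance:
    def test_unanimous_profile_passes(self):
        assert predictor_concordance(ALL_DELETERIOUS) == (7, True)

    def test_five_votes_fail_quorum(self):
        profile = replace(ALL_DELETERIOUS, sift="T", fathmm="T")
        assert predictor_concordance(profile) == (5, False)

    def test_cadd_at_exactly_20_does_not_vote(self):
        profile = replace(ALL_DELETERIOUS, cadd_phred=20.0)
        votes, ok = predictor_concordance(profile)
        assert (votes, ok) == (6, True)  # six categorical votes still reach quorum

    def test_absent_predictions_count_as_non_deleterious(self):
        profile = PredictionProfile(cadd_phred=30)
        assert predictor_concordance(profile) == (1, False)


class TestNoncodingRule:
    def test_intronic_within_window_passes(self):
        assert noncoding_rule(variant(consequence="intronic", offset=4))[0]
        assert noncoding_rule(variant(consequence="intronic", offset=3))[0]
        assert noncoding_rule(variant(consequence="intronic", offset=-5))[0]

    def test_intronic_outside_window_fails(self):
        assert not noncoding_rule(variant(consequence="intronic", offset=6))[0]

    def test_essential_splice_always_passes(self):
        assert noncoding_rule(variant(consequence="splice_essential", offset=1))[0]
        assert noncoding_rule(variant(consequence="splice_essential", offset=-2))[0]

    def test_rejects_coding_consequence(self):
        with pytest.raises(ModelError):
            noncoding_rule(variant(consequence="missense"))


def small_cohort():
    """A hand-built mixed cohort of 8 variants across filter fates."""
    variants = [
        variant(pos=100, gene="ATP7B", predictors=ALL_DELETERIOUS),      # prioritized missense
        variant(pos=200, gene="MUTYH", consequence="nonsense"),          # LoF bypass
        variant(pos=300, gene="MUTYH", consequence="intronic", offset=3),  # near-exon intronic
        variant(pos=400, gene="LDLR", predictors=PredictionProfile()),   # missense, no votes
        variant(pos=500, gene="TTN"),                                    # off panel
        variant(pos=600, gene="DSP",
                freqs=PopulationFrequencies(af_gnomad_exome=0.05)),      # common
        variant(pos=700, gene="RET", predictors=ALL_DELETERIOUS),        # recurrent
        variant(pos=800, gene="PTEN", predictors=ALL_DELETERIOUS),       # low quality
    ]
    calls = [
        call(pos=100), call(pos=200), call(pos=300), call(pos=400),
        call(pos=500), call(pos=600),
        *[call(subject=f"S{i}", pos=700) for i in range(3)],  # 3/100 carriers > 1%
        call(pos=800, depth=15, fraction=0.5),
    ]
    return variants, calls


def test_cascade_partitions_and_traces():
    variants, calls = small_cohort()
    result = run_cascade(variants, calls, PANEL, n_subjects=100)
    retained_pos = sorted(v.pos for v in result.retained)
    prioritized_pos = sorted(v.pos for v in result.prioritized)
    assert retained_pos == [100, 200, 300, 400]
    assert prioritized_pos == [100, 200, 300]
    # every removed variant has exactly one failing verdict, and it is last
    for trace in result.traces.values():
        failures = [v for v in trace.verdicts if not v.passed]
        assert len(failures) <= 1
        if failures:
            assert trace.verdicts[-1] is failures[0]
    assert result.traces[variants[4].key].first_failure.stage == "panel"
    assert result.traces[variants[5].key].first_failure.stage == "population_frequency"
    assert result.traces[variants[6].key].first_failure.stage == "cohort_recurrence"
    assert result.traces[variants[7].key].first_failure.stage == "call_quality"
    assert result.traces[variants[3].key].first_failure.stage == "prioritization"


def test_cascade_is_idempotent_and_order_independent():
    variants, calls = small_cohort()
    first = run_cascade(variants, calls, PANEL, n_subjects=100)
    second = run_cascade(list(reversed(variants)), list(reversed(calls)), PANEL, 100)
    third = run_cascade(first.retained, calls, PANEL, n_subjects=100)
    assert first.retained_keys == second.retained_keys == third.retained_keys
    assert first.prioritized_keys == second.prioritized_keys


@pytest.mark.parametrize(
    "relaxed",
    [
        dict(population_af_max=0.05),
        dict(cohort_freq_max=Fraction(1, 10)),
        dict(min_depth=10),
        dict(min_alt_fraction=0.1),
        dict(predictor_quorum=4),
        dict(intron_window=10),
        dict(cadd_min=10.0),
    ],
)
def test_relaxing_any_threshold_never_shrinks_the_sets(relaxed):
    variants, calls = small_cohort()
    strict = run_cascade(variants, calls, PANEL, 100, DEFAULT_FILTER_CONFIG)
    loose = run_cascade(variants, calls, PANEL, 100, FilterConfig(**relaxed))
    assert strict.retained_keys <= loose.retained_keys
    assert strict.prioritized_keys <= loose.prioritized_keys


def test_inframe_indel_requires_lof_annotation():
    v = GenomicVariant(chrom="1", pos=900, ref="GAAA", alt="G", gene="ATP7B",
                       consequence="inframe_indel")
    calls = [SubjectCall("S1", "F1", "1", 900, "GAAA", "G", "het", 142, 0.48)]
    without = run_cascade([v], calls, PANEL, 100)
    assert without.prioritized == []
    with_pvs1 = run_cascade([v], calls, PANEL, 100, evidence={v.key: frozenset({"PVS1"})})
    assert [x.key for x in with_pvs1.prioritized] == [v.key]


def test_synonymous_variants_are_never_prioritized():
    v = variant(consequence="synonymous", predictors=ALL_DELETERIOUS)
    result = run_cascade([v], [call()], PANEL, 100)
    assert result.retained and not result.prioritized


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("population_af_max: 0.005\npredictor_quorum: 5\ncohort_freq_max: '1/50'\n")
    config = FilterConfig.from_yaml(path)
    assert config.population_af_max == 0.005
    assert config.predictor_quorum == 5
    assert config.cohort_freq_max == Fraction(1, 50)
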