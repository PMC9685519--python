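"""The synthetic-cohort generator: planted annotation fidelity, seeded
determinism, demographic marginals, and labeled-oracle equivalence of the
filter cascade on generated data."""

import hashlib
from dataclasses import replace

import pandas as pd
import pytest

from sfscreen.errors import ConfigError
from sfscreen.filters import run_cascade
from sfscreen.io import read_cohort, read_evidence, read_subjects
from sfscreen.model import VariantKey
from sfscreen.panel import Panel
from sfscreen.synthetic import (
    TABLE2_BY_ID,
    CohortDesign,
    DEFAULT_CARRIER_PLAN,
    generate_cohort,
    plant_table2,
    table2_variants,
)

SMALL_DESIGN = CohortDesign(
    n_subjects=100, n_families=80, n_pediatric=40, n_adult=60,
    n_female=50, n_male=50,
    n_rare_plp=2, n_rare_ci=12, n_rare_nr=10, n_rare_vus=6, n_rare_blb=4,
    n_ci_pass=3, n_nr_pass=2,
    n_decoy_offpanel=3, n_decoy_common=3, n_decoy_recurrent=2, n_decoy_lowquality=2,
    plant_table2=False, seed=11,
)


def file_hashes(files):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in (files.vcf, files.annotations, files.evidence, files.panel,
                  files.subjects, files.labels)
    }


class TestPlantedContent:
    def test_planted_mutyh_row_carries_published_annotation(self, canonical_cohort):
        frame = pd.read_csv(canonical_cohort.annotations, sep="\t", dtype=str,
                            keep_default_na=False)
        row = frame[frame.hgvs_c == "NM_001048174.2:c.1103G>A"]
        assert len(row) == 1
        assert float(row.iloc[0].af_gnomad_exome) == 0.003027
        assert row.iloc[0].gene == "MUTYH"

    def test_planted_atp7b_row_carries_dbsnp_id(self, canonical_cohort):
        frame = pd.read_csv(canonical_cohort.annotations, sep="\t", dtype=str,
                            keep_default_na=False)
        row = frame[frame.hgvs_c == "NM_000053.4:c.2906G>A"]
        assert row.iloc[0].dbsnp_id == "rs121907996"

    def test_planted_clinvar_submission_profiles(self):
        dsp = TABLE2_BY_ID["DSP:c.4198C>T"]
        assert dsp.clinvar.n_plp == 6
        atp7b_ci = TABLE2_BY_ID["ATP7B:c.2605G>A"]
        assert (atp7b_ci.clinvar.n_vus, atp7b_ci.clinvar.n_lp, atp7b_ci.clinvar.n_p) == (1, 7, 10)
        unreported = TABLE2_BY_ID["DSP:c.6202_6205del"]
        assert unreported.clinvar.total == 0

    def test_planted_evidence_codes(self):
        assert plant_table2({"DSP:c.4198C>T": ("R1",)})[0][0].acmg_codes == "PVS1,PM2,PP5"
        with pytest.raises(ConfigError, match="unknown planted variant id"):
            plant_table2({"GENE:c.1A>T": ("R1",)})

    def test_twenty_one_planted_variants_with_unique_keys(self):
        variants = table2_variants()
        assert len(variants) == 21
        assert len({v.key for v in variants}) == 21

    def test_planted_calls_are_heterozygous_and_high_quality(self, canonical_cohort):
        _, calls, _ = read_cohort(canonical_cohort.vcf, canonical_cohort.annotations,
                                  canonical_cohort.subjects)
        planted_keys = {v.key for v in table2_variants()}
        planted_calls = [c for c in calls if c.variant_key in planted_keys]
        assert len(planted_calls) == 28  # carrier observations in the plan
        assert all(c.genotype == "het" for c in planted_calls)
        assert all(c.depth > 20 and c.alt_fraction > 0.25 for c in planted_calls)
        # dual-carrier subject exists: 27 distinct subjects over 28 observations
        assert len({c.subject_id for c in planted_calls}) == 27

    def test_carrier_plan_subject_counts(self):
        observations = sum(len(slots) for slots in DEFAULT_CARRIER_PLAN.values())
        slots = {s for slots in DEFAULT_CARRIER_PLAN.values() for s in slots}
        assert observations == 28
        assert len(slots) == 27


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        first = generate_cohort(SMALL_DESIGN, tmp_path / "a")
        second = generate_cohort(SMALL_DESIGN, tmp_path / "b")
        assert file_hashes(first) == file_hashes(second)

    def test_different_seed_changes_outputs(self, tmp_path):
        first = generate_cohort(SMALL_DESIGN, tmp_path / "a")
        second = generate_cohort(replace(SMALL_DESIGN, seed=12), tmp_path / "b")
        assert file_hashes(first)["cohort.vcf"] != file_hashes(second)["cohort.vcf"]


class TestDesignValidation:
    def test_demographic_marginals_match_design_exactly(self, canonical_cohort):
        subjects = read_subjects(canonical_cohort.subjects)
        assert len(subjects) == 383
        assert len({s.family_id for s in subjects.values()}) == 266
        ages = [s.age_class for s in subjects.values()]
        sexes = [s.sex for s in subjects.values()]
        assert ages.count("pediatric") == 156 and ages.count("adult") == 227
        assert sexes.count("F") == 193 and sexes.count("M") == 190

    def test_tiny_design_produces_requested_shapes(self, tmp_path):
        design = CohortDesign(
            n_subjects=3, n_families=3, n_pediatric=1, n_adult=2,
            n_female=2, n_male=1,
            n_rare_plp=0, n_rare_ci=2, n_rare_nr=2, n_rare_vus=1, n_rare_blb=0,
            n_ci_pass=0, n_nr_pass=0,
            n_decoy_offpanel=0, n_decoy_common=0, n_decoy_recurrent=0,
            n_decoy_lowquality=0, plant_table2=False, seed=5,
        )
        files = generate_cohort(design, tmp_path)
        header = [l for l in files.vcf.read_text().splitlines() if l.startswith("#CHROM")][0]
        assert len(header.split("\t")) == 9 + 3  # three sample columns
        sidecar = pd.read_csv(files.annotations, sep="\t")
        assert len(sidecar) == 5

    def test_inconsistent_design_rejected_before_writing(self, tmp_path):
        bad = replace(SMALL_DESIGN, n_pediatric=99)
        out = tmp_path / "out"
        with pytest.raises(ConfigError):
            generate_cohort(bad, out)
        assert not out.exists()

    def test_plant_requires_room_for_published_composition(self):
        with pytest.raises(ConfigError):
            CohortDesign(n_rare_plp=5).validate()


@pytest.fixture(scope="module")
def generated(tmp_path_factory):
    files = generate_cohort(SMALL_DESIGN, tmp_path_factory.mktemp("labeled"))
    variants, calls, _ = read_cohort(files.vcf, files.annotations, files.subjects)
    panel = Panel.from_tsv(files.panel)
    evidence = read_evidence(files.evidence)
    result = run_cascade(variants, calls, panel, SMALL_DESIGN.n_subjects,
                         evidence=evidence)
    labels = pd.read_csv(files.labels, sep="\t", dtype=str, keep_default_na=False)
    return result, labels


class TestLabeledOracle:

    def test_every_variant_meets_its_designed_filter_fate(self, generated):
        result, labels = generated
        stage_of = {
            "fail_panel": "panel",
            "fail_population": "population_frequency",
            "fail_cohort": "cohort_recurrence",
            "fail_quality": "call_quality",
        }
        for row in labels.itertuples(index=False):
            key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
            trace = result.traces[key]
            if row.label == "retained_prioritized":
                assert key in result.prioritized_keys, (key, row.label)
            elif row.label == "retained_only":
                assert key in result.retained_keys - result.prioritized_keys, key
            else:
                assert key not in result.retained_keys
                assert trace.first_failure.stage == stage_of[row.label], key

    def test_label_census_matches_design(self, generated):
        _, labels = generated
        counts = labels.label.value_counts().to_dict()
        assert counts["fail_panel"] == SMALL_DESIGN.n_decoy_offpanel
        assert counts["fail_population"] == SMALL_DESIGN.n_decoy_common
        assert counts["fail_cohort"] == SMALL_DESIGN.n_decoy_recurrent
        assert counts["fail_quality"] == SMALL_DESIGN.n_decoy_lowquality
        retained = counts["retained_prioritized"] + counts["retained_only"]
        assert retained == SMALL_DESIGN.n_rare_total
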