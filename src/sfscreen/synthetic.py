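"""Seeded synthetic-cohort generator.

Emulates the data structure of a 383-subject, 266-family clinical-exome
cohort screened against the 59-gene actionable panel: a multi-sample VCF,
an annotation sidecar, an evidence-code table, a panel file and a subjects
table. The canonical design plants the 21 published secondary-finding
variants (with their published annotation: HGVS, dbSNP id, gnomAD exome
frequency, ClinVar submission counts and curated ACMG evidence codes) into
a constructed carrier assignment, surrounded by background rare variation
whose ClinVar-group composition matches the published cohort (1213 retained
rare variants: 14 consensus-PLP, 283 conflicting, 406 unreported and 510
uncertain/benign), plus decoy variants designed to fail each filter stage.

Every generated variant carries a design label stating its intended filter
fate, so the filter cascade can be checked against a labeled oracle.
Genomic coordinates are synthetic (each gene owns a fixed 1-Mb window on a
deterministic chromosome); HGVS descriptions and annotations are the
authoritative content. Outputs are a pure function of (design, seed):
identical seeds give byte-identical files.

The carrier assignment is constructed, not observed: published cohort
aggregates fix the carrier and family totals but not which subject carries
which variant, so recurrence choices (e.g. which recessive alleles recur)
are plausible inventions constrained to reproduce every printed total
simultaneously while keeping each variant's carrier frequency at or below
the 1% cohort-recurrence bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .model import ClinVarProfile, GenomicVariant, PopulationFrequencies, PredictionProfile
from .panel import Panel, default_panel

FATE_LABELS = (
    "retained_prioritized",
    "retained_only",
    "fail_panel",
    "fail_population",
    "fail_cohort",
    "fail_quality",
)

_GENE_WINDOW = 900_000


def gene_locus(index: int) -> tuple[str, int]:
    """Deterministic synthetic locus for the gene with panel index ``index``."""
    return str(index % 22 + 1), (index + 1) * 1_000_000


def gene_loci(panel: Optional[Panel] = None) -> dict[str, tuple[str, int]]:
    panel = panel or default_panel()
    return {symbol: gene_locus(i) for i, symbol in enumerate(panel.symbols)}


# --------------------------------------------------------------------------
# The 21 planted secondary-finding variants and their published annotation.
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Table2Variant:
    """Annotation of one planted secondary-finding variant."""

    variant_id: str  # "<gene>:<hgvs_c short form>"
    gene: str
    offset: int  # position offset within the gene's synthetic window
    ref: str
    alt: str
    transcript: str
    hgvs_c: str
    hgvs_p: str
    dbsnp_id: str
    consequence: str
    intron_offset: int
    af_gnomad_exome: Optional[float]
    clinvar: ClinVarProfile
    acmg_codes: str


_FULLY_DELETERIOUS = PredictionProfile(
    cadd_phred=27.0,
    lrt="D",
    mutation_assessor="H",
    mutation_taster="D",
    polyphen2_hdiv="D",
    sift="D",
    fathmm="D",
)

TABLE2: tuple[Table2Variant, ...] = (
    # -- Class I expected -------------------------------------------------
    Table2Variant("ATP7B:c.2906G>A", "ATP7B", 2906, "G", "A", "NM_000053.4",
                  "NM_000053.4:c.2906G>A", "p.Arg969Gln", "rs121907996",
                  "missense", 0, 0.000036, ClinVarProfile(n_p=8),
                  "PM1,PM2,PM5,PP2,PP3,PP5"),
    Table2Variant("ATP7B:c.2519C>T", "ATP7B", 2519, "C", "T", "NM_000053.4",
                  "NM_000053.4:c.2519C>T", "p.Pro840Leu", "rs768671894",
                  "missense", 0, None, ClinVarProfile(n_p=8),
                  "PM2,PM5,PP2,PP3,PP5"),
    Table2Variant("ATP7B:c.51+4A>T", "ATP7B", 55, "A", "T", "NM_000053.4",
                  "NM_000053.4:c.51+4A>T", "", "rs369488210",
                  "intronic", 4, 0.000016, ClinVarProfile(n_p=10),
                  "PM2,PP3,PP5"),
    Table2Variant("DSP:c.4198C>T", "DSP", 4198, "C", "T", "NM_004415.4",
                  "NM_004415.4:c.4198C>T", "p.Arg1400*", "rs770873593",
                  "nonsense", 0, 0.000004, ClinVarProfile(n_p=3, n_lp=3),
                  "PVS1,PM2,PP5"),
    Table2Variant("FBN1:c.6739+1G>A", "FBN1", 6740, "G", "A", "NM_000138.5",
                  "NM_000138.5:c.6739+1G>A", "", "rs869025419",
                  "splice_essential", 1, None, ClinVarProfile(n_p=1, n_lp=1),
                  "PVS1,PM2,PP5"),
    Table2Variant("KCNH2:c.1129-2A>G", "KCNH2", 1127, "A", "G", "NM_000238.4",
                  "NM_000238.4:c.1129-2A>G", "", "rs794728365",
                  "splice_essential", -2, None, ClinVarProfile(n_p=2),
                  "PVS1,PM2,PP5"),
    Table2Variant("LDLR:c.465C>A", "LDLR", 465, "C", "A", "NM_000527.5",
                  "NM_000527.5:c.465C>A", "p.Cys155*", "rs766094434",
                  "nonsense", 0, 0.000004, ClinVarProfile(n_p=4),
                  "PVS1,PM2,PP5"),
    Table2Variant("LDLR:c.1775G>A", "LDLR", 1775, "G", "A", "NM_000527.5",
                  "NM_000527.5:c.1775G>A", "p.Gly592Glu", "rs137929307",
                  "missense", 0, 0.000044, ClinVarProfile(n_p=36),
                  "PS3,PM1,PM2,PM5,PP2,PP3,PP5"),
    Table2Variant("MSH6:c.3514dupA", "MSH6", 3514, "A", "AA", "NM_000179.3",
                  "NM_000179.3:c.3514dupA", "p.Arg1172Lysfs*5", "rs63751327",
                  "frameshift", 0, 0.000008, ClinVarProfile(n_p=12),
                  "PVS1,PM2,PP5"),
    Table2Variant("MUTYH:c.1103G>A", "MUTYH", 1103, "G", "A", "NM_001048174.2",
                  "NM_001048174.2:c.1103G>A", "p.Gly368Asp", "rs36053993",
                  "missense", 0, 0.003027, ClinVarProfile(n_p=32, n_lp=32),
                  "PS3,PM2,PM5,PP3,PP5"),
    Table2Variant("MUTYH:c.228C>A", "MUTYH", 228, "C", "A", "NM_001048174.2",
                  "NM_001048174.2:c.228C>A", "p.Tyr76*", "rs121908380",
                  "nonsense", 0, None, ClinVarProfile(n_p=12),
                  "PVS1,PM2,PP5"),
    Table2Variant("PTEN:c.475A>G", "PTEN", 475, "A", "G", "NM_000314.8",
                  "NM_000314.8:c.475A>G", "p.Arg159Gly", "rs786202688",
                  "missense", 0, None, ClinVarProfile(n_lp=3),
                  "PM1,PM2,PM5,PP2,PP3,PP5"),
    Table2Variant("RET:c.2410G>A", "RET", 2410, "G", "A", "NM_020975.6",
                  "NM_020975.6:c.2410G>A", "p.Val804Met", "rs79658334",
                  "missense", 0, None, ClinVarProfile(n_p=13, n_lp=12),
                  "PM2,PM5,PP2,PP3,PP5"),
    Table2Variant("RYR1:c.1841G>A", "RYR1", 1841, "G", "A", "NM_000540.3",
                  "NM_000540.3:c.1841G>A", "p.Arg614His", "rs193922772",
                  "missense", 0, 0.00002, ClinVarProfile(n_lp=2),
                  "PM2,PM5,PP3,PP5"),
    # -- Class II expected ------------------------------------------------
    Table2Variant("ATP7B:c.2605G>A", "ATP7B", 2605, "G", "A", "NM_000053.4",
                  "NM_000053.4:c.2605G>A", "p.Gly869Arg", "rs191312027",
                  "missense", 0, None, ClinVarProfile(n_p=10, n_lp=7, n_vus=1),
                  "PM1,PM2,PM5,PP2,PP3,PP5"),
    Table2Variant("LDLR:c.1003G>A", "LDLR", 1003, "G", "A", "NM_000527.5",
                  "NM_000527.5:c.1003G>A", "p.Gly335Ser", "rs544453230",
                  "missense", 0, None,
                  ClinVarProfile(n_p=2, n_lp=8, n_vus=1, n_lb=1),
                  "PM1,PM2,PM5,PP2,PP3,PP5"),
    Table2Variant("MUTYH:c.849+3A>C", "MUTYH", 852, "A", "C", "NM_001048174.2",
                  "NM_001048174.2:c.849+3A>C", "", "rs587780751",
                  "intronic", 3, 0.000076, ClinVarProfile(n_p=17, n_vus=1),
                  "PM2,PP3,PP5"),
    # -- Class III expected -----------------------------------------------
    Table2Variant("ACTA2:c.554G>A", "ACTA2", 554, "G", "A", "NM_001613.4",
                  "NM_001613.4:c.554G>A", "p.Arg185Gln", "rs1057521105",
                  "missense", 0, None, ClinVarProfile(n_lp=1, n_vus=1),
                  "PM1,PM2,PP2,PP3"),
    Table2Variant("ATP7B:c.19_20delCA", "ATP7B", 18, "ACA", "A", "NM_000053.4",
                  "NM_000053.4:c.19_20delCA", "p.Gln7Aspfs*14", "rs749363958",
                  "frameshift", 0, 0.000152,
                  ClinVarProfile(n_p=1, n_lp=3, n_vus=4), "PVS1,PM2,PP5"),
    Table2Variant("MYBPC3:c.2429G>A", "MYBPC3", 2429, "G", "A", "NM_000256.3",
                  "NM_000256.3:c.2429G>A", "p.Arg810His", "rs375675796",
                  "missense", 0, 0.000048, ClinVarProfile(n_lp=5, n_vus=3),
                  "PM1,PM2,PM5,PP3,PP5"),
    Table2Variant("DSP:c.6202_6205del", "DSP", 6201, "TACTG", "T", "NM_004415.4",
                  "NM_004415.4:c.6202_6205del", "p.Thr2068Serfs*5", "",
                  "frameshift", 0, None, ClinVarProfile(), "PVS1,PM2"),
)

TABLE2_BY_ID = {v.variant_id: v for v in TABLE2}


def table2_genomic_variant(entry: Table2Variant, loci: Optional[dict] = None) -> GenomicVariant:
    """Build the fully annotated variant for one planted entry."""
    loci = loci or gene_loci()
    chrom, start = loci[entry.gene]
    predictors = _FULLY_DELETERIOUS if entry.consequence == "missense" else PredictionProfile()
    return GenomicVariant(
        chrom=chrom,
        pos=start + entry.offset,
        ref=entry.ref,
        alt=entry.alt,
        gene=entry.gene,
        transcript=entry.transcript,
        hgvs_c=entry.hgvs_c,
        hgvs_p=entry.hgvs_p,
        consequence=entry.consequence,
        intron_offset=entry.intron_offset,
        dbsnp_id=entry.dbsnp_id,
        frequencies=PopulationFrequencies(af_gnomad_exome=entry.af_gnomad_exome),
        predictors=predictors,
        clinvar=entry.clinvar,
    )


def table2_variants() -> list[GenomicVariant]:
    """All 21 planted secondary findings as annotated variants."""
    loci = gene_loci()
    return [table2_genomic_variant(entry, loci) for entry in TABLE2]


#: Constructed carrier plan: variant id -> carrier slots. Slots beginning R
#: are subjects carrying a recessive-gene allele, slots beginning D carry
#: dominant/semidominant-gene alleles; R1 is the single dual-carrier subject.
DEFAULT_CARRIER_PLAN: dict[str, tuple[str, ...]] = {
    "ATP7B:c.2906G>A": ("R1", "R2"),
    "ATP7B:c.2519C>T": ("R1",),
    "ATP7B:c.51+4A>T": ("R3",),
    "ATP7B:c.2605G>A": ("R4",),
    "MUTYH:c.1103G>A": ("R5", "R6", "R7"),
    "MUTYH:c.228C>A": ("R8", "R9"),
    "MUTYH:c.849+3A>C": ("R10", "R11"),
    "ATP7B:c.19_20delCA": ("R12",),
    "LDLR:c.1775G>A": ("D1", "D2"),
    "DSP:c.4198C>T": ("D3", "D4"),
    "FBN1:c.6739+1G>A": ("D5",),
    "KCNH2:c.1129-2A>G": ("D6",),
    "LDLR:c.465C>A": ("D7",),
    "MSH6:c.3514dupA": ("D8",),
    "PTEN:c.475A>G": ("D9",),
    "RET:c.2410G>A": ("D10",),
    "RYR1:c.1841G>A": ("D11",),
    "LDLR:c.1003G>A": ("D12",),
    "ACTA2:c.554G>A": ("D13",),
    "MYBPC3:c.2429G>A": ("D14",),
    "DSP:c.6202_6205del": ("D15",),
}

#: Slot pairs that must share a family (high-evidence carrier pairs), and the
#: one family shared between a high-evidence and a moderate-evidence carrier.
_FAMILY_PAIRS = (("R1", "R2"), ("R5", "R6"), ("D1", "D2"), ("D3", "D4"))
_SHARED_FAMILY = ("D5", "D13")


def plant_table2(carrier_table: dict[str, tuple[str, ...]]) -> list[tuple[Table2Variant, tuple[str, ...]]]:
    """Resolve a carrier table (variant id -> carrier slots/subjects) against
    the planted variant annotations.

    Every planted genotype is heterozygous; depth and allele fraction are
    drawn near typical clinical-exome values (depth well above 20, fraction
    near one half) at generation time.
    """
    unknown = sorted(set(carrier_table) - set(TABLE2_BY_ID))
    if unknown:
        raise ConfigError(
            f"unknown planted variant id(s) {unknown}; valid ids: {sorted(TABLE2_BY_ID)}"
        )
    return [(TABLE2_BY_ID[vid], tuple(slots)) for vid, slots in carrier_table.items()]


# --------------------------------------------------------------------------
# Cohort design
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDesign:
    """Composition of a synthetic cohort.

    The rare-variant counts are totals over retained rare variants per
    ClinVar consensus group, including any planted variants; the generator
    plants the remainder as background. ``n_ci_pass``/``n_nr_pass`` are the
    background CI/NR variants constructed to survive prioritization (their
    curated evidence combines only to VUS, so they add no secondary
    finding). Decoy counts are variants constructed to fail one specific
    filter stage each.
    """

    n_subjects: int = 383
    n_families: int = 266
    n_pediatric: int = 156
    n_adult: int = 227
    n_female: int = 193
    n_male: int = 190
    n_rare_plp: int = 14
    n_rare_ci: int = 283
    n_rare_nr: int = 406
    n_rare_vus: int = 380
    n_rare_blb: int = 130
    n_ci_pass: int = 34
    n_nr_pass: int = 16
    n_decoy_offpanel: int = 15
    n_decoy_common: int = 12
    n_decoy_recurrent: int = 10
    n_decoy_lowquality: int = 8
    plant_table2: bool = True
    seed: int = 20221110

    @property
    def n_rare_total(self) -> int:
        return self.n_rare_plp + self.n_rare_ci + self.n_rare_nr + self.n_rare_vus + self.n_rare_blb

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_families < 1:
            raise ConfigError("cohort must have at least one subject and one family")
        if self.n_families > self.n_subjects:
            raise ConfigError("more families than subjects")
        if self.n_pediatric + self.n_adult != self.n_subjects:
            raise ConfigError("n_pediatric + n_adult must equal n_subjects")
        if self.n_female + self.n_male != self.n_subjects:
            raise ConfigError("n_female + n_male must equal n_subjects")
        for f in dc_fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 0:
                raise ConfigError(f"{f.name} must be >= 0")
        planted_ci = 6 if self.plant_table2 else 0
        planted_nr = 1 if self.plant_table2 else 0
        if self.plant_table2:
            if self.n_rare_plp < 14 or self.n_rare_ci < 6 or self.n_rare_nr < 1:
                raise ConfigError(
                    "planting the 21 canonical variants requires rare-variant "
                    "totals of at least PLP=14, CI=6, NR=1"
                )
            if self.n_subjects < 60 or self.n_families < 30:
                raise ConfigError(
                    "planting the canonical carrier plan requires at least "
                    "60 subjects in 30 families"
                )
        if self.n_ci_pass > self.n_rare_ci - planted_ci:
            raise ConfigError("n_ci_pass exceeds available background CI variants")
        if self.n_nr_pass > self.n_rare_nr - planted_nr:
            raise ConfigError("n_nr_pass exceeds available background NR variants")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortDesign":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"design file {path} must be a mapping")
        unknown = set(raw) - {f.name for f in dc_fields(cls)}
        if unknown:
            raise ConfigError(f"unknown design keys: {sorted(unknown)}")
        design = cls(**raw)
        design.validate()
        return design


@dataclass
class CohortFiles:
    """Paths of one generated fixture set."""

    out_dir: Path
    vcf: Path
    annotations: Path
    evidence: Path
    panel: Path
    subjects: Path
    labels: Path
    design: CohortDesign


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


@dataclass
class _Draft:
    """One variant being assembled, with its carriers and design label."""

    variant: GenomicVariant
    codes: str
    label: str
    carriers: list[tuple[int, int, int]] = field(default_factory=list)  # (subject_idx, depth, alt_reads)


def _family_sizes(design: CohortDesign) -> list[int]:
    sizes = [1] * design.n_families
    extra = design.n_subjects - design.n_families
    i = 0
    while extra > 0:
        sizes[i % design.n_families] += 1
        extra -= 1
        i += 1
    return sizes


def _deleterious_profile(rng: np.random.Generator) -> PredictionProfile:
    return PredictionProfile(
        cadd_phred=float(np.round(rng.uniform(21.0, 38.0), 1)),
        lrt="D",
        mutation_assessor=str(rng.choice(["H", "M"])),
        mutation_taster=str(rng.choice(["A", "D"])),
        polyphen2_hdiv=str(rng.choice(["D", "P"])),
        sift="D",
        fathmm="D",
    )


def _weak_profile(rng: np.random.Generator) -> PredictionProfile:
    """A missense profile with at most five deleterious votes."""
    n_votes = int(rng.integers(0, 6))
    flags = [True] * n_votes + [False] * (7 - n_votes)
    rng.shuffle(flags)
    benign = {
        "lrt": "N", "mutation_assessor": "L", "mutation_taster": "N",
        "polyphen2_hdiv": "B", "sift": "T", "fathmm": "T",
    }
    deleterious = {
        "lrt": "D", "mutation_assessor": "H", "mutation_taster": "D",
        "polyphen2_hdiv": "D", "sift": "D", "fathmm": "D",
    }
    tools = ["lrt", "mutation_assessor", "mutation_taster", "polyphen2_hdiv", "sift", "fathmm"]
    values = {"cadd_phred": float(np.round(rng.uniform(22.0, 30.0), 1)) if flags[0] else 8.0}
    for tool, flag in zip(tools, flags[1:]):
        values[tool] = deleterious[tool] if flag else benign[tool]
    return PredictionProfile(**values)


def _rare_frequencies(rng: np.random.Generator) -> PopulationFrequencies:
    values = {}
    for name in ("af_gnomad_exome", "af_gnomad_genome", "af_exac", "af_1000g"):
        if rng.random() < 0.7:
            values[name] = float(np.format_float_positional(
                10 ** rng.uniform(-6.0, -2.3), precision=6, fractional=False))
        else:
            values[name] = None
    return PopulationFrequencies(**values)


def _background_clinvar(group: str, rng: np.random.Generator) -> ClinVarProfile:
    if group == "NR":
        return ClinVarProfile()
    if group == "VUS":
        return ClinVarProfile(n_vus=int(rng.integers(1, 5)))
    if group == "BLB":
        n_b = int(rng.integers(0, 4))
        n_lb = int(rng.integers(0, 4))
        if n_b + n_lb == 0:
            n_b = 1
        return ClinVarProfile(n_b=n_b, n_lb=n_lb)
    if group == "CI":
        profile = ClinVarProfile(
            n_p=int(rng.integers(0, 7)),
            n_lp=int(rng.integers(0, 7)),
            n_vus=int(rng.integers(1, 5)),
            n_lb=int(rng.integers(0, 2)),
            n_b=int(rng.integers(0, 2)),
        )
        if profile.n_plp + profile.n_lb + profile.n_b == 0:
            profile = replace(profile, n_p=1)
        return profile
    if group == "PLP":
        n_p = int(rng.integers(0, 7))
        n_lp = int(rng.integers(0, 7))
        if n_p + n_lp < 2:
            n_p += 2
        return ClinVarProfile(n_p=n_p, n_lp=n_lp)
    raise ConfigError(f"unknown ClinVar group {group!r}")


def _good_call(rng: np.random.Generator, subject_idx: int) -> tuple[int, int, int]:
    depth = int(rng.integers(60, 201))
    alt = int(round(depth * rng.uniform(0.35, 0.60)))
    return subject_idx, depth, alt


def generate_cohort(design: CohortDesign, out_dir: str | Path) -> CohortFiles:
    """Generate the full fixture file set for one cohort design.

    Writes cohort.vcf, annotations.tsv, evidence.tsv, panel.tsv,
    subjects.tsv and design_labels.tsv into ``out_dir``. Raises before
    writing anything if the design is inconsistent.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    panel = default_panel()
    loci = gene_loci(panel)
    out = Path(out_dir)

    # ---- subjects and families ------------------------------------------
    sizes = _family_sizes(design)
    subject_ids = [f"S{i + 1:04d}" for i in range(design.n_subjects)]
    family_ids = [f"F{i + 1:04d}" for i in range(design.n_families)]
    family_of: list[int] = []
    members: list[list[int]] = [[] for _ in sizes]
    cursor = 0
    for fam_idx, size in enumerate(sizes):
        for _ in range(size):
            family_of.append(fam_idx)
            members[fam_idx].append(cursor)
            cursor += 1

    ages = np.array(["pediatric"] * design.n_pediatric + ["adult"] * design.n_adult)
    rng.shuffle(ages)
    sexes = np.array(["F"] * design.n_female + ["M"] * design.n_male)
    rng.shuffle(sexes)
    histories = rng.choice(["unknown", "negative", "positive"], size=design.n_subjects,
                           p=[0.7, 0.2, 0.1])

    # ---- carrier slots for the planted variants -------------------------
    slot_subject: dict[str, int] = {}
    if design.plant_table2:
        multi = [i for i, size in enumerate(sizes) if size >= 2]
        if len(multi) < 5:
            raise ConfigError("canonical plant needs at least five multi-member families")
        chosen_multi = list(rng.choice(multi, size=5, replace=False))
        pair_fams, shared_fam = chosen_multi[:4], chosen_multi[4]
        for (slot_a, slot_b), fam in zip(_FAMILY_PAIRS, pair_fams):
            slot_subject[slot_a] = members[fam][0]
            slot_subject[slot_b] = members[fam][1]
        slot_subject[_SHARED_FAMILY[0]] = members[shared_fam][0]
        slot_subject[_SHARED_FAMILY[1]] = members[shared_fam][1]
        single_slots = ["R3", "R4", "R7", "R8", "R9", "R10", "R11", "R12",
                        "D6", "D7", "D8", "D9", "D10", "D11", "D12", "D14", "D15"]
        available = [i for i in range(design.n_families) if i not in set(chosen_multi)]
        chosen_single = list(rng.choice(available, size=len(single_slots), replace=False))
        for slot, fam in zip(single_slots, chosen_single):
            slot_subject[slot] = members[fam][0]

    # ---- assemble variant drafts ----------------------------------------
    drafts: list[_Draft] = []
    used_keys: set[tuple[str, int]] = set()
    gene_cursor: dict[str, int] = {}

    def _next_position(gene: str, chrom: str, start: int) -> int:
        k = gene_cursor.get(gene, 0)
        while True:
            pos = start + 10_000 + k * 13
            k += 1
            if pos >= start + _GENE_WINDOW:
                raise ConfigError(f"gene window exhausted for {gene}")
            if (chrom, pos) not in used_keys:
                gene_cursor[gene] = k
                used_keys.add((chrom, pos))
                return pos

    bases = np.array(["A", "C", "G", "T"])

    def _snv_alleles() -> tuple[str, str]:
        ref, alt = rng.choice(bases, size=2, replace=False)
        return str(ref), str(alt)

    max_carriers = int(Fraction(1, 100) * design.n_subjects)  # 1% recurrence bar

    def _background(gene: str, group: str, fate: str) -> _Draft:
        chrom, start = loci[gene]
        pos = _next_position(gene, chrom, start)
        ref, alt = _snv_alleles()
        passes = fate == "retained_prioritized"
        if passes:
            consequence, offset, predictors = "missense", 0, _deleterious_profile(rng)
        else:
            shape = rng.choice(["weak_missense", "deep_intronic", "synonymous"],
                               p=[0.6, 0.25, 0.15])
            if shape == "weak_missense":
                consequence, offset, predictors = "missense", 0, _weak_profile(rng)
            elif shape == "deep_intronic":
                consequence = "intronic"
                offset = int(rng.integers(6, 41)) * int(rng.choice([-1, 1]))
                predictors = PredictionProfile()
            else:
                consequence, offset, predictors = "synonymous", 0, PredictionProfile()
        variant = GenomicVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{900000 + len(drafts):06d}.1",
            hgvs_c=f"c.{pos - start}{ref}>{alt}",
            hgvs_p="", consequence=consequence, intron_offset=offset,
            dbsnp_id="", frequencies=_rare_frequencies(rng),
            predictors=predictors, clinvar=_background_clinvar(group, rng),
        )
        label = fate
        n_carriers = int(rng.integers(1, 4))
        if max_carriers >= 1:
            n_carriers = min(n_carriers, max_carriers)
        else:
            label = "fail_cohort"
        codes = "PM2,PP3" if passes else ""
        draft = _Draft(variant, codes, label)
        for subject_idx in rng.choice(design.n_subjects, size=n_carriers, replace=False):
            draft.carriers.append(_good_call(rng, int(subject_idx)))
        return draft

    panel_symbols = panel.symbols

    if design.plant_table2:
        for entry, slots in plant_table2(DEFAULT_CARRIER_PLAN):
            variant = table2_genomic_variant(entry, loci)
            used_keys.add((variant.chrom, variant.pos))
            draft = _Draft(variant, entry.acmg_codes, "retained_prioritized")
            for slot in slots:
                depth = int(rng.integers(120, 165))
                alt_reads = int(round(depth * rng.uniform(0.45, 0.55)))
                draft.carriers.append((slot_subject[slot], depth, alt_reads))
            drafts.append(draft)

    planted_counts = {"PLP": 14, "CI": 6, "NR": 1} if design.plant_table2 else {}
    background_quota = {
        "PLP": design.n_rare_plp - planted_counts.get("PLP", 0),
        "CI": design.n_rare_ci - planted_counts.get("CI", 0),
        "NR": design.n_rare_nr - planted_counts.get("NR", 0),
        "VUS": design.n_rare_vus,
        "BLB": design.n_rare_blb,
    }
    passing_quota = {"CI": design.n_ci_pass, "NR": design.n_nr_pass,
                     "PLP": background_quota["PLP"]}

    for group in ("PLP", "CI", "NR", "VUS", "BLB"):
        n_pass = passing_quota.get(group, 0)
        total = background_quota[group]
        for i in range(total):
            gene = str(rng.choice(panel_symbols))
            fate = "retained_prioritized" if i < n_pass else "retained_only"
            drafts.append(_background(gene, group, fate))

    # ---- decoys ----------------------------------------------------------
    for i in range(design.n_decoy_offpanel):
        gene = f"NPNL{i + 1}"
        chrom, start = gene_locus(80 + i)
        pos = _next_position(gene, chrom, start)
        ref, alt = _snv_alleles()
        variant = GenomicVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{800000 + i:06d}.1", hgvs_c=f"c.{i + 1}{ref}>{alt}",
            consequence="missense", frequencies=_rare_frequencies(rng),
            predictors=_deleterious_profile(rng), clinvar=ClinVarProfile(),
        )
        draft = _Draft(variant, "", "fail_panel")
        draft.carriers.append(_good_call(rng, int(rng.integers(design.n_subjects))))
        drafts.append(draft)

    for i in range(design.n_decoy_common):
        gene = str(rng.choice(panel_symbols))
        chrom, start = loci[gene]
        pos = _next_position(gene, chrom, start)
        ref, alt = _snv_alleles()
        variant = GenomicVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{810000 + i:06d}.1", hgvs_c=f"c.{pos - start}{ref}>{alt}",
            consequence="missense",
            frequencies=PopulationFrequencies(
                af_gnomad_exome=float(np.round(rng.uniform(0.02, 0.3), 4))),
            predictors=_deleterious_profile(rng), clinvar=ClinVarProfile(),
        )
        draft = _Draft(variant, "", "fail_population")
        draft.carriers.append(_good_call(rng, int(rng.integers(design.n_subjects))))
        drafts.append(draft)

    recurrent_min = max_carriers + 2  # clearly above the 1% bar
    for i in range(design.n_decoy_recurrent):
        gene = str(rng.choice(panel_symbols))
        chrom, start = loci[gene]
        pos = _next_position(gene, chrom, start)
        ref, alt = _snv_alleles()
        variant = GenomicVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{820000 + i:06d}.1", hgvs_c=f"c.{pos - start}{ref}>{alt}",
            consequence="missense", frequencies=_rare_frequencies(rng),
            predictors=_deleterious_profile(rng), clinvar=ClinVarProfile(),
        )
        draft = _Draft(variant, "", "fail_cohort")
        n = int(rng.integers(recurrent_min, recurrent_min + 4))
        n = min(n, design.n_subjects)
        for subject_idx in rng.choice(design.n_subjects, size=n, replace=False):
            draft.carriers.append(_good_call(rng, int(subject_idx)))
        drafts.append(draft)

    for i in range(design.n_decoy_lowquality):
        gene = str(rng.choice(panel_symbols))
        chrom, start = loci[gene]
        pos = _next_position(gene, chrom, start)
        ref, alt = _snv_alleles()
        variant = GenomicVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"NM_{830000 + i:06d}.1", hgvs_c=f"c.{pos - start}{ref}>{alt}",
            consequence="missense", frequencies=_rare_frequencies(rng),
            predictors=_deleterious_profile(rng), clinvar=ClinVarProfile(),
        )
        draft = _Draft(variant, "", "fail_quality")
        subject_idx = int(rng.integers(design.n_subjects))
        if i % 2 == 0:
            depth = int(rng.integers(5, 21))  # depth <= 20 fails strictly
            draft.carriers.append((subject_idx, depth, depth // 2))
        else:
            draft.carriers.append((subject_idx, 40, 10))  # fraction exactly 0.25
        drafts.append(draft)

    # ---- write files -----------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    files = CohortFiles(
        out_dir=out,
        vcf=out / "cohort.vcf",
        annotations=out / "annotations.tsv",
        evidence=out / "evidence.tsv",
        panel=out / "panel.tsv",
        subjects=out / "subjects.tsv",
        labels=out / "design_labels.tsv",
        design=design,
    )

    panel.to_tsv(files.panel)

    with open(files.subjects, "w") as handle:
        handle.write("subject_id\tfamily_id\tage_class\tsex\topt_in\tfamily_history\n")
        for i, subject in enumerate(subject_ids):
            opt_in = "1" if ages[i] == "adult" else "0"
            handle.write(
                f"{subject}\t{family_ids[family_of[i]]}\t{ages[i]}\t{sexes[i]}"
                f"\t{opt_in}\t{histories[i]}\n"
            )

    drafts.sort(key=lambda d: (int(d.variant.chrom), d.variant.pos, d.variant.alt))

    from .io import write_annotations  # local import to avoid a cycle

    write_annotations([d.variant for d in drafts], files.annotations)

    with open(files.evidence, "w") as handle:
        handle.write("chrom\tpos\tref\talt\tcodes\n")
        for d in drafts:
            v = d.variant
            handle.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{d.codes}\n")

    with open(files.labels, "w") as handle:
        handle.write("chrom\tpos\tref\talt\tgene\tlabel\n")
        for d in drafts:
            v = d.variant
            handle.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.gene}\t{d.label}\n")

    with open(files.vcf, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write("##source=sfscreen-simulate (synthetic cohort; coordinates are synthetic)\n")
        for chrom in range(1, 23):
            handle.write(f"##contig=<ID={chrom},length=999000000>\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        handle.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        handle.write("\t".join(subject_ids))
        handle.write("\n")
        for d in drafts:
            v = d.variant
            samples = ["0/0:100:100,0"] * design.n_subjects
            for subject_idx, depth, alt_reads in d.carriers:
                samples[subject_idx] = f"0/1:{depth}:{depth - alt_reads},{alt_reads}"
            row = [v.chrom, str(v.pos), v.dbsnp_id or ".", v.ref, v.alt, ".", "PASS", ".",
                   "GT:DP:AD"] + samples
            handle.write("\t".join(row))
            handle.write("\n")

    return files


def table2_cohort(out_dir: str | Path, seed: int = 20221110) -> CohortFiles:
    """Generate the canonical fixture: default design, planted canonical
    variants, chosen seed."""
    return generate_cohort(replace(CohortDesign(), seed=seed), out_dir)
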