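"""The rare-variant prioritization funnel.

Stages, in order: restriction to the actionable-gene panel; population
frequency filter (< 1% in every database where the allele is present, with
fully absent alleles treated as novel and rare); cohort recurrence filter
(carrier frequency within the tested cohort itself, which removes recurrent
artifacts from low-mappability or homopolymeric regions); per-call quality
filter (read depth > 20 and alternate-allele fraction > 0.25, strictly); and
a final prioritization stage that keeps coding nonsynonymous SNVs on which
at least 6 of 7 in-silico predictors agree, essential splice-site variants,
near-exon intronic variants (within five intronic positions), and
protein-truncating variants, which bypass the missense predictor consensus.

Variants passing everything up to the quality stage are the "retained" rare
variants; the subset passing prioritization feeds the tiering stage. Every
inequality at a printed threshold is strict, and every verdict is recorded
in a per-variant trace for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import ConfigError, ModelError
from .model import (
    LOF_CONSEQUENCES,
    PREDICTOR_DELETERIOUS,
    GenomicVariant,
    PredictionProfile,
    SubjectCall,
    VariantKey,
)
from .panel import Panel

STAGES = (
    "panel",
    "population_frequency",
    "cohort_recurrence",
    "call_quality",
    "prioritization",
)

#: Stages whose joint pass defines a "retained" rare variant.
RETENTION_STAGES = STAGES[:4]


@dataclass(frozen=True)
class FilterConfig:
    population_af_max: float = 0.01  # exclusive: keep < 1%
    cohort_freq_max: Fraction = Fraction(1, 100)  # exclusive: drop > 1%
    min_depth: int = 20  # exclusive: keep > 20
    min_alt_fraction: float = 0.25  # exclusive: keep > 0.25
    cadd_min: float = 20.0  # exclusive: deleterious vote iff > 20
    predictor_quorum: int = 6  # of the 7 predictors
    intron_window: int = 5  # |offset| <= 5 kept

    def __post_init__(self) -> None:
        if not (0 < self.population_af_max <= 1):
            raise ConfigError("population_af_max must lie in (0, 1]")
        if not (0 < self.cohort_freq_max <= 1):
            raise ConfigError("cohort_freq_max must lie in (0, 1]")
        for name in ("min_depth", "min_alt_fraction", "cadd_min", "intron_window"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (1 <= self.predictor_quorum <= 7):
            raise ConfigError("predictor_quorum must lie in 1..7")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"filter config {path} must be a mapping")
        if "cohort_freq_max" in raw:
            raw["cohort_freq_max"] = Fraction(str(raw["cohort_freq_max"]))
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown filter config keys: {sorted(unknown)}")
        return cls(**raw)


DEFAULT_FILTER_CONFIG = FilterConfig()


@dataclass(frozen=True)
class StageVerdict:
    stage: str
    passed: bool
    reason: str


@dataclass
class FilterTrace:
    """Ordered per-variant record of stage verdicts.

    Evaluation stops at the first failing retention stage, so a removed
    variant has exactly one failing entry and it is the last one.
    """

    key: VariantKey
    verdicts: list[StageVerdict] = field(default_factory=list)

    def add(self, stage: str, passed: bool, reason: str) -> None:
        self.verdicts.append(StageVerdict(stage, passed, reason))

    @property
    def first_failure(self) -> Optional[StageVerdict]:
        for verdict in self.verdicts:
            if not verdict.passed:
                return verdict
        return None

    @property
    def retained(self) -> bool:
        return all(v.passed for v in self.verdicts if v.stage in RETENTION_STAGES) and any(
            v.stage == RETENTION_STAGES[-1] for v in self.verdicts
        )


def restrict_to_panel(
    variants: Iterable[GenomicVariant], panel: Panel
) -> list[GenomicVariant]:
    """Keep exactly the variants whose gene symbol is on the panel."""
    return [v for v in variants if v.gene in panel]


def population_frequency_filter(
    variant: GenomicVariant, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> tuple[bool, str]:
    """Pass iff the maximum frequency across present databases is < 1%.

    An allele absent from all four databases is novel, hence rare: pass.
    """
    max_af = variant.frequencies.max_af
    if max_af is None:
        return True, "absent from all population databases (novel)"
    if max_af < config.population_af_max:
        return True, f"max_af={max_af:g}<{config.population_af_max:g}"
    return False, f"max_af={max_af:g}>={config.population_af_max:g}"


def cohort_recurrence_filter(
    variant: GenomicVariant,
    subject_calls: Sequence[SubjectCall],
    n_subjects: int,
    config: FilterConfig = DEFAULT_FILTER_CONFIG,
) -> tuple[bool, str]:
    """Fail iff distinct carrier subjects exceed 1% of the tested cohort.

    Carrier counting (rather than allele counting) is the conservative
    reading; the two coincide for all-heterozygous data.
    """
    if n_subjects <= 0:
        raise ConfigError("n_subjects must be positive")
    carriers = len({c.subject_id for c in subject_calls})
    freq = Fraction(carriers, n_subjects)
    if freq > config.cohort_freq_max:
        return False, f"cohort_freq={carriers}/{n_subjects}>{config.cohort_freq_max}"
    return True, f"cohort_freq={carriers}/{n_subjects}<={config.cohort_freq_max}"


def quality_filter(
    call: SubjectCall, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> tuple[bool, str]:
    """Pass iff depth > 20 and alternate-allele fraction > 0.25 (both strict)."""
    if call.depth <= config.min_depth:
        return False, f"depth={call.depth}<={config.min_depth}"
    if call.alt_fraction <= config.min_alt_fraction:
        return False, f"alt_fraction={call.alt_fraction:g}<={config.min_alt_fraction:g}"
    return True, f"depth={call.depth}>{config.min_depth}, alt_fraction>{config.min_alt_fraction:g}"


def predictor_concordance(
    profile: PredictionProfile, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> tuple[int, bool]:
    """Count deleterious votes among the seven predictors and apply the quorum.

    Per-tool deleterious criteria: CADD Phred > 20, LRT D, MutationAssessor
    H or M, MutationTaster A or D, PolyPhen2-HumDiv D or P, SIFT D, FATHMM D.
    An absent prediction is not a deleterious vote; the quorum denominator
    stays at seven.
    """
    votes = 0
    if profile.cadd_phred is not None and profile.cadd_phred > config.cadd_min:
        votes += 1
    for tool, deleterious in PREDICTOR_DELETERIOUS.items():
        code = getattr(profile, tool)
        if code is not None and code in deleterious:
            votes += 1
    return votes, votes >= config.predictor_quorum


def noncoding_rule(
    variant: GenomicVariant, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> tuple[bool, str]:
    """Keep essential splice donor/acceptor variants and intronic variants
    within the intron window (five positions by default)."""
    if variant.consequence == "splice_essential":
        return True, f"essential splice site (offset {variant.intron_offset:+d})"
    if variant.consequence == "intronic":
        if abs(variant.intron_offset) <= config.intron_window:
            return True, f"intronic offset {variant.intron_offset:+d} within +/-{config.intron_window}"
        return False, f"intronic offset {variant.intron_offset:+d} outside +/-{config.intron_window}"
    raise ModelError(
        f"noncoding_rule applies to splice_essential/intronic variants, got {variant.consequence}"
    )


def _prioritize(
    variant: GenomicVariant,
    evidence: Mapping[VariantKey, frozenset[str]],
    config: FilterConfig,
) -> tuple[bool, str]:
    consequence = variant.consequence
    if consequence in LOF_CONSEQUENCES:
        return True, f"loss-of-function consequence ({consequence}) bypasses predictor consensus"
    if consequence == "inframe_indel":
        if "PVS1" in evidence.get(variant.key, frozenset()):
            return True, "inframe indel with PVS1 annotation bypasses predictor consensus"
        return False, "inframe indel without loss-of-function annotation"
    if consequence == "missense":
        votes, passed = predictor_concordance(variant.predictors, config)
        missing = sum(
            1 for name in ("cadd_phred", *PREDICTOR_DELETERIOUS) if getattr(variant.predictors, name) is None
        )
        note = f" ({missing} prediction(s) missing, counted non-deleterious)" if missing else ""
        if passed:
            return True, f"{votes}/7 predictors deleterious (quorum {config.predictor_quorum}){note}"
        return False, f"{votes}/7 predictors deleterious (<{config.predictor_quorum}){note}"
    if consequence in ("splice_essential", "intronic"):
        return noncoding_rule(variant, config)
    return False, f"consequence {consequence} has no prioritization path"


@dataclass
class CascadeResult:
    retained: list[GenomicVariant]
    prioritized: list[GenomicVariant]
    traces: dict[VariantKey, FilterTrace]

    @property
    def retained_keys(self) -> set[VariantKey]:
        return {v.key for v in self.retained}

    @property
    def prioritized_keys(self) -> set[VariantKey]:
        return {v.key for v in self.prioritized}


def run_cascade(
    variants: Sequence[GenomicVariant],
    calls: Sequence[SubjectCall],
    panel: Panel,
    n_subjects: int,
    config: FilterConfig = DEFAULT_FILTER_CONFIG,
    evidence: Optional[Mapping[VariantKey, frozenset[str]]] = None,
) -> CascadeResult:
    """Run the full funnel and record a trace for every input variant.

    A variant passes the call-quality stage when at least one of its carrier
    calls passes; carrier-level statistics downstream use only passing calls.
    The retained/prioritized sets are order-independent and the cascade is
    idempotent.
    """
    evidence = evidence or {}
    calls_by_key: dict[VariantKey, list[SubjectCall]] = {}
    for call in calls:
        calls_by_key.setdefault(call.variant_key, []).append(call)

    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    retained: list[GenomicVariant] = []
    prioritized: list[GenomicVariant] = []
    traces: dict[VariantKey, FilterTrace] = {}

    for variant in ordered:
        trace = FilterTrace(variant.key)
        traces[variant.key] = trace

        on_panel = variant.gene in panel
        trace.add("panel", on_panel, f"gene {variant.gene} {'on' if on_panel else 'not on'} panel")
        if not on_panel:
            continue

        passed, reason = population_frequency_filter(variant, config)
        trace.add("population_frequency", passed, reason)
        if not passed:
            continue

        variant_calls = calls_by_key.get(variant.key, [])
        passed, reason = cohort_recurrence_filter(variant, variant_calls, n_subjects, config)
        trace.add("cohort_recurrence", passed, reason)
        if not passed:
            continue

        if variant_calls:
            passing_calls = [c for c in variant_calls if quality_filter(c, config)[0]]
            passed = bool(passing_calls)
            reason = f"{len(passing_calls)}/{len(variant_calls)} carrier call(s) pass depth/alt-fraction"
        else:
            passed, reason = True, "no carrier calls to assess"
        trace.add("call_quality", passed, reason)
        if not passed:
            continue

        retained.append(variant)

        passed, reason = _prioritize(variant, evidence, config)
        trace.add("prioritization", passed, reason)
        if passed:
            prioritized.append(variant)

    return CascadeResult(retained, prioritized, traces)


def quality_passing_calls(
    calls: Sequence[SubjectCall], config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> list[SubjectCall]:
    return [c for c in calls if quality_filter(c, config)[0]]


def traces_to_rows(traces: Mapping[VariantKey, FilterTrace]) -> list[dict]:
    """Flatten traces for TSV export."""
    rows = []
    for key in sorted(traces):
        for verdict in traces[key].verdicts:
            rows.append(
                {
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "stage": verdict.stage,
                    "verdict": "pass" if verdict.passed else "fail",
                    "reason": verdict.reason,
                }
            )
    return rows
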