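"""Cohort-level aggregation of tier assignments and the end-to-end pipeline.

Turns per-variant tier assignments and carrier observations into the
headline screening statistics: unique secondary findings by evidence level,
subject- and family-level carrier rates, the dominant/recessive carrier
partition, and disease-domain composition. Percentages are exact rationals
rounded half-up to one decimal only at presentation time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import io as sfio
from .acmg import explain
from .errors import ConfigError, DataIntegrityError
from .filters import (
    DEFAULT_FILTER_CONFIG,
    CascadeResult,
    FilterConfig,
    quality_passing_calls,
    run_cascade,
    traces_to_rows,
)
from .model import GenomicVariant, SubjectCall, TierAssignment, VariantKey
from .panel import Panel
from .tiering import (
    DEFAULT_TIER_CONFIG,
    TierConfig,
    assign_tier,
    clinvar_group,
    plp_fraction,
)

logger = logging.getLogger(__name__)

DOMAIN_BASES = ("unique_variants", "carrier_subjects", "observations")


def round_half_up(value: Fraction | float, ndigits: int = 1) -> float:
    """Round half away from zero at the given decimal place, exactly."""
    if isinstance(value, Fraction):
        quotient = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        quotient = Decimal(repr(value))
    step = Decimal(1).scaleb(-ndigits)
    return float(quotient.quantize(step, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Exact percentage, rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        return 0.0
    return round_half_up(Fraction(100 * numerator, denominator), ndigits)


@dataclass
class CohortSummary:
    n_subjects: int = 0
    n_families: int = 0
    n_rare_variants: int = 0
    mean_rare_per_subject: float = 0.0
    clinvar_group_counts: dict[str, int] = field(default_factory=dict)
    n_prioritized_ci: int = 0
    n_prioritized_nr: int = 0
    n_unique_sf: int = 0
    n_sf_high: int = 0
    n_sf_moderate: int = 0
    n_subjects_with_sf: int = 0
    n_subjects_high: int = 0
    n_subjects_moderate_only: int = 0
    n_subjects_both_levels: int = 0
    pct_subjects_with_sf: float = 0.0
    pct_subjects_high: float = 0.0
    pct_subjects_moderate_only: float = 0.0
    n_families_with_sf: int = 0
    n_families_high: int = 0
    n_families_moderate: int = 0
    pct_families_with_sf: float = 0.0
    pct_families_high: float = 0.0
    pct_families_moderate: float = 0.0
    n_subjects_recessive_carrier: int = 0
    n_subjects_dominant: int = 0
    pct_recessive_carrier: float = 0.0
    pct_dominant: float = 0.0
    domain_composition: dict[str, float] = field(default_factory=dict)
    sf_per_subject_min: int = 0
    sf_per_subject_max: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _carriers_by_variant(
    assignments: Mapping[VariantKey, TierAssignment],
    calls: Sequence[SubjectCall],
) -> dict[VariantKey, list[SubjectCall]]:
    tiered = {k for k, a in assignments.items() if a.is_secondary_finding}
    carriers: dict[VariantKey, list[SubjectCall]] = {k: [] for k in tiered}
    for call in calls:
        if call.variant_key in carriers:
            carriers[call.variant_key].append(call)
    return carriers


def summarize(
    assignments: Mapping[VariantKey, TierAssignment],
    calls: Sequence[SubjectCall],
    subjects: Mapping[str, sfio.SubjectInfo],
    panel: Panel,
    variants: Optional[Mapping[VariantKey, GenomicVariant]] = None,
) -> CohortSummary:
    """Aggregate tier assignments into cohort statistics.

    Unique-finding counts are over variants; carrier counts are over
    distinct subjects (a dual carrier counts once per rate); family counts
    are over distinct family identifiers among carriers. A subject carrying
    findings at both evidence levels is counted once in the any-finding rate
    and once per level, with the overlap reported explicitly.
    """
    for call in calls:
        if call.subject_id not in subjects:
            raise DataIntegrityError(f"call references unknown subject {call.subject_id!r}")

    n_subjects = len(subjects)
    n_families = len({info.family_id for info in subjects.values()})

    carriers = _carriers_by_variant(assignments, calls)
    for key in carriers:
        if variants is not None and key not in variants:
            raise DataIntegrityError(f"assignment references unknown variant {key}")

    high_keys = {k for k, a in assignments.items() if a.evidence_level == "high"}
    moderate_keys = {k for k, a in assignments.items() if a.evidence_level == "moderate"}

    subjects_high = {c.subject_id for k in high_keys for c in carriers.get(k, [])}
    subjects_moderate = {c.subject_id for k in moderate_keys for c in carriers.get(k, [])}
    subjects_any = subjects_high | subjects_moderate
    families_high = {subjects[s].family_id for s in subjects_high}
    families_moderate = {subjects[s].family_id for s in subjects_moderate}
    families_any = families_high | families_moderate

    per_subject: dict[str, int] = {}
    for calls_for_variant in carriers.values():
        for c in {c.subject_id for c in calls_for_variant}:
            per_subject[c] = per_subject.get(c, 0) + 1

    recessive, dominant = inheritance_partition(assignments, calls, panel, variants)

    summary = CohortSummary(
        n_subjects=n_subjects,
        n_families=n_families,
        n_unique_sf=len(high_keys) + len(moderate_keys),
        n_sf_high=len(high_keys),
        n_sf_moderate=len(moderate_keys),
        n_subjects_with_sf=len(subjects_any),
        n_subjects_high=len(subjects_high),
        n_subjects_moderate_only=len(subjects_moderate - subjects_high),
        n_subjects_both_levels=len(subjects_high & subjects_moderate),
        pct_subjects_with_sf=percent(len(subjects_any), n_subjects),
        pct_subjects_high=percent(len(subjects_high), n_subjects),
        pct_subjects_moderate_only=percent(len(subjects_moderate - subjects_high), n_subjects),
        n_families_with_sf=len(families_any),
        n_families_high=len(families_high),
        n_families_moderate=len(families_moderate),
        pct_families_with_sf=percent(len(families_any), n_families),
        pct_families_high=percent(len(families_high), n_families),
        pct_families_moderate=percent(len(families_moderate), n_families),
        n_subjects_recessive_carrier=recessive,
        n_subjects_dominant=dominant,
        pct_recessive_carrier=percent(recessive, len(subjects_any)) if subjects_any else 0.0,
        pct_dominant=percent(dominant, len(subjects_any)) if subjects_any else 0.0,
        sf_per_subject_min=min(per_subject.values()) if per_subject else 0,
        sf_per_subject_max=max(per_subject.values()) if per_subject else 0,
    )
    assert summary.n_subjects_with_sf == (
        summary.n_subjects_high + summary.n_subjects_moderate_only
    ), "any-SF subjects must equal high plus moderate-only carriers"
    assert summary.n_families_with_sf <= summary.n_subjects_with_sf
    return summary


def _gene_of(key: VariantKey, variants: Mapping[VariantKey, GenomicVariant]) -> str:
    variant = variants.get(key)
    if variant is None:
        raise DataIntegrityError(f"assignment references unknown variant {key}")
    return variant.gene


def inheritance_partition(
    assignments: Mapping[VariantKey, TierAssignment],
    calls: Sequence[SubjectCall],
    panel: Panel,
    variants: Optional[Mapping[VariantKey, GenomicVariant]] = None,
) -> tuple[int, int]:
    """Partition carrier subjects by the inheritance mode of their findings.

    A subject is a recessive carrier iff at least one of their findings lies
    in an AR gene; a subject counts as dominant iff every finding lies in an
    AD or SD gene. Gene symbols are taken from the variant annotation when
    provided, else from the chromosome-keyed call lookup built here.
    """
    carriers = _carriers_by_variant(assignments, calls)
    genes_by_subject: dict[str, set[str]] = {}
    for key, variant_calls in carriers.items():
        if variants is not None:
            gene = _gene_of(key, variants)
        else:
            gene = _gene_from_panel_locus(key, panel)
        for call in variant_calls:
            genes_by_subject.setdefault(call.subject_id, set()).add(gene)

    recessive = 0
    dominant = 0
    for genes in genes_by_subject.values():
        mois = set()
        for gene in genes:
            entry = panel.get(gene)
            if entry is None:
                raise ConfigError(f"secondary-finding gene {gene!r} lacks a panel entry")
            mois.add(entry.moi)
        if "AR" in mois:
            recessive += 1
        elif mois <= {"AD", "SD"}:
            dominant += 1
    return recessive, dominant


def _gene_from_panel_locus(key: VariantKey, panel: Panel) -> str:
    # Fallback when no annotation map is supplied: resolve via the synthetic
    # gene windows (1 Mb per panel gene, deterministic order).
    from .synthetic import gene_locus

    for index, symbol in enumerate(panel.symbols):
        chrom, start = gene_locus(index)
        if key.chrom == chrom and start <= key.pos < start + 1_000_000:
            return symbol
    raise ConfigError(f"cannot resolve gene for variant {key}")


def domain_composition(
    assignments: Mapping[VariantKey, TierAssignment],
    panel: Panel,
    basis: str = "unique_variants",
    variants: Optional[Mapping[VariantKey, GenomicVariant]] = None,
    calls: Sequence[SubjectCall] = (),
) -> dict[str, Fraction]:
    """Share of each disease domain among the secondary findings.

    ``basis`` chooses the counting unit: unique tiered variants, distinct
    carrier subjects per domain, or carrier observations. Shares are exact
    rationals summing to one over represented domains. The published domain
    percentages match none of these denominators exactly; the basis is
    therefore explicit rather than tuned.
    """
    if basis not in DOMAIN_BASES:
        raise ConfigError(f"basis must be one of {DOMAIN_BASES}, got {basis!r}")
    tiered = {k for k, a in assignments.items() if a.is_secondary_finding}

    def domain_of(key: VariantKey) -> str:
        gene = (
            _gene_of(key, variants) if variants is not None else _gene_from_panel_locus(key, panel)
        )
        return panel.domain(gene)

    weights: dict[str, int] = {}
    if basis == "unique_variants":
        for key in tiered:
            weights[domain_of(key)] = weights.get(domain_of(key), 0) + 1
    else:
        carriers = _carriers_by_variant(assignments, calls)
        if basis == "carrier_subjects":
            seen: dict[str, set[str]] = {}
            for key in tiered:
                for call in carriers.get(key, []):
                    seen.setdefault(domain_of(key), set()).add(call.subject_id)
            weights = {d: len(s) for d, s in seen.items()}
        else:
            for key in tiered:
                for call in carriers.get(key, []):
                    weights[domain_of(key)] = weights.get(domain_of(key), 0) + 1
    total = sum(weights.values())
    if total == 0:
        return {}
    return {domain: Fraction(count, total) for domain, count in sorted(weights.items())}


@dataclass
class PipelineResult:
    variants: dict[VariantKey, GenomicVariant]
    calls: list[SubjectCall]
    rejected: list[VariantKey]
    cascade: CascadeResult
    groups: dict[VariantKey, str]
    acmg_classes: dict[VariantKey, str]
    assignments: dict[VariantKey, TierAssignment]
    records: list[sfio.SecondaryFindingRecord]
    summary: CohortSummary


def tier_prioritized(
    prioritized: Sequence[GenomicVariant],
    evidence: Mapping[VariantKey, frozenset[str]],
    tier_config: TierConfig = DEFAULT_TIER_CONFIG,
) -> tuple[dict[VariantKey, str], dict[VariantKey, str], dict[VariantKey, TierAssignment]]:
    """ClinVar-group, ACMG-combine and tier every prioritized variant."""
    groups: dict[VariantKey, str] = {}
    classes: dict[VariantKey, str] = {}
    assignments: dict[VariantKey, TierAssignment] = {}
    for variant in prioritized:
        key = variant.key
        group = clinvar_group(variant.clinvar)
        fraction = plp_fraction(variant.clinvar) if variant.clinvar.total > 0 else None
        acmg_class = explain(evidence.get(key, frozenset())).classification
        groups[key] = group
        classes[key] = acmg_class
        assignments[key] = assign_tier(
            group, fraction, acmg_class,
            n_submissions=variant.clinvar.total, config=tier_config,
        )
    return groups, classes, assignments


def run_pipeline(
    vcf_path: str | Path,
    annotation_path: str | Path,
    evidence_path: str | Path,
    panel_path: str | Path,
    out_dir: Optional[str | Path] = None,
    subjects_path: Optional[str | Path] = None,
    filter_config: FilterConfig = DEFAULT_FILTER_CONFIG,
    tier_config: TierConfig = DEFAULT_TIER_CONFIG,
) -> PipelineResult:
    """Read -> filter cascade -> ClinVar grouping -> ACMG combine -> tier ->
    summarize -> write. Logs per-stage counts; identical inputs give
    identical outputs."""
    panel = Panel.from_tsv(panel_path)
    variants, calls, rejected = sfio.read_cohort(vcf_path, annotation_path, subjects_path)
    logger.info("read %d variants, %d calls, %d rejected alleles",
                len(variants), len(calls), len(rejected))
    subjects = (
        sfio.read_subjects(subjects_path)
        if subjects_path is not None
        else {
            s: sfio.SubjectInfo(s, s, "adult", "F", False, "unknown")
            for s in sorted({c.subject_id for c in calls})
        }
    )
    evidence = sfio.read_evidence(evidence_path)

    cascade = run_cascade(variants, calls, panel, len(subjects), filter_config, evidence)
    logger.info("cascade retained %d rare variants, prioritized %d",
                len(cascade.retained), len(cascade.prioritized))

    group_counts: dict[str, int] = {}
    retained_groups: dict[VariantKey, str] = {}
    for variant in cascade.retained:
        group = clinvar_group(variant.clinvar)
        retained_groups[variant.key] = group
        group_counts[group] = group_counts.get(group, 0) + 1

    groups, classes, assignments = tier_prioritized(cascade.prioritized, evidence, tier_config)
    logger.info("tiered %d prioritized variants, %d secondary findings",
                len(assignments), sum(a.is_secondary_finding for a in assignments.values()))

    variant_map = {v.key: v for v in variants}
    good_calls = quality_passing_calls(calls, filter_config)
    summary = summarize(assignments, good_calls, subjects, panel, variant_map)
    summary.n_rare_variants = len(cascade.retained)
    summary.mean_rare_per_subject = round_half_up(
        Fraction(len(cascade.retained), len(subjects)), 1
    )
    summary.clinvar_group_counts = dict(sorted(group_counts.items()))
    summary.n_prioritized_ci = sum(
        1 for v in cascade.prioritized if retained_groups[v.key] == "CI"
    )
    summary.n_prioritized_nr = sum(
        1 for v in cascade.prioritized if retained_groups[v.key] == "NR"
    )
    summary.domain_composition = {
        domain: round_half_up(100 * share, 1)
        for domain, share in domain_composition(
            assignments, panel, "unique_variants", variant_map
        ).items()
    }

    carriers = _carriers_by_variant(assignments, good_calls)
    records = []
    for key, assignment in sorted(assignments.items()):
        if not assignment.is_secondary_finding:
            continue
        variant = variant_map[key]
        variant_calls = carriers.get(key, [])
        subject_ids = sorted({c.subject_id for c in variant_calls})
        family_ids = sorted({subjects[s].family_id for s in subject_ids})
        fraction = (
            str(plp_fraction(variant.clinvar)) if variant.clinvar.total > 0 else ""
        )
        records.append(
            sfio.SecondaryFindingRecord(
                chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                gene=variant.gene, transcript=variant.transcript,
                hgvs_c=variant.hgvs_c, hgvs_p=variant.hgvs_p,
                consequence=variant.consequence,
                clinvar_group=groups[key], plp_fraction=fraction,
                acmg_codes=",".join(sorted(evidence.get(key, frozenset()))),
                acmg_class=classes[key], tier=assignment.tier,
                evidence_level=assignment.evidence_level,
                n_carrier_subjects=len(subject_ids),
                carrier_subjects=";".join(subject_ids),
                families=";".join(family_ids),
                rationale="|".join(assignment.rationale),
            )
        )

    if out_dir is not None:
        sfio.write_report(records, summary.to_dict(), out_dir)
        trace_path = Path(out_dir) / "filter_traces.tsv"
        import pandas as pd

        pd.DataFrame(traces_to_rows(cascade.traces)).to_csv(trace_path, sep="\t", index=False)

    return PipelineResult(
        variants=variant_map,
        calls=calls,
        rejected=rejected,
        cascade=cascade,
        groups=groups,
        acmg_classes=classes,
        assignments=assignments,
        records=records,
        summary=summary,
    )
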