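"""Readers and writers for the pipeline's external formats.

Inputs: a multi-sample VCF (GT/DP/AD per sample), an annotation sidecar TSV
keyed by (chrom, pos, ref, alt), an optional subjects TSV carrying
family/demographic/consent attributes, an evidence-code TSV and a panel TSV.
Outputs: a per-variant secondary-findings TSV and a JSON cohort summary,
written so that re-reading reproduces the records exactly.

Annotations travel in a sidecar TSV rather than in VCF INFO fields so the
dialect is explicit and hermetic; the sidecar is authoritative for gene,
transcript and consequence assignment.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .acmg import parse_codes
from .errors import DataIntegrityError, SfScreenError, VcfParseError
from .model import (
    ClinVarProfile,
    GenomicVariant,
    PopulationFrequencies,
    PredictionProfile,
    SubjectCall,
    VariantKey,
)

SIDECAR_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c", "hgvs_p",
    "consequence", "intron_offset", "dbsnp_id",
    "af_gnomad_exome", "af_gnomad_genome", "af_exac", "af_1000g",
    "cadd_phred", "lrt", "mutation_assessor", "mutation_taster",
    "polyphen2_hdiv", "sift", "fathmm",
    "clinvar_p", "clinvar_lp", "clinvar_vus", "clinvar_lb", "clinvar_b",
]

SUBJECTS_COLUMNS = ["subject_id", "family_id", "age_class", "sex", "opt_in", "family_history"]


@dataclass(frozen=True)
class SubjectInfo:
    subject_id: str
    family_id: str
    age_class: str
    sex: str
    opt_in: bool
    family_history: str


def trim_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-trim an allele pair: remove shared suffix, then shared
    prefix (advancing pos), always keeping at least one base on each side.

    Full left-alignment against a reference genome is out of scope; the
    sidecar key is authoritative and uses the same trimming.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _opt_float(cell: str) -> Optional[float]:
    if cell is None or cell == "":
        return None
    value = float(cell)
    if math.isnan(value):
        return None
    return value


def _opt_str(cell: str) -> Optional[str]:
    return cell if cell not in (None, "") else None


def _int0(cell: str) -> int:
    return int(cell) if cell not in (None, "") else 0


def read_annotations(path: str | Path) -> dict[VariantKey, GenomicVariant]:
    """Read the sidecar TSV into fully annotated variants, keyed by allele."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SIDECAR_COLUMNS if c not in frame.columns]
    if missing:
        raise DataIntegrityError(f"annotation sidecar {path} lacks column(s) {missing}")
    variants: dict[VariantKey, GenomicVariant] = {}
    for row in frame.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in variants:
            raise DataIntegrityError(f"duplicate sidecar key {key}")
        variants[key] = GenomicVariant(
            chrom=key.chrom,
            pos=key.pos,
            ref=key.ref,
            alt=key.alt,
            gene=row.gene,
            transcript=row.transcript,
            hgvs_c=row.hgvs_c,
            hgvs_p=row.hgvs_p,
            consequence=row.consequence,
            intron_offset=_int0(row.intron_offset),
            dbsnp_id=row.dbsnp_id,
            frequencies=PopulationFrequencies(
                af_gnomad_exome=_opt_float(row.af_gnomad_exome),
                af_gnomad_genome=_opt_float(row.af_gnomad_genome),
                af_exac=_opt_float(row.af_exac),
                af_1000g=_opt_float(row.af_1000g),
            ),
            predictors=PredictionProfile(
                cadd_phred=_opt_float(row.cadd_phred),
                lrt=_opt_str(row.lrt),
                mutation_assessor=_opt_str(row.mutation_assessor),
                mutation_taster=_opt_str(row.mutation_taster),
                polyphen2_hdiv=_opt_str(row.polyphen2_hdiv),
                sift=_opt_str(row.sift),
                fathmm=_opt_str(row.fathmm),
            ),
            clinvar=ClinVarProfile(
                n_p=_int0(row.clinvar_p),
                n_lp=_int0(row.clinvar_lp),
                n_vus=_int0(row.clinvar_vus),
                n_lb=_int0(row.clinvar_lb),
                n_b=_int0(row.clinvar_b),
            ),
        )
    return variants


def write_annotations(variants: Iterable[GenomicVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        f, p, c = v.frequencies, v.predictors, v.clinvar

        def fmt(x):
            return "" if x is None else (f"{x:g}" if isinstance(x, float) else str(x))

        rows.append(
            [
                v.chrom, v.pos, v.ref, v.alt, v.gene, v.transcript, v.hgvs_c,
                v.hgvs_p, v.consequence, v.intron_offset, v.dbsnp_id,
                fmt(f.af_gnomad_exome), fmt(f.af_gnomad_genome), fmt(f.af_exac), fmt(f.af_1000g),
                fmt(p.cadd_phred), fmt(p.lrt), fmt(p.mutation_assessor), fmt(p.mutation_taster),
                fmt(p.polyphen2_hdiv), fmt(p.sift), fmt(p.fathmm),
                c.n_p, c.n_lp, c.n_vus, c.n_lb, c.n_b,
            ]
        )
    frame = pd.DataFrame(rows, columns=SIDECAR_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)


def read_subjects(path: str | Path) -> dict[str, SubjectInfo]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SUBJECTS_COLUMNS if c not in frame.columns]
    if missing:
        raise DataIntegrityError(f"subjects file {path} lacks column(s) {missing}")
    subjects: dict[str, SubjectInfo] = {}
    for row in frame.itertuples(index=False):
        if row.subject_id in subjects:
            raise DataIntegrityError(f"duplicate subject_id {row.subject_id!r}")
        subjects[row.subject_id] = SubjectInfo(
            subject_id=row.subject_id,
            family_id=row.family_id,
            age_class=row.age_class,
            sex=row.sex,
            opt_in=row.opt_in in ("1", "true", "True", "yes"),
            family_history=row.family_history,
        )
    return subjects


def read_evidence(path: str | Path) -> dict[VariantKey, frozenset[str]]:
    """Read the per-variant ACMG evidence-code table."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "pos", "ref", "alt", "codes"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataIntegrityError(f"evidence file {path} lacks column(s) {missing}")
    evidence: dict[VariantKey, frozenset[str]] = {}
    for row in frame.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), row.ref, row.alt)
        if key in evidence:
            raise DataIntegrityError(f"duplicate evidence key {key}")
        evidence[key] = parse_codes(row.codes)
    return evidence


def read_cohort(
    vcf_path: str | Path,
    annotation_path: str | Path,
    subjects_path: Optional[str | Path] = None,
) -> tuple[list[GenomicVariant], list[SubjectCall], list[VariantKey]]:
    """Read a multi-sample VCF and its annotation sidecar.

    Returns annotated variants (one per normalized alternate allele observed
    in the VCF), one SubjectCall per non-reference genotype, and the keys of
    VCF alleles missing from the sidecar (the reject list). Multi-allelic
    records are split; alleles are parsimony-trimmed before sidecar lookup.
    Without a subjects file each sample is treated as its own single-member
    family of unknown demographics (adult, not opted in).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise SfScreenError("cyvcf2 is required to read VCF input") from exc

    annotations = read_annotations(annotation_path)
    subjects = read_subjects(subjects_path) if subjects_path is not None else None

    try:
        reader = VCF(str(vcf_path))
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {vcf_path}: {exc}") from exc

    samples = list(reader.samples)
    if subjects is not None:
        unknown = [s for s in samples if s not in subjects]
        if unknown:
            raise DataIntegrityError(
                f"VCF sample(s) missing from subjects file: {unknown[:5]}"
            )

    variants: list[GenomicVariant] = []
    calls: list[SubjectCall] = []
    rejects: list[VariantKey] = []
    seen: set[VariantKey] = set()

    try:
        for record in reader:
            alts = record.ALT
            if not alts:
                continue
            genotypes = record.genotypes  # [a0, a1, phased] per sample
            ad = record.format("AD")
            dp = record.format("DP")
            for alt_index, alt in enumerate(alts, start=1):
                pos, ref, allele = trim_allele(record.POS, record.REF, alt)
                key = VariantKey(str(record.CHROM), pos, ref, allele)
                annotated = annotations.get(key)
                if annotated is None:
                    if key not in seen:
                        rejects.append(key)
                        seen.add(key)
                    continue
                if key not in seen:
                    variants.append(annotated)
                    seen.add(key)
                for sample_index, sample in enumerate(samples):
                    gt = genotypes[sample_index]
                    allele_calls = [a for a in gt[:-1] if a is not None and a >= 0]
                    n_alt = sum(1 for a in allele_calls if a == alt_index)
                    if n_alt == 0:
                        continue
                    depth = 0
                    if dp is not None:
                        depth = max(int(dp[sample_index][0]), 0)
                    alt_reads = 0
                    if ad is not None and ad.shape[1] > alt_index:
                        alt_reads = max(int(ad[sample_index][alt_index]), 0)
                    fraction = alt_reads / depth if depth > 0 else 0.0
                    info = subjects.get(sample) if subjects is not None else None
                    calls.append(
                        SubjectCall(
                            subject_id=sample,
                            family_id=info.family_id if info else sample,
                            chrom=key.chrom,
                            pos=key.pos,
                            ref=key.ref,
                            alt=key.alt,
                            genotype="hom" if n_alt >= 2 else "het",
                            depth=depth,
                            alt_fraction=min(fraction, 1.0),
                            age_class=info.age_class if info else "adult",
                            sex=info.sex if info else "F",
                        )
                    )
    except SfScreenError:
        raise
    except Exception as exc:
        raise VcfParseError(f"error while parsing VCF {vcf_path}: {exc}") from exc

    return variants, calls, rejects


REPORT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c", "hgvs_p",
    "consequence", "clinvar_group", "plp_fraction", "acmg_codes", "acmg_class",
    "tier", "evidence_level", "n_carrier_subjects", "carrier_subjects",
    "families", "rationale",
]


@dataclass(frozen=True)
class SecondaryFindingRecord:
    """One prioritized secondary finding as written to the report TSV."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    hgvs_c: str
    hgvs_p: str
    consequence: str
    clinvar_group: str
    plp_fraction: str  # exact rational as text, e.g. "17/18"; "" if undefined
    acmg_codes: str
    acmg_class: str
    tier: str
    evidence_level: str
    n_carrier_subjects: int
    carrier_subjects: str  # ";"-joined subject ids
    families: str  # ";"-joined family ids
    rationale: str  # "|"-joined rule clauses


def write_report(
    records: Iterable[SecondaryFindingRecord],
    summary: dict,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write secondary_findings.tsv and cohort_summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv_path = out / "secondary_findings.tsv"
    json_path = out / "cohort_summary.json"

    rows = [asdict(r) for r in records]
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(tsv_path, sep="\t", index=False)

    with open(json_path, "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return tsv_path, json_path


def read_report(out_dir: str | Path) -> tuple[list[SecondaryFindingRecord], dict]:
    out = Path(out_dir)
    frame = pd.read_csv(out / "secondary_findings.tsv", sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in frame.itertuples(index=False):
        values = dict(zip(REPORT_COLUMNS, row))
        values["pos"] = int(values["pos"])
        values["n_carrier_subjects"] = int(values["n_carrier_subjects"])
        records.append(SecondaryFindingRecord(**values))
    with open(out / "cohort_summary.json") as handle:
        summary = json.load(handle)
    return records, summary
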