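# Methods

`sfscreen` implements opportunistic genomic screening for medically
actionable secondary findings (SFs): given multi-sample clinical-exome
variant data, it restricts analysis to an actionable-gene panel, filters to
rare, well-supported variants, classifies each survivor by combining curated
ACMG/AMP evidence codes and by scoring the consensus of ClinVar submissions,
ranks findings into three classes, and aggregates carrier statistics over
the cohort. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic cohort does and does not emulate.

## The screening model

A secondary finding is a pathogenic or likely pathogenic variant in a
medically actionable gene, deliberately sought in sequencing data generated
for an unrelated indication. The screen proceeds in five stages.

**1. Panel restriction.** Variants are kept only in genes of the screening
panel. The default panel is the 59-gene ACMG secondary-findings v2.0 list,
shipped as a TSV with one mode of inheritance (AD, AR, XL, or SD for the
semidominant hypercholesterolemia genes) and one disease domain per gene.
Alternative panels (e.g. the later 73-gene update) are plain TSV drop-ins.

**2. Frequency filters.** A variant is rare when its alternate-allele
frequency is below 1% in every population database where it is present
(gnomAD exome, gnomAD genome, ExAC, 1000 Genomes); an allele absent from
all four is novel and therefore rare. A second, within-cohort filter
removes variants whose distinct-carrier frequency exceeds 1% of tested
subjects — these are overwhelmingly recurrent artifacts from low-mappability
or homopolymeric regions. Carriers rather than alleles are counted; for
all-heterozygous data the two coincide, and carrier counting is the more
conservative reading. Both comparisons are strict, and the cohort
comparison is done on exact rationals (`Fraction(carriers, n_subjects) >
1/100`), so 4 carriers of 383 (1.04%) fail while 3 of 383 (0.78%) pass.

**3. Call quality.** A carrier call is trusted when read depth exceeds 20
and the alternate-allele read fraction exceeds 0.25, both strictly; a
variant passes when at least one of its carrier calls does. Depth 20 or
fraction 0.25 exactly fail. Downstream carrier statistics use only passing
calls.

**4. Prioritization.** The route depends on consequence class:

- *missense*: at least 6 of 7 in-silico predictors must call the variant
  deleterious — CADD Phred > 20 (strict), LRT D, MutationAssessor H or M,
  MutationTaster A or D, PolyPhen-2 HumDiv D or P, SIFT D, FATHMM D. An
  absent prediction is a non-deleterious vote and the denominator stays at
  7; the trace records how many predictions were missing.
- *splice-essential* (intron positions ±1/±2): kept unconditionally.
- *intronic*: kept when within five intronic positions of an exon
  (|offset| ≤ 5, HGVS sign convention).
- *nonsense and frameshift*: kept unconditionally. Predictor consensus is a
  missense instrument, so protein-truncating variants bypass it; without
  this route no truncating finding could survive, contradicting the
  reference classification this pipeline reproduces. Inframe indels take
  the bypass only when their curated evidence contains PVS1.
- *synonymous and other*: never prioritized.

**5. Classification and ranking** (below).

Every variant receives an ordered trace of stage verdicts; evaluation stops
at the first failing retention stage, so each removed variant has exactly
one recorded failure. Retention (stages 1–4 minus prioritization) defines
the "rare variant" set; prioritization defines the candidates for ranking.

## ACMG/AMP evidence combining

Evidence codes (PVS1; PS1–PS4; PM1–PM6; PP1–PP5; BA1; BS1–BS4; BP1–BP7) are
an *input*: the screen models a workflow in which a geneticist curates codes
per variant, and the engine only combines them. The combining table is the
published rule set, shipped as a human-readable TSV
(`data/combining_rules_v1.tsv`) of clauses over strength counts, e.g.
`PVS>=1,PM>=1,PP>=1 → P`. Precedence is P over LP and B over LB; clauses
firing on both sides are contradictory and yield VUS; with no firing clause
the result falls back to VUS.

One extension is the **VUS-LP** ("VUS-favor pathogenic") sublabel used by
the three-class ranking: at least one PM and two PP, no benign code, and no
LP/P clause firing. This is the weakest rule covering the evidence profiles
({PM2, PP3, PP5}) that the reference classification labels VUS-LP, and it is
isolated in a single swappable clause. Strength modulation of individual
codes (e.g. PVS1 downgrading) is deliberately out of scope.

The engine is verified two ways: exhaustively against an independently
written literal transcription of the rule text (all ~5,000 configurations
with ≤1 PVS, ≤2 PS, ≤5 PM, ≤5 PP, ≤1 BA, ≤2 BS, ≤3 BP), and by regression
over the 21 reference evidence rows.

## ClinVar consensus and the three-class ranking

ClinVar is consumed as a version-pinned snapshot of per-category submission
counts (P, LP, VUS, LB, B), not queried live, so results are hermetic. The
profile reduces to one consensus group: **NR** (no submissions), **PLP**
(all P/LP), **BLB** (all B/LB), **VUS** (all uncertain), **CI** (two or more
distinct categories). For reported variants the *PLP fraction* is the exact
rational share of P/LP submissions.

Tiers, evaluated with precedence I > II > III:

| Class | Rule | Evidence |
|---|---|---|
| I | ClinVar PLP (≥2 submissions) and ACMG P/LP/VUS-LP | high |
| II | ClinVar CI, PLP fraction > 4/5, ACMG P/LP/VUS-LP | high |
| III | ClinVar CI, fraction ≥ 1/2, ACMG P/LP/VUS-LP; or ClinVar NR and ACMG P/LP | moderate |

Three boundary decisions deserve note. First, the CI bands overlap as
written (≥50% includes >80%); precedence makes them a partition: II above
4/5, III on [1/2, 4/5], nothing below 1/2. Fractions are exact rationals,
so 4/5 exactly is Class III. Second, VUS-LP is accepted wherever the class
rules say "PLP" for Classes II–III, because the reference classification
places a VUS-LP variant in Class II; Class I states the wider acceptance
explicitly. Third, an NR variant whose ACMG class is only VUS-LP gets no
tier, and a consensus-PLP annotation resting on a single submission is
demoted to no tier unless `TierConfig(min_plp_submissions=1)` relaxes it.

**Reporting.** Findings are communicated only to adults with opt-in
consent. Classes I–II are then reported outright; Class III is reported
with a positive family history and otherwise held pending family-history
re-evaluation ("dynamic" consent). Demographics affect only this reporting
decision, never detection or tiering.

## Cohort aggregation

Unique-finding counts are over variants; carrier rates over distinct
subjects (a dual carrier counts once per rate); family rates over distinct
family identifiers among carriers. A subject is a *recessive carrier* when
at least one finding lies in an AR gene, and *dominant* when all findings
lie in AD/SD genes. Percentages are exact rationals rounded half-up to one
decimal only at presentation (27/383 → 7.0, 22/266 → 8.3, 12/27 → 44.4).

Disease-domain composition takes an explicit `basis` parameter
(unique variants, carrier subjects, or carrier observations) because no
single denominator is canonical; with the canonical fixture and the
unique-variant basis, cancer predisposition is 6/21, cardiac disorders
4/21, familial hypercholesterolemia 3/21. Published domain percentages for
this kind of screen are often computed on an unstated denominator; the
parameter surfaces the choice instead of hard-coding one.

## The synthetic cohort

No real genotypes ship with the package (clinical cohorts of this kind are
not publishable), so the generator builds one from a declarative
`CohortDesign`: 383 subjects in 266 families (156 pediatric / 227 adult,
193 female / 190 male) by default, with family sizes of 1–2 members.

- **Planted findings.** The 21 reference secondary findings are planted
  with their published annotation verbatim: HGVS, transcript, dbSNP id,
  gnomAD exome frequency where given, ClinVar submission counts, and
  curated evidence codes. Where a published count covers P and LP jointly
  ("PLP (n)"), the split is an even synthetic one — the consensus group and
  fraction are invariant to it. Planted calls are heterozygous with depth
  120–165 and allele fraction near one half.
- **Carrier assignment.** The published aggregates fix totals (27 carrier
  subjects in 22 families; 23 high-evidence subjects in 19 families; one
  dual carrier of two ATP7B alleles; 12 recessive-allele carriers; 13
  recessive-gene observations) but not the subject-to-variant map. The
  shipped plan is a constructed assignment satisfying all of them
  simultaneously: four high-evidence carrier pairs share families, one
  family contains both a high- and a moderate-evidence carrier, and
  recessive recurrences are MUTYH c.1103G>A ×3 and c.228C>A ×2 —
  recurrence choices are invented, and chosen so that every variant's
  carrier count stays at or below the 1% cohort-recurrence bar (4 carriers
  of 383 would be filtered out by the pipeline's own rule).
- **Background variation.** Retained rare variants total 1213 (14
  consensus-PLP, 283 CI, 406 NR, and 510 VUS+BLB split 380/130 — the
  VUS/BLB split is a free choice; only the sum is constrained). Of the
  background CI and NR variants, 34 and 16 respectively are built to pass
  prioritization (fully concordant missense) but carry evidence combining
  only to VUS, so they are prioritized without adding findings: 34 + 6
  planted CI = 40 prioritized CI, 16 + 1 planted NR = 17 prioritized NR.
  All cohort-level counts are therefore *computed* outcomes of the rule
  implementations, not planted answers.
- **Decoys.** Each generated cohort also contains variants constructed to
  fail exactly one stage (off-panel, population-common, cohort-recurrent,
  low-quality, non-prioritizable), and every variant carries a design label
  of its intended fate. A labeled-oracle test asserts the cascade realizes
  every fate.
- **Determinism.** Outputs are a pure function of (design, seed):
  identical seeds give byte-identical files. The seed moves only positions,
  alleles, carrier identities and nuisance profiles — never a designed
  filter fate — so the cohort aggregates are seed-invariant by
  construction.

What the generator does **not** emulate: read-level data, linkage and
haplotype structure, population-genetic realism beyond marginal
frequencies, genotype errors, or real genomic coordinates (each gene owns a
synthetic 1-Mb window; HGVS strings carry the real identity). Passing
end-to-end tests therefore demonstrates that the *rules* reproduce the
reference results on faithful inputs, not that the pipeline is robust to
upstream calling artifacts.

## Numerical and interface choices

- Coordinates are 1-based VCF; multi-allelic records are split and alleles
  parsimony-trimmed (shared suffix, then shared prefix). Full
  left-alignment needs a reference genome and is out of scope; the
  annotation sidecar key is authoritative and uses the same trimming.
- All printed thresholds are strict comparisons; frequency and fraction
  thresholds are exact rationals end to end (no floating-point boundary
  surprises at 0.8, 0.5, 1%).
- Annotations travel in a sidecar TSV (documented header, empty cell =
  absent) rather than VCF INFO, keeping the dialect explicit; the VCF
  carries only genotypes, depths and allele depths.
- A VCF allele with no sidecar row goes to a reject list rather than
  aborting the run; duplicate sidecar keys abort with an integrity error.
- Subjects (family, age class, sex, consent, family history) travel in
  their own TSV; without it, each sample is its own adult, non-consented
  single-member family, which zeroes reporting but leaves detection intact.

## Known limitations and open discrepancies

- Evidence-code curation is manual by design; the package never derives
  codes from annotations.
- Whether repeated submissions from one ClinVar submitter should be
  deduplicated before the consensus fraction is unspecified upstream;
  counts are used as given.
- Aggregates reported for this kind of screen contain two internal
  tensions that this package surfaces rather than resolves: the count of
  ACMG-PLP findings among prioritized CI/NR variants (7 + 1 as prose, 6 + 1
  by the reference table; the table is followed), and disease-domain
  percentages whose denominator matches no basis computable from the
  findings table (hence the explicit `basis` parameter).
- The default test and acceptance runs use the full-size design (383
  subjects, ~1250 variants); generation plus the end-to-end screen takes
  about one second, so no scaled-down problem size is needed.
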