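# sfscreen

Opportunistic genomic screening for medically actionable **secondary
findings** (SFs): variants in actionable genes — cancer predisposition,
cardiomyopathies and arrhythmias, familial hypercholesterolemia, Wilson
disease, malignant hyperthermia — deliberately sought in clinical-exome
data that was generated for an unrelated diagnostic question.

The package is for molecular geneticists and bioinformaticians who want a
tested, reproducible implementation of such a screen: a rare-variant filter
cascade, an ACMG/AMP evidence-combining engine, ClinVar
submission-consensus scoring, a three-class SF ranking with reporting
rules, cohort-level summaries, and a seeded synthetic-cohort generator for
end-to-end validation.

## The screen

Given a multi-sample VCF (GT/DP/AD), an annotation sidecar and a gene
panel, a variant survives to ranking when it passes:

1. **panel** — gene on the actionable panel (59-gene ACMG SF v2.0 list by
   default; any `symbol / moi / domain` TSV works);
2. **population frequency** — AF < 1% in every database where present
   (gnomAD exome/genome, ExAC, 1000 Genomes); absent everywhere = novel =
   rare;
3. **cohort recurrence** — distinct-carrier frequency within the tested
   cohort ≤ 1% (removes recurrent mapping artifacts);
4. **call quality** — depth > 20 and alternate-allele fraction > 0.25
   (strict) for at least one carrier call;
5. **prioritization** — missense: ≥ 6/7 in-silico predictors deleterious
   (CADD Phred > 20, LRT D, MutationAssessor H–M, MutationTaster A–D,
   PolyPhen-2 HumDiv D–P, SIFT D, FATHMM D); splice-essential: kept;
   intronic: |offset| ≤ 5; nonsense/frameshift: kept (LoF bypass).

Curated ACMG/AMP evidence codes are then combined by the published rule
table into {P, LP, VUS-LP, VUS, LB, B}, ClinVar submission counts reduce to
a consensus group (PLP / CI / NR / VUS / BLB) with an exact-rational PLP
fraction, and each variant lands in a class:

| Class | Rule | Reporting |
|---|---|---|
| I | ClinVar PLP (≥2 submissions), ACMG P/LP/VUS-LP | report (adult, opt-in) |
| II | ClinVar CI, PLP fraction > 80%, ACMG P/LP/VUS-LP | report (adult, opt-in) |
| III | ClinVar CI, fraction ≥ 50%, ACMG P/LP/VUS-LP; or NR with ACMG P/LP | only with positive family history |

See `docs/methods.md` for the full model, parameter defaults and design
rationale.

## Worked example

```python
from sfscreen import (assign_tier, clinvar_group, combine, parse_codes,
                      plp_fraction, ClinVarProfile)

profile = ClinVarProfile(n_p=10, n_lp=7, n_vus=1)   # 18 submissions
group = clinvar_group(profile)                      # 'CI'  (conflicting)
fraction = plp_fraction(profile)                    # Fraction(17, 18)
acmg = combine(parse_codes("PM1,PM2,PM5,PP2,PP3,PP5"))  # 'LP' (3 PM rule)
tier = assign_tier(group, fraction, acmg, n_submissions=profile.total)
print(group, fraction, acmg, tier.tier)
```

prints

```
CI 17/18 LP II
```

i.e. a conflicting-interpretation variant whose pathogenic share (17/18 ≈
94%) clears the 80% bar and whose evidence combines to likely pathogenic:
a Class II finding, reportable to a consenting adult.

Running the whole screen on the canonical synthetic cohort
(`python examples/04_end_to_end_cohort_screen.py`) prints:

```
subjects: 383 in 266 families
retained rare variants: 1213 (3.2 per subject)
ClinVar census of retained variants: {'BLB': 130, 'CI': 283, 'NR': 406, 'PLP': 14, 'VUS': 380}
prioritized: 40 CI + 17 NR variants
unique secondary findings: 21 (17 high evidence, 4 moderate)
subjects with a finding: 27 (7.0%); high evidence 6.0%, moderate only 1.0%
families with a finding: 22 (8.3%)
recessive-allele carriers among finding subjects: 12 (44.4%), dominant-only: 15
findings per carrier subject: 1-2
```

Each `examples/*.py` script demonstrates one capability (evidence
combining, consensus tiering, the filter cascade, the end-to-end screen,
reporting decisions) and prints what the numbers mean.

## Command line

```bash
sfscreen simulate --seed 7 --out cohort/          # synthetic fixture set
sfscreen filter   --vcf cohort/cohort.vcf --annotations cohort/annotations.tsv \
                  --subjects cohort/subjects.tsv  # cascade counts
sfscreen classify --evidence cohort/evidence.tsv  # ACMG combining per variant
sfscreen run      --vcf cohort/cohort.vcf --annotations cohort/annotations.tsv \
                  --evidence cohort/evidence.tsv --panel cohort/panel.tsv \
                  --subjects cohort/subjects.tsv --out report/
```

`run` writes `secondary_findings.tsv` (one row per finding with consensus
group, fraction, codes, class, tier, carriers and rule rationale),
`cohort_summary.json` and `filter_traces.tsv`.

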