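"""Tier the 21 reference secondary findings from their ClinVar submission
counts and curated evidence codes.

For each variant: the ClinVar consensus group (PLP / CI / NR / ...), the
exact share of pathogenic submissions, the combined ACMG class, and the
resulting secondary-finding class. Classes I-II carry high evidence of
pathogenicity (reportable to consenting adults); Class III carries moderate
evidence (reportable only with positive family history).
"""

from sfscreen import assign_tier, clinvar_group, combine, parse_codes, plp_fraction
from sfscreen.synthetic import TABLE2

print(f"{'variant':22s} {'group':6s} {'plp_frac':>9s} {'acmg':7s} tier")
for entry in TABLE2:
    group = clinvar_group(entry.clinvar)
    fraction = plp_fraction(entry.clinvar) if entry.clinvar.total else None
    acmg_class = combine(parse_codes(entry.acmg_codes))
    tier = assign_tier(group, fraction, acmg_class,
                       n_submissions=entry.clinvar.total).tier
    frac_text = str(fraction) if fraction is not None else "-"
    print(f"{entry.variant_id:22s} {group:6s} {frac_text:>9s} {acmg_class:7s} {tier}")

tiers = []
for entry in TABLE2:
    group = clinvar_group(entry.clinvar)
    fraction = plp_fraction(entry.clinvar) if entry.clinvar.total else None
    acmg_class = combine(parse_codes(entry.acmg_codes))
    tiers.append(assign_tier(group, fraction, acmg_class,
                             n_submissions=entry.clinvar.total).tier)
print(f"\ncensus: {tiers.count('I')} Class I, {tiers.count('II')} Class II, "
      f"{tiers.count('III')} Class III "
      f"({sum(1 for t in tiers if t in ('I', 'II'))} with high evidence)")
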