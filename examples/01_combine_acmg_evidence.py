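"""Combine ACMG/AMP evidence codes into a variant classification.

Each line shows an evidence-code set, the resulting classification, and the
combining-rule clause that won. VUS-LP marks uncertain variants whose
evidence leans pathogenic without reaching likely pathogenic.
"""

from sfscreen import explain, parse_codes

EXAMPLES = [
    "PVS1,PM2,PP5",            # truncating, absent from controls, reputable P reports
    "PM1,PM2,PM5,PP2,PP3,PP5",  # hotspot missense with computational support
    "PM2,PP3,PP5",             # too little for LP, but leaning pathogenic
    "PVS1,PM2",                # truncating with one moderate criterion
    "BS1,BP1",                 # benign-side evidence
    "PVS1,PS1,BA1",            # contradictory evidence on both sides
    "",                        # no evidence at all
]

for text in EXAMPLES:
    result = explain(parse_codes(text))
    clause = result.winning.name if result.winning else "fallback"
    print(f"{text or '(none)':30s} -> {result.classification:7s} via {clause}")
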