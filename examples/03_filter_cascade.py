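"""Run the rare-variant filter cascade on a small hand-built input.

Builds six variants covering the main filter fates, runs the funnel, and
prints each variant's trace: the first failing stage, or the prioritization
route that kept it.
"""

from sfscreen import (
    GenomicVariant,
    PopulationFrequencies,
    PredictionProfile,
    SubjectCall,
    default_panel,
    run_cascade,
)

deleterious = PredictionProfile(cadd_phred=28, lrt="D", mutation_assessor="H",
                                mutation_taster="D", polyphen2_hdiv="D",
                                sift="D", fathmm="D")

variants = [
    GenomicVariant("1", 100, "G", "A", "ATP7B", consequence="missense",
                   predictors=deleterious),
    GenomicVariant("1", 200, "C", "T", "MUTYH", consequence="nonsense"),
    GenomicVariant("1", 300, "A", "C", "MUTYH", consequence="intronic",
                   intron_offset=3),
    GenomicVariant("1", 400, "G", "A", "LDLR", consequence="missense",
                   predictors=PredictionProfile(cadd_phred=12, sift="T")),
    GenomicVariant("1", 500, "G", "A", "TTN", consequence="missense"),
    GenomicVariant("1", 600, "G", "A", "DSP", consequence="missense",
                   frequencies=PopulationFrequencies(af_gnomad_exome=0.05)),
]
calls = [SubjectCall("S1", "F1", "1", v.pos, v.ref, v.alt, "het", 142, 0.48)
         for v in variants]

result = run_cascade(variants, calls, default_panel(), n_subjects=100)
print(f"retained {len(result.retained)} rare variants, "
      f"prioritized {len(result.prioritized)}\n")
for key, trace in sorted(result.traces.items()):
    last = trace.verdicts[-1]
    status = "PASS" if last.passed else "FAIL"
    print(f"pos {key.pos}: {status} at stage '{last.stage}' — {last.reason}")
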