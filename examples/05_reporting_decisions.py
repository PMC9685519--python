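"""Reporting decisions: who actually receives a secondary finding.

Communication is restricted to adults with opt-in consent; high-evidence
findings (Classes I-II) are then reported outright, while moderate-evidence
findings (Class III) wait for a positive family history.
"""

from sfscreen import reporting_decision

CASES = [
    ("I", "adult", True, "unknown"),
    ("II", "adult", True, "negative"),
    ("III", "adult", True, "unknown"),
    ("III", "adult", True, "positive"),
    ("II", "pediatric", True, "positive"),
    ("I", "adult", False, "unknown"),
    ("none", "adult", True, "unknown"),
]

for tier, age, opt_in, history in CASES:
    decision = reporting_decision(tier, age, opt_in, history)
    consent = "opt-in" if opt_in else "no consent"
    print(f"class {tier:4s} {age:9s} {consent:10s} history={history:8s} "
          f"-> {decision.decision}  ({'; '.join(decision.reasons)})")
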