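# ACMG/AMP evidence-combining clauses (Richards et al. 2015 rule set), v1.
# One clause per line: name, outcome, comma-separated conditions over
# evidence-strength counts (PVS, PS, PM, PP, BA, BS, BP).
# ">=" conditions are minimum counts; "==0" conditions require absence.
# Precedence at evaluation: P > LP on the pathogenic side, B > LB on the
# benign side; a clause firing on both sides is a contradiction and yields
# VUS; the VUS-LP sublabel is considered only when no other clause fires.
name	outcome	conditions
pathogenic_vs_plus_strong	P	PVS>=1,PS>=1
pathogenic_vs_plus_2moderate	P	PVS>=1,PM>=2
pathogenic_vs_plus_moderate_supporting	P	PVS>=1,PM>=1,PP>=1
pathogenic_vs_plus_2supporting	P	PVS>=1,PP>=2
pathogenic_2strong	P	PS>=2
pathogenic_strong_3moderate	P	PS>=1,PM>=3
pathogenic_strong_2moderate_2supporting	P	PS>=1,PM>=2,PP>=2
pathogenic_strong_moderate_4supporting	P	PS>=1,PM>=1,PP>=4
likely_pathogenic_vs_moderate	LP	PVS>=1,PM>=1
likely_pathogenic_strong_moderate	LP	PS>=1,PM>=1
likely_pathogenic_strong_2supporting	LP	PS>=1,PP>=2
likely_pathogenic_3moderate	LP	PM>=3
likely_pathogenic_2moderate_2supporting	LP	PM>=2,PP>=2
likely_pathogenic_moderate_4supporting	LP	PM>=1,PP>=4
benign_standalone	B	BA>=1
benign_2strong	B	BS>=2
likely_benign_strong_supporting	LB	BS>=1,BP>=1
likely_benign_2supporting	LB	BP>=2
vus_favor_pathogenic	VUS-LP	PM>=1,PP>=2,BA==0,BS==0,BP==0
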