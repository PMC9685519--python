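"""Independent brute-force evaluator of the ACMG/AMP combining rules.

Written as a literal transcription of the published rule text (nested
conditionals over evidence counts), deliberately independent of the
clause-table engine it cross-checks.
"""

from __future__ import annotations


def combine_by_the_book(pvs: int, ps: int, pm: int, pp: int,
                        ba: int, bs: int, bp: int) -> str:
    pathogenic = False
    if pvs >= 1:
        if ps >= 1:
            pathogenic = True
        if pm >= 2:
            pathogenic = True
        if pm == 1 and pp == 1:
            pathogenic = True
        if pp >= 2:
            pathogenic = True
    if ps >= 2:
        pathogenic = True
    if ps == 1:
        if pm >= 3:
            pathogenic = True
        if pm == 2 and pp >= 2:
            pathogenic = True
        if pm == 1 and pp >= 4:
            pathogenic = True

    likely_pathogenic = False
    if pvs == 1 and pm == 1:
        likely_pathogenic = True
    if ps == 1 and 1 <= pm <= 2:
        likely_pathogenic = True
    if ps == 1 and pp >= 2:
        likely_pathogenic = True
    if pm >= 3:
        likely_pathogenic = True
    if pm == 2 and pp >= 2:
        likely_pathogenic = True
    if pm == 1 and pp >= 4:
        likely_pathogenic = True

    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2

    pathogenic_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if pathogenic_side and benign_side:
        return "VUS"
    if pathogenic:
        return "P"
    if likely_pathogenic:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    if pm >= 1 and pp >= 2 and ba == 0 and bs == 0 and bp == 0:
        return "VUS-LP"
    return "VUS"


def code_set_for_counts(pvs: int, ps: int, pm: int, pp: int,
                        ba: int, bs: int, bp: int) -> frozenset[str]:
    """A concrete evidence-code set realizing the given strength counts."""
    codes: list[str] = []
    codes += ["PVS1"][:pvs]
    codes += [f"PS{i}" for i in range(1, ps + 1)]
    codes += [f"PM{i}" for i in range(1, pm + 1)]
    codes += [f"PP{i}" for i in range(1, pp + 1)]
    codes += ["BA1"][:ba]
    codes += [f"BS{i}" for i in range(1, bs + 1)]
    codes += [f"BP{i}" for i in range(1, bp + 1)]
    return frozenset(codes)
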