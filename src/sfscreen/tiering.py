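"""ClinVar submission-consensus statistics and the three-class ranking of
secondary findings, with the reporting decision.

A variant's ClinVar submission profile is reduced to one of five consensus
groups (PLP, BLB, VUS, CI, NR). For conflicting-interpretation (CI)
variants the share of pathogenic/likely-pathogenic submissions (the "PLP
fraction") drives the boundary between the high-evidence second class
(fraction > 80%) and the moderate-evidence third class (50% <= fraction
<= 80%). All threshold comparisons use exact rationals so that a fraction of
exactly 4/5 sits unambiguously below the Class II bar.

Classes I and II carry high evidence of pathogenicity and are reported to
consenting adults; Class III carries moderate evidence and is reported only
with a positive family history.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .errors import ConfigError, UndefinedFractionError
from .model import ClinVarProfile, TierAssignment

CLINVAR_GROUPS = ("PLP", "BLB", "VUS", "CI", "NR")

#: ACMG classifications accepted as "pathogenic-leaning" by the tier rules.
PLP_LIKE_CLASSES = frozenset({"P", "LP", "VUS-LP"})


def clinvar_group(profile: ClinVarProfile) -> str:
    """Map a submission profile to its consensus group.

    NR: no submissions; PLP: all submissions pathogenic/likely pathogenic;
    BLB: all benign/likely benign; VUS: all uncertain; CI: at least two
    distinct interpretation categories.
    """
    if profile.total == 0:
        return "NR"
    categories = sum(
        1
        for n in (profile.n_plp, profile.n_vus, profile.n_lb + profile.n_b)
        if n > 0
    )
    if categories >= 2:
        return "CI"
    if profile.n_plp == profile.total:
        return "PLP"
    if profile.n_vus == profile.total:
        return "VUS"
    return "BLB"


def plp_fraction(profile: ClinVarProfile) -> Fraction:
    """Exact share of P/LP submissions among all submissions."""
    if profile.total == 0:
        raise UndefinedFractionError(
            "PLP fraction is undefined for a variant with no ClinVar submissions"
        )
    return Fraction(profile.n_plp, profile.total)


@dataclass(frozen=True)
class TierConfig:
    """Thresholds of the three-class ranking.

    class2_min_fraction is exclusive (> 4/5), class3_min_fraction inclusive
    (>= 1/2). min_plp_submissions enforces the requirement that a consensus
    PLP annotation rest on at least two submissions; setting it to 1 relaxes
    the constraint.
    """

    class2_min_fraction: Fraction = Fraction(4, 5)
    class3_min_fraction: Fraction = Fraction(1, 2)
    min_plp_submissions: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.class3_min_fraction <= self.class2_min_fraction <= 1):
            raise ConfigError(
                "tier fractions must satisfy 0 <= class3 <= class2 <= 1, got "
                f"{self.class3_min_fraction} / {self.class2_min_fraction}"
            )
        if self.min_plp_submissions < 1:
            raise ConfigError("min_plp_submissions must be >= 1")


DEFAULT_TIER_CONFIG = TierConfig()


def assign_tier(
    group: str,
    fraction: Optional[Fraction],
    acmg_class: str,
    n_submissions: Optional[int] = None,
    config: TierConfig = DEFAULT_TIER_CONFIG,
) -> TierAssignment:
    """Assign a secondary-finding class with precedence I > II > III.

    Class I: consensus-PLP variants whose ACMG classification is P, LP or
    VUS-LP (with at least ``min_plp_submissions`` submissions when the
    submission total is supplied). Class II: CI variants with PLP fraction
    strictly above the Class II bar and a pathogenic-leaning ACMG class.
    Class III: CI variants with fraction at or above one half and a
    pathogenic-leaning ACMG class, or unreported (NR) variants the ACMG
    rules classify P or LP.
    """
    if group not in CLINVAR_GROUPS:
        raise ConfigError(f"unknown ClinVar group {group!r}")
    if group not in ("NR",) and fraction is None:
        raise ConfigError(f"a PLP fraction is required for ClinVar group {group}")

    rationale: list[str] = [f"clinvar_group={group}", f"acmg_class={acmg_class}"]
    plp_like = acmg_class in PLP_LIKE_CLASSES

    if group == "PLP" and plp_like:
        if n_submissions is None or n_submissions >= config.min_plp_submissions:
            rationale.append("consensus PLP in ClinVar and ACMG P/LP/VUS-LP")
            if n_submissions is not None:
                rationale.append(f"n_submissions={n_submissions}>={config.min_plp_submissions}")
            return TierAssignment("I", tuple(rationale))
        rationale.append(
            f"consensus PLP rests on {n_submissions} submission(s) "
            f"(<{config.min_plp_submissions}); demoted"
        )
        return TierAssignment("none", tuple(rationale))

    if group == "CI" and plp_like:
        rationale.append(f"plp_fraction={fraction}")
        if fraction > config.class2_min_fraction:
            rationale.append(f"fraction>{config.class2_min_fraction}")
            return TierAssignment("II", tuple(rationale))
        if fraction >= config.class3_min_fraction:
            rationale.append(f"fraction>={config.class3_min_fraction}")
            return TierAssignment("III", tuple(rationale))
        rationale.append(f"fraction<{config.class3_min_fraction}")
        return TierAssignment("none", tuple(rationale))

    if group == "NR" and acmg_class in ("P", "LP"):
        rationale.append("not reported in ClinVar but ACMG P/LP")
        return TierAssignment("III", tuple(rationale))

    rationale.append("no tier rule satisfied")
    return TierAssignment("none", tuple(rationale))


FAMILY_HISTORIES = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class ReportingDecision:
    decision: str  # "report", "report_if_family_history", "withhold"
    reasons: tuple[str, ...] = ()


def reporting_decision(
    tier: str,
    subject_age_class: str,
    opt_in: bool,
    family_history: str = "unknown",
) -> ReportingDecision:
    """Decide whether a tiered finding is communicated to a subject.

    Secondary findings are communicated exclusively to adults who opted in.
    High-evidence findings (Classes I-II) are then reported outright;
    moderate-evidence findings (Class III) are reported only with a positive
    family history, otherwise held pending family-history re-evaluation.
    """
    if family_history not in FAMILY_HISTORIES:
        raise ConfigError(f"unknown family_history {family_history!r}")
    if tier == "none":
        return ReportingDecision("withhold", ("no secondary finding",))
    if subject_age_class == "pediatric":
        return ReportingDecision("withhold", ("communication restricted to adults",))
    if not opt_in:
        return ReportingDecision("withhold", ("no opt-in consent",))
    if tier in ("I", "II"):
        return ReportingDecision("report", (f"class {tier}: high evidence",))
    if family_history == "positive":
        return ReportingDecision(
            "report", ("class III with positive family history",)
        )
    return ReportingDecision(
        "report_if_family_history",
        ("class III: pending family-history evaluation",),
    )
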