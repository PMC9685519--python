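"""Domain types shared by every stage of the secondary-finding screen.

The model follows VCF conventions: coordinates are 1-based, one record per
normalized alternate allele (multi-allelic sites are split upstream).
Intron offsets follow the HGVS sign convention: positive downstream of a
donor site (c.X+n), negative upstream of an acceptor (c.X-n), zero for
exonic positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple, Optional

from .errors import ModelError, VocabularyError

CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice_essential",
        "intronic",
        "synonymous",
        "other",
    }
)

#: Consequences treated as protein-truncating (loss of function) for the
#: prioritization bypass: no in-silico missense consensus is meaningful for
#: them, so they are prioritized on consequence alone.
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift"})

MODES_OF_INHERITANCE = frozenset({"AD", "AR", "XL", "SD"})

AGE_CLASSES = frozenset({"pediatric", "adult"})
SEXES = frozenset({"F", "M"})

class VariantKey(NamedTuple):
    """Identity of a normalized alternate allele: (chrom, pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, ref, alt = text.split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class PopulationFrequencies:
    """Alternate-allele frequencies from four population databases.

    ``None`` means the allele is absent from that database (a novel allele),
    which is distinct from a frequency of 0.0.
    """

    af_gnomad_exome: Optional[float] = None
    af_gnomad_genome: Optional[float] = None
    af_exac: Optional[float] = None
    af_1000g: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("af_gnomad_exome", "af_gnomad_genome", "af_exac", "af_1000g"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ModelError(f"{name}={value!r} outside [0, 1]")

    @property
    def max_af(self) -> Optional[float]:
        present = [
            v
            for v in (
                self.af_gnomad_exome,
                self.af_gnomad_genome,
                self.af_exac,
                self.af_1000g,
            )
            if v is not None
        ]
        return max(present) if present else None


#: Categorical vocabularies of the six categorical in-silico predictors, as
#: emitted by each tool. CADD is numeric (Phred-scaled) and handled apart.
PREDICTOR_VOCABULARY = {
    "lrt": frozenset({"D", "N", "U"}),
    "mutation_assessor": frozenset({"H", "M", "L", "N"}),
    "mutation_taster": frozenset({"A", "D", "N", "P"}),
    "polyphen2_hdiv": frozenset({"D", "P", "B"}),
    "sift": frozenset({"D", "T"}),
    "fathmm": frozenset({"D", "T"}),
}

#: Codes counted as a deleterious vote per tool (CADD votes when Phred > cutoff).
PREDICTOR_DELETERIOUS = {
    "lrt": frozenset({"D"}),
    "mutation_assessor": frozenset({"H", "M"}),
    "mutation_taster": frozenset({"A", "D"}),
    "polyphen2_hdiv": frozenset({"D", "P"}),
    "sift": frozenset({"D"}),
    "fathmm": frozenset({"D"}),
}

PREDICTOR_NAMES = ("cadd_phred", "lrt", "mutation_assessor", "mutation_taster",
                   "polyphen2_hdiv", "sift", "fathmm")


@dataclass(frozen=True)
class PredictionProfile:
    """Outputs of the seven in-silico pathogenicity predictors.

    ``None`` marks an absent prediction; absence never counts as a
    deleterious vote.
    """

    cadd_phred: Optional[float] = None
    lrt: Optional[str] = None
    mutation_assessor: Optional[str] = None
    mutation_taster: Optional[str] = None
    polyphen2_hdiv: Optional[str] = None
    sift: Optional[str] = None
    fathmm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ModelError(f"cadd_phred={self.cadd_phred!r} must be >= 0")
        for tool, vocab in PREDICTOR_VOCABULARY.items():
            code = getattr(self, tool)
            if code is not None and code not in vocab:
                raise VocabularyError(
                    f"unknown code {code!r} for predictor {tool!r}; "
                    f"expected one of {sorted(vocab)}"
                )


@dataclass(frozen=True)
class ClinVarProfile:
    """Per-category ClinVar submission counts for one variant.

    A variant absent from the ClinVar snapshot has all counts zero.
    """

    n_p: int = 0
    n_lp: int = 0
    n_vus: int = 0
    n_lb: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        for name in ("n_p", "n_lp", "n_vus", "n_lb", "n_b"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.n_p + self.n_lp + self.n_vus + self.n_lb + self.n_b

    @property
    def n_plp(self) -> int:
        return self.n_p + self.n_lp


@dataclass(frozen=True)
class GenomicVariant:
    """One normalized alternate allele with its annotation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: str = "other"
    intron_offset: int = 0
    dbsnp_id: str = ""
    frequencies: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    predictors: PredictionProfile = field(default_factory=PredictionProfile)
    clinvar: ClinVarProfile = field(default_factory=ClinVarProfile)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ModelError(f"pos={self.pos} must be >= 1 (1-based VCF coordinate)")
        if self.ref == self.alt:
            raise ModelError(f"ref and alt are identical ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise VocabularyError(
                f"unknown consequence {self.consequence!r}; expected one of {sorted(CONSEQUENCES)}"
            )
        if self.consequence == "intronic" and self.intron_offset == 0:
            raise ModelError(f"intronic variant {self.key} must have a nonzero intron_offset")
        if self.consequence == "splice_essential" and abs(self.intron_offset) not in (1, 2):
            raise ModelError(
                f"splice_essential variant {self.key} must sit at intron position +/-1 or +/-2"
            )

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SubjectCall:
    """One non-reference genotype observation for one subject."""

    subject_id: str
    family_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" or "hom"
    depth: int
    alt_fraction: float
    age_class: str = "adult"
    sex: str = "F"

    def __post_init__(self) -> None:
        if self.genotype not in ("het", "hom"):
            raise ModelError(f"genotype must be 'het' or 'hom', got {self.genotype!r}")
        if self.depth < 0:
            raise ModelError("depth must be >= 0")
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise ModelError(f"alt_fraction={self.alt_fraction} outside [0, 1]")
        if self.age_class not in AGE_CLASSES:
            raise VocabularyError(f"unknown age_class {self.age_class!r}")
        if self.sex not in SEXES:
            raise VocabularyError(f"unknown sex {self.sex!r}")

    @property
    def variant_key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PanelGene:
    symbol: str
    moi: str
    domain: str

    def __post_init__(self) -> None:
        if self.moi not in MODES_OF_INHERITANCE:
            raise VocabularyError(
                f"unknown mode of inheritance {self.moi!r} for {self.symbol}; "
                f"expected one of {sorted(MODES_OF_INHERITANCE)}"
            )


TIERS = ("I", "II", "III", "none")
EVIDENCE_LEVELS = {"I": "high", "II": "high", "III": "moderate", "none": "none"}


@dataclass(frozen=True)
class TierAssignment:
    """Outcome of the three-class secondary-finding ranking for one variant."""

    tier: str
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise VocabularyError(f"unknown tier {self.tier!r}; expected one of {TIERS}")

    @property
    def evidence_level(self) -> str:
        return EVIDENCE_LEVELS[self.tier]

    @property
    def is_secondary_finding(self) -> bool:
        return self.tier != "none"


def exact_fraction(numerator: int, denominator: int) -> Fraction:
    """Exact rational helper used wherever a printed threshold is compared."""
    return Fraction(numerator, denominator)
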