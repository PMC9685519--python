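"""Exception hierarchy for the screening pipeline."""


class SfScreenError(Exception):
    """Base class for all package errors."""


class ModelError(SfScreenError, ValueError):
    """A domain-type invariant was violated."""


class VocabularyError(SfScreenError, ValueError):
    """A categorical value fell outside its closed vocabulary."""


class VcfParseError(SfScreenError):
    """The VCF input could not be parsed."""


class DataIntegrityError(SfScreenError):
    """Cross-file references or uniqueness constraints are broken."""


class ConfigError(SfScreenError, ValueError):
    """A configuration (panel, thresholds, cohort design) is inconsistent."""


class UndefinedFractionError(SfScreenError, ZeroDivisionError):
    """A submission-consensus fraction was requested for an unreported variant."""
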