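"""Exception types shared across the pipeline."""


class MitofusionError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MitofusionError, ValueError):
    """A configuration value is missing, out of range, or inconsistent."""


class SizingError(MitofusionError, ValueError):
    """A layout or split cannot be realized with the requested sizes."""


class StructureParseError(MitofusionError, ValueError):
    """A SMILES string could not be parsed or standardized.

    Carries the offending input text as ``.offending``.
    """

    def __init__(self, message: str, offending: str = ""):
        super().__init__(message)
        self.offending = offending


class NormalizationError(MitofusionError, ValueError):
    """Plate-control normalization is impossible (e.g. a plate lacks DMSO)."""


class ContractViolation(MitofusionError, ValueError):
    """An operation was called outside its contract (degenerate input)."""


class LeakageError(MitofusionError, ValueError):
    """Train and test sets share compound identifiers."""

    def __init__(self, message: str, offenders=()):
        super().__init__(message)
        self.offenders = tuple(offenders)
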