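"""Typed errors shared across the package.

Every failure mode callers are expected to branch on has its own class;
plain ``ValueError`` is reserved for programming errors (bad arguments).
"""


class MrMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrMediateError):
    """A column map, config file, or manifest cannot be resolved."""


class EmptyInputError(MrMediateError):
    """A dataset contains no valid records."""


class NoInstrumentsError(MrMediateError):
    """Instrument selection or harmonization left zero usable SNPs.

    Mirrors the practice of excluding an exposure when no SNPs survive
    selection/harmonization rather than aborting a screen.
    """


class InsufficientInstrumentsError(NoInstrumentsError):
    """An operation needs more instruments than are available (e.g. Egger < 3)."""


class UndefinedRatioError(MrMediateError):
    """Wald ratio with a zero SNP-exposure effect."""


class DegenerateInputError(MrMediateError):
    """Collinear or otherwise degenerate input (e.g. Egger with no spread)."""


class UndefinedProportionError(MrMediateError):
    """Mediated proportion with a zero total effect."""


class LegFailureError(MrMediateError):
    """One leg of a mediation triangle failed instrument selection."""

    def __init__(self, leg: str, message: str = ""):
        self.leg = leg
        super().__init__(message or f"mediation leg failed: {leg}")
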