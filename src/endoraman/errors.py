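"""Exception hierarchy shared across the pipeline.

Each stage raises a subclass of :class:`EndoRamanError` so that callers (and
the CLI) can report which contract was violated without string matching.
"""


class EndoRamanError(Exception):
    """Base class for all package errors."""


class SchemaError(EndoRamanError):
    """A metadata sidecar is missing a required field or has a bad type."""


class StructuralError(EndoRamanError):
    """Array shapes or lengths disagree (e.g. dark frame vs. frame width)."""


class VocabularyError(EndoRamanError):
    """A label falls outside a closed vocabulary (tissue, prep method)."""


class ConfigError(EndoRamanError):
    """A generator or pipeline configuration violates its invariants."""


class ParameterError(EndoRamanError):
    """A processing parameter is out of its valid domain."""


class CalibrationError(EndoRamanError):
    """Axis or response calibration is underdetermined or non-physical."""


class RangeError(EndoRamanError):
    """A requested spectral range does not intersect the axis."""


class DegenerateInputError(EndoRamanError):
    """Input is degenerate for the requested statistic (e.g. constant
    spectrum passed to SNV, zero vector passed to SAM)."""


class ContractError(EndoRamanError):
    """An input violates a documented precondition (e.g. QF on a spectrum
    that is not SNV-normalized)."""


class InsufficientDataError(EndoRamanError):
    """Too few records to compute the requested summary."""


class TaskError(EndoRamanError):
    """A classification task cannot be formed from the given records."""


class LeakageError(EndoRamanError):
    """A subject (head) appears on both sides of a train/test split."""
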