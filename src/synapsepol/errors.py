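"""Exception hierarchy.

Every error carries a stable machine-readable ``code`` so batch drivers can
record per-scene failures without string matching on messages.
"""

from __future__ import annotations


class SynapsePolError(Exception):
    """Base class for all package errors."""

    code: str = "error"


class SceneValidationError(SynapsePolError, ValueError):
    """A scene/config field is out of its documented domain.

    Parameters
    ----------
    field:
        Name of the offending field.
    message:
        Human-readable description including the valid range.
    """

    code = "invalid_field"

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ConfigError(SynapsePolError, ValueError):
    code = "invalid_config"


class NoCellError(SynapsePolError):
    code = "no_cell"


class NoConjugateError(SynapsePolError):
    code = "no_conjugate"


class NoOrganellesError(SynapsePolError):
    code = "no_organelles"


class NoMtocError(SynapsePolError):
    code = "no_mtoc"


class DegenerateGeometryError(SynapsePolError):
    code = "degenerate_geometry"


class EmptyCohortError(SynapsePolError):
    code = "empty_cohort"


class UndefinedCorrelationError(SynapsePolError):
    code = "undefined_correlation"


class UnstableConjugateError(SynapsePolError):
    code = "unstable_conjugate"


class ZeroBaselineError(SynapsePolError):
    code = "zero_baseline"


class TrackTooShortError(SynapsePolError):
    code = "track_too_short"


class InterfaceOutOfStackError(SynapsePolError):
    code = "interface_out_of_stack"


class NoInterfaceSignalError(SynapsePolError):
    code = "no_interface_signal"


class DegenerateRoiError(SynapsePolError):
    code = "degenerate_roi"
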