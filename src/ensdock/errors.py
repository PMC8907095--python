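"""Exception hierarchy shared across the package."""


class EnsdockError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(EnsdockError, ValueError):
    """A generator or pipeline spec violates its invariants."""


class InvalidArgumentError(EnsdockError, ValueError):
    """An operation argument is out of its valid range."""


class FormatError(EnsdockError, ValueError):
    """A file does not conform to its declared format."""


class EmptySelectionError(EnsdockError, ValueError):
    """An atom selection matched no atoms."""


class TopologyError(EnsdockError, ValueError):
    """Structures do not share a compatible topology."""


class GeometryError(EnsdockError, ValueError):
    """A geometric operation received degenerate coordinates."""


class DegenerateInputError(EnsdockError, ValueError):
    """Numerical input has no usable variance/structure."""


class ShapeError(EnsdockError, ValueError):
    """Array dimensions do not match the model."""


class PairingError(EnsdockError, ValueError):
    """Two labelled vectors could not be paired by id."""


class CutoffSelectionError(EnsdockError, RuntimeError):
    """No candidate cutoff satisfied the clustering criteria.

    Carries the per-candidate pass/fail report in ``report``.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class AlignmentError(EnsdockError, ValueError):
    """Score columns and centroid ids could not be aligned."""
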