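"""Exception hierarchy for canopymetrics.

All package errors derive from :class:`CanopyMetricsError` so callers can
catch one base class at CLI or pipeline level.
"""

from __future__ import annotations


class CanopyMetricsError(Exception):
    """Base class for all canopymetrics errors."""


class PointCloudParseError(CanopyMetricsError):
    """A point-cloud text file could not be parsed.

    Parameters
    ----------
    line_number : line (1-based) at which parsing failed.
    message : human-readable description.
    """

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class TransformFormatError(CanopyMetricsError):
    """A transformation-matrix file violates the 4x4 homogeneous layout."""


class DegenerateInputError(CanopyMetricsError):
    """Geometric input is degenerate (too few points, collinear, zero extent)."""


class InsufficientPointsError(CanopyMetricsError):
    """An operation needs more points than the cloud provides."""


class MeasurementError(CanopyMetricsError):
    """A pipeline stage failed; carries the stage name for the failure log."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


class SchemaError(CanopyMetricsError):
    """A cylinder CSV is missing a mandatory column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"missing mandatory column: {column!r}")


class CylinderValidationError(CanopyMetricsError):
    """A cylinder record violates a structural invariant."""


class TopologyError(CanopyMetricsError):
    """The cylinder parent pointers do not form a forest."""

    def __init__(self, message: str, cycle=None):
        self.cycle = cycle
        super().__init__(message)


class SyntheticSpecError(CanopyMetricsError):
    """A synthetic tree specification is geometrically infeasible."""
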