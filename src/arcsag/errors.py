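"""Exception hierarchy for the arcsag pipeline.

Every failure mode of the pipeline maps onto one of these classes so that
callers (and the CLI exit-code logic) can distinguish bad inputs from
detection/coverage failures.
"""


class ArcSagError(Exception):
    """Base class for all arcsag errors."""


class InputError(ArcSagError):
    """Invalid user input: missing files, malformed configuration."""


class MetadataError(InputError):
    """A mandatory DICOM metadata element is missing or unusable."""


class FormatError(InputError):
    """The file is not a usable single-frame portal image."""


class ConsistencyError(InputError):
    """Images in one arc series disagree on collimator angle or mode."""


class ReferenceFrameError(ArcSagError):
    """No frame close enough to gantry zero to serve as reference."""


class CoverageError(ArcSagError):
    """Angular coverage of a series is insufficient for the analysis."""


class DetectionError(ArcSagError):
    """Ball-bearing detection failed (wrong candidate count, low score)."""

    def __init__(self, message: str, count: int | None = None):
        super().__init__(message)
        self.count = count


class AssignmentError(DetectionError):
    """Candidate blobs could not be unambiguously assigned to roles a-e."""


class EdgeError(ArcSagError):
    """A field edge could not be located."""

    def __init__(self, message: str, side: str | None = None):
        super().__init__(message)
        self.side = side


class GeometryError(ArcSagError):
    """Degenerate phantom geometry (near-zero denominators)."""


class RenderError(ArcSagError):
    """Simulated geometry falls outside the imaging panel."""
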