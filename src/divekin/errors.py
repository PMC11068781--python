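"""Exception hierarchy shared across the package."""


class DivekinError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DivekinError):
    """A keypoint record could not be parsed; message names the frame."""


class EmptyInputError(DivekinError):
    """An input held zero frames / zero records."""


class TrialUnusableError(DivekinError):
    """A trial violates a quality rule (e.g. a gap longer than max_gap)."""


class InsufficientPointsError(DivekinError):
    """Fewer control points than the calibration requires."""


class DegenerateGeometryError(DivekinError):
    """Control points are (near-)coplanar; message carries the condition ratio."""


class BehindCameraError(DivekinError):
    """A world point projects with a non-positive DLT denominator."""


class InsufficientViewsError(DivekinError):
    """Fewer than two valid observations for a 3D reconstruction."""


class FilterError(DivekinError):
    """Invalid filter specification or series too short to filter."""


class MissingLandmarkError(DivekinError):
    """A landmark required by a computation is absent (NaN) at some frame."""


class UndefinedAngleError(DivekinError):
    """An angle is undefined (zero-length segment or zero displacement)."""


class AmbiguousSideError(DivekinError):
    """Net mediolateral displacement too small to decide the dive side."""


class NoDiveError(DivekinError):
    """The ipsilateral foot never leaves the ground."""


class BadTrialError(DivekinError):
    """The ipsilateral foot is never detected on the ground."""


class EventWindowError(DivekinError):
    """An event window is empty or inverted."""


class PairingError(DivekinError):
    """Paired samples do not share unit ids or lengths."""


class DegenerateTestError(DivekinError):
    """A statistical test is undefined (e.g. zero-variance differences)."""


class DesignError(DivekinError):
    """Study design invalid (unbalanced within-subject data, missing cells)."""


class SpecError(DivekinError):
    """A synthetic-dive specification is physically inconsistent."""
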