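"""Exception hierarchy for the guidedev pipeline."""


class GuideDevError(Exception):
    """Base class for all guidedev errors."""


class InvalidPoseError(GuideDevError):
    """A bur pose is degenerate (zero length, non-finite coordinates)."""


class ConfigError(GuideDevError):
    """A study or run configuration failed validation."""


class RegistrationError(GuideDevError):
    """Base class for landmark-registration failures."""


class InsufficientLandmarksError(RegistrationError):
    """Fewer than three landmark correspondences were supplied."""


class DegenerateLandmarksError(RegistrationError):
    """Landmarks are collinear (or coincident); the rotation is not identifiable."""


class CorrespondenceError(RegistrationError):
    """Landmark label sets of the two frames do not match."""


class UndefinedROCError(GuideDevError):
    """ROC analysis requested with only one outcome class present."""
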