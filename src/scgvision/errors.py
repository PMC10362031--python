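"""Exception hierarchy for the scgvision pipeline.

Every failure mode a caller may want to catch has its own class; all inherit
from :class:`ScgVisionError` so ``except ScgVisionError`` guards a whole
pipeline stage.
"""


class ScgVisionError(Exception):
    """Base class for all scgvision errors."""


# --- video tracking ---------------------------------------------------------

class RoiBoundsError(ScgVisionError, ValueError):
    """ROI (partially) outside the frame."""


class UntrackableTemplateError(ScgVisionError, ValueError):
    """Template has no intensity variation; the Gauss-Newton Hessian is singular."""


class DegenerateTextureError(ScgVisionError):
    """Hessian singular or ill-conditioned at solve time."""


class OutOfViewError(ScgVisionError):
    """Warped template coordinates leave the frame."""


class TrackingLostError(ScgVisionError):
    """Target left the field of view during tracking; carries the frame index."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(message or f"tracking lost at frame {frame_index}")


class UnitsError(ScgVisionError, ValueError):
    """Operation applied to a trajectory/signal in the wrong units."""


# --- signal processing ------------------------------------------------------

class DomainError(ScgVisionError, ValueError):
    """Parameter outside its mathematical domain (non-positive length, bad band...)."""


class SignalLengthError(ScgVisionError, ValueError):
    """Signal too short for the requested operation."""


class NoTapsError(ScgVisionError):
    """No synchronization taps found in an audio track."""


class InsufficientAnchorsError(ScgVisionError):
    """Fewer than two tap events available for clock alignment."""


class ClockDriftError(ScgVisionError):
    """Estimated clock drift outside the plausible range."""


# --- beat analysis ----------------------------------------------------------

class NoBeatsError(ScgVisionError):
    """No QRS complexes detected."""


class CannotComputeCycleError(ScgVisionError):
    """Fewer than two R peaks: the average cardiac cycle length is undefined."""


class EmptySegmentationError(ScgVisionError):
    """No beat segments available to average."""


# --- validation metrics -----------------------------------------------------

class UndefinedCorrelationError(ScgVisionError):
    """Pearson correlation undefined (constant input)."""


class InfeasibleBandError(ScgVisionError):
    """DTW band too narrow to connect the path corners."""


class ZeroNormalizerError(ScgVisionError):
    """Similarity-index normalizer M is zero (all-zero gold standard)."""


class UndefinedLagError(ScgVisionError):
    """Cross-correlation lag undefined (constant input)."""


class AlignmentError(ScgVisionError, ValueError):
    """Two signals do not share a common grid (fs/length mismatch)."""


class InsufficientPairsError(ScgVisionError, ValueError):
    """Too few paired observations for agreement statistics."""


class InsufficientBeatsError(ScgVisionError):
    """Too few beats/peaks to form rate intervals."""


# --- pipeline ---------------------------------------------------------------

class ConfigError(ScgVisionError, ValueError):
    """Invalid or incomplete pipeline configuration."""


class RenderBoundsError(ScgVisionError, ValueError):
    """Synthetic motion exceeds the renderer's guard margin."""
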