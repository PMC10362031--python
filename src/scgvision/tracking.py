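"""Lucas-Kanade template tracking of a high-contrast chest target.

The target patch (e.g. a printed QR-code sticker used purely as texture) is
cut from the first video frame and located in every later frame by
minimizing the sum-of-squared-differences intensity error

    E(u) = sum_x [ I_n(W(x; u)) - T(x) ]^2

over a pure-translation warp ``W(x; u) = (x + u1, y + u2)``. The nonlinear
least-squares problem is solved with Gauss-Newton iterations: linearizing
``I_n(W(x; u + du))`` to first order gives the normal equations

    du = H^-1 sum_x [grad I_n J]^T [T(x) - I_n(W(x; u))],
    H  = sum_x [grad I_n J]^T [grad I_n J],

where ``J = dW/du`` is the 2x2 identity for pure translation, so H reduces
to the classic structure tensor ``sum grad I^T grad I``. Frame intensities
are sampled at sub-pixel warped positions by bilinear interpolation; the
frame gradient is computed once per frame by central differences and
sampled at the same warped positions (forward-additive variant).

Pixel displacement is converted to millimeters with a scaling factor from
either the known physical size of the target (SF = D_mm / D_pixel) or the
pinhole geometry (SF = d * p / f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateTextureError,
    DomainError,
    OutOfViewError,
    RoiBoundsError,
    TrackingLostError,
    UnitsError,
    UntrackableTemplateError,
)
from .signals import UniformSignal

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSequence",
    "TemplateRegion",
    "TrackerConfig",
    "TrackerState",
    "DisplacementTrajectory",
    "CameraCalibration",
    "extract_template",
    "warp_sample",
    "solve_warp_increment",
    "track_sequence",
    "scaling_factor_from_target",
    "scaling_factor_from_intrinsics",
    "apply_calibration",
]

#: condition number of H above which the texture is declared degenerate
CONDITION_LIMIT = 1e6


@dataclass
class FrameSequence:
    """Ordered grayscale frames with a common geometry.

    ``frames`` is an (n, height, width) float array with intensities in
    [0, 1]. Coordinates are 0-based with the origin at the top-left corner:
    x = column (rightward), y = row (downward).
    """

    frames: np.ndarray
    frame_rate: float
    audio: UniformSignal | None = None
    rotation_deg: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise DomainError("frames must be a (n, height, width) array")
        if self.frame_rate <= 0:
            raise DomainError("frame_rate must be positive")
        if not np.all(np.isfinite(f)):
            raise DomainError("frame intensities must be finite")
        if f.min() < -1e-9 or f.max() > 1 + 1e-9:
            raise DomainError("frame intensities must lie in [0, 1]")
        self.frames = f

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class TemplateRegion:
    """Reference patch cut from frame 1 plus its coordinate grid."""

    patch: np.ndarray
    origin: tuple[int, int]          # (column, row) of the top-left corner
    ys: np.ndarray = field(repr=False, default=None)  # row grid, template frame
    xs: np.ndarray = field(repr=False, default=None)  # column grid

    def __post_init__(self):
        if self.ys is None or self.xs is None:
            x0, y0 = self.origin
            h, w = self.patch.shape
            self.ys, self.xs = np.mgrid[y0:y0 + h, x0:x0 + w].astype(float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.patch.shape


@dataclass(frozen=True)
class TrackerConfig:
    """Tunables of the Gauss-Newton tracker.

    epsilon : convergence threshold on ||du|| in pixels (default 0.01 px,
        comfortably below the 0.05 px accuracy target).
    max_iterations : Gauss-Newton iteration cap per frame.
    init_policy : "previous_frame" warm-starts each frame at the previous
        converged u (inter-frame chest motion is far below the patch size);
        "zero" restarts from (0, 0).
    template_update : "off" keeps the frame-1 template throughout (default;
        chest motion is small enough that appearance drift is negligible);
        "drift_corrected" re-cuts a working template every
        ``update_period_frames`` frames and corrects its placement against
        the frame-1 template so re-cut errors cannot accumulate.
    interpolation : "bilinear" (order 1, matches the first-order model) or
        "bicubic" (order 3).
    """

    epsilon: float = 0.01
    max_iterations: int = 50
    init_policy: str = "previous_frame"
    template_update: str = "off"
    update_period_frames: int = 60
    interpolation: str = "bilinear"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise DomainError("epsilon must be positive")
        if self.max_iterations < 1:
            raise DomainError("max_iterations must be >= 1")
        if self.init_policy not in ("previous_frame", "zero"):
            raise DomainError(f"unknown init_policy {self.init_policy!r}")
        if self.template_update not in ("off", "drift_corrected"):
            raise DomainError(f"unknown template_update {self.template_update!r}")
        if self.interpolation not in ("bilinear", "bicubic"):
            raise DomainError(f"unknown interpolation {self.interpolation!r}")

    @property
    def spline_order(self) -> int:
        return 1 if self.interpolation == "bilinear" else 3


@dataclass
class TrackerState:
    """Diagnostic snapshot of one Gauss-Newton solve."""

    u: np.ndarray
    delta_u: np.ndarray
    error: float
    hessian: np.ndarray
    iterations_used: int = 0
    converged: bool = False

    #: Jacobian dW/du of the translation warp — constant identity.
    jacobian: np.ndarray = field(default_factory=lambda: np.eye(2))


@dataclass
class DisplacementTrajectory:
    """Per-frame target displacement relative to frame 1.

    ``ux`` is motion along image x (columns, rightward), ``uy`` along image
    y (rows, downward). ``per_frame_error`` holds the final SSD error of
    each frame's solve; ``initial_error`` the SSD at that frame's starting
    u, so error decrease can be audited.
    """

    ux: np.ndarray
    uy: np.ndarray
    frame_rate: float
    per_frame_error: np.ndarray
    initial_error: np.ndarray | None = None
    units: str = "pixel"

    def __len__(self) -> int:
        return len(self.ux)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.ux)) / self.frame_rate

    def component(self, axis: str) -> UniformSignal:
        """Displacement along ``axis`` ("x" or "y") as a UniformSignal."""
        values = self.ux if axis == "x" else self.uy
        return UniformSignal(values, self.frame_rate, units=self.units)


@dataclass(frozen=True)
class CameraCalibration:
    """mm-per-pixel scaling factor for a fronto-parallel target plane."""

    sf: float
    method: str
    d_mm: float | None = None
    d_pixel: float | None = None
    distance_d: float | None = None
    unit_length_p: float | None = None
    focal_f: float | None = None

    def __post_init__(self):
        if self.sf <= 0:
            raise DomainError("scaling factor must be positive")


def extract_template(frames: FrameSequence, roi: tuple[int, int, int, int]) -> TemplateRegion:
    """Cut the tracking template from frame 1.

    ``roi`` is (x0, y0, w, h), 0-based, half-open. The patch must lie fully
    inside the frame and have nonzero intensity variance — a constant patch
    has zero gradient everywhere, which makes the Gauss-Newton Hessian
    exactly singular.
    """
    x0, y0, w, h = roi
    if w < 8 or h < 8:
        raise RoiBoundsError(f"roi {roi}: width/height must be >= 8 px")
    if x0 < 0 or y0 < 0 or x0 + w > frames.width or y0 + h > frames.height:
        raise RoiBoundsError(f"roi {roi} outside frame "
                             f"({frames.width}x{frames.height})")
    patch = frames.frames[0, y0:y0 + h, x0:x0 + w].copy()
    if patch.var() == 0:
        raise UntrackableTemplateError(
            "template has zero intensity variance (untrackable)")
    return TemplateRegion(patch=patch, origin=(x0, y0))


def _warped_grids(template: TemplateRegion, u) -> tuple[np.ndarray, np.ndarray]:
    return template.ys + u[1], template.xs + u[0]


def warp_sample(frame: np.ndarray, u, template: TemplateRegion,
                order: int = 1) -> np.ndarray:
    """Sample ``frame`` at the warped template grid W(x; u) = x + u.

    Sub-pixel positions are interpolated (bilinear by default). Raises
    :class:`OutOfViewError` when any warped coordinate leaves the frame —
    the tracking-loss signal.
    """
    rows, cols = _warped_grids(template, u)
    h, w = frame.shape
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() > h - 1 or cols.max() > w - 1):
        raise OutOfViewError(
            f"warped template at u=({u[0]:.2f}, {u[1]:.2f}) leaves the frame")
    return ndimage.map_coordinates(frame, [rows, cols], order=order,
                                   mode="nearest", prefilter=order > 1)


def _frame_gradient(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient (d/dx, d/dy) of a full frame."""
    gy, gx = np.gradient(frame)
    return gx, gy


def _gn_step(frame, gx, gy, template, u, order):
    """One Gauss-Newton increment at the current u. Returns (du, state)."""
    rows, cols = _warped_grids(template, u)
    h, w = frame.shape
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() > h - 1 or cols.max() > w - 1):
        raise OutOfViewError(
            f"warped template at u=({u[0]:.2f}, {u[1]:.2f}) leaves the frame")
    coords = [rows, cols]
    warped = ndimage.map_coordinates(frame, coords, order=order,
                                     mode="nearest", prefilter=order > 2)
    ix = ndimage.map_coordinates(gx, coords, order=1, mode="nearest")
    iy = ndimage.map_coordinates(gy, coords, order=1, mode="nearest")
    residual = template.patch - warped
    error = float(np.sum(residual**2))
    # dW/du = I, so [grad I * J] = (Ix, Iy) and H is the structure tensor
    hxy = float(np.sum(ix * iy))
    hess = np.array([[float(np.sum(ix * ix)), hxy],
                     [hxy, float(np.sum(iy * iy))]])
    if not np.all(np.isfinite(hess)) or np.linalg.cond(hess) > CONDITION_LIMIT:
        raise DegenerateTextureError(
            f"Hessian ill-conditioned (cond > {CONDITION_LIMIT:g}): "
            "texture too weak along at least one axis")
    b = np.array([float(np.sum(ix * residual)), float(np.sum(iy * residual))])
    du = np.linalg.solve(hess, b)
    state = TrackerState(u=np.asarray(u, float).copy(), delta_u=du,
                         error=error, hessian=hess)
    return du, state


def solve_warp_increment(frame: np.ndarray, template: TemplateRegion, u,
                         order: int = 1) -> tuple[np.ndarray, TrackerState]:
    """Solve one Gauss-Newton increment du = H^-1 sum [grad I]^T [T - I(W)].

    The frame gradient is computed by central differences on the full frame
    and sampled at the warped template positions.
    """
    gx, gy = _frame_gradient(np.asarray(frame, float))
    return _gn_step(np.asarray(frame, float), gx, gy, template, u, order)


#: a frame solve counts as diverged when its final SSD exceeds the starting
#: SSD by more than this factor; below it, tiny non-monotonicity at the
#: interpolation-noise floor is expected and the final iterate is kept
_DIVERGENCE_FACTOR = 1.10


def _iterate_frame(frame, gx, gy, template, u0, config):
    """Run Gauss-Newton to convergence on one frame.

    Returns the final iterate: the Gauss-Newton fixed point is the accurate
    sub-pixel estimate, and reverting to an earlier iterate whenever the
    measured SSD wiggles by a fraction of its noise floor would bias the
    trajectory toward the warm start. Only a genuinely diverging solve
    (final SSD > _DIVERGENCE_FACTOR x starting SSD) falls back to the best
    iterate seen.
    """
    u = np.asarray(u0, float).copy()
    best_u, best_err = None, np.inf
    initial_err = None
    iterations = 0
    converged = False
    for iterations in range(1, config.max_iterations + 1):
        du, state = _gn_step(frame, gx, gy, template, u,
                             config.spline_order)
        if initial_err is None:
            initial_err = state.error
        if state.error < best_err:
            best_err, best_u = state.error, u.copy()
        u = u + du
        if np.hypot(du[0], du[1]) <= config.epsilon:
            converged = True
            break
    # evaluate the final iterate
    rows, cols = _warped_grids(template, u)
    h, w = frame.shape
    final_err = np.inf
    if (rows.min() >= 0 and cols.min() >= 0
            and rows.max() <= h - 1 and cols.max() <= w - 1):
        warped = ndimage.map_coordinates(frame, [rows, cols],
                                         order=config.spline_order,
                                         mode="nearest",
                                         prefilter=config.spline_order > 2)
        final_err = float(np.sum((template.patch - warped) ** 2))
    if final_err <= _DIVERGENCE_FACTOR * initial_err + 1e-12:
        return u, final_err, initial_err, iterations, converged
    return best_u, best_err, initial_err, iterations, converged


def _recut_template(frame, reference: TemplateRegion, u, order):
    """Cut a working template from ``frame`` at the tracked position."""
    rows, cols = _warped_grids(reference, u)
    patch = ndimage.map_coordinates(frame, [rows, cols], order=order,
                                    mode="nearest", prefilter=order > 2)
    return TemplateRegion(patch=patch, origin=reference.origin,
                          ys=reference.ys, xs=reference.xs)


def track_sequence(frames: FrameSequence, template: TemplateRegion,
                   config: TrackerConfig | None = None) -> DisplacementTrajectory:
    """Track the template through every frame.

    For each frame, Gauss-Newton increments are iterated until
    ``||du|| <= epsilon`` or ``max_iterations``; non-convergence is logged
    and the best iterate kept. The returned trajectory is u per frame
    relative to frame 1 (frame 1 itself is solved too and lands at ~0).

    With ``template_update="drift_corrected"`` the working template is
    re-cut from the current frame every ``update_period_frames`` frames;
    each frame is first aligned against the working template and the result
    is then refined against the frame-1 template, which anchors the track
    and prevents re-cut errors from accumulating (default off: no
    significant benefit for millimeter-scale chest motion).
    """
    if config is None:
        config = TrackerConfig()
    if len(frames) < 2:
        raise DomainError("need at least 2 frames to track")
    n = len(frames)
    ux = np.zeros(n)
    uy = np.zeros(n)
    err = np.zeros(n)
    err0 = np.zeros(n)
    u_prev = np.zeros(2)
    working = template
    for i in range(n):
        frame = frames.frames[i]
        gx, gy = _frame_gradient(frame)
        u_init = u_prev if config.init_policy == "previous_frame" else np.zeros(2)
        try:
            u, e, e_init, iters, conv = _iterate_frame(
                frame, gx, gy, working, u_init, config)
            if working is not template:
                # drift correction: refine against the frame-1 template
                u, e, _, _, conv = _iterate_frame(frame, gx, gy, template,
                                                  u, config)
        except OutOfViewError as exc:
            raise TrackingLostError(i, f"frame {i}: {exc}") from exc
        if not conv:
            logger.info("frame %d: no convergence in %d iterations "
                        "(|du| last step unknown, keeping best u)",
                        i, config.max_iterations)
        ux[i], uy[i] = u
        err[i] = e
        err0[i] = e_init
        u_prev = u
        if (config.template_update == "drift_corrected"
                and (i + 1) % config.update_period_frames == 0):
            working = _recut_template(frame, template, u, config.spline_order)
    return DisplacementTrajectory(ux=ux, uy=uy, frame_rate=frames.frame_rate,
                                  per_frame_error=err, initial_error=err0,
                                  units="pixel")


def scaling_factor_from_target(d_mm: float, d_pixel: float) -> CameraCalibration:
    """Scaling factor from the known physical size of the tracked target:
    SF = D_mm / D_pixel (mm per pixel)."""
    if d_mm <= 0 or d_pixel <= 0:
        raise DomainError("target dimensions must be positive")
    return CameraCalibration(sf=d_mm / d_pixel, method="target_dimension",
                             d_mm=d_mm, d_pixel=d_pixel)


def scaling_factor_from_intrinsics(distance_d: float, unit_length_p: float,
                                   focal_f: float) -> CameraCalibration:
    """Scaling factor from pinhole geometry: SF = d * p / f, with the
    camera-object distance d in mm, sensor unit length p in um/pixel
    (converted to mm internally) and focal length f in mm."""
    if distance_d <= 0 or unit_length_p <= 0 or focal_f <= 0:
        raise DomainError("distance, unit length and focal length must be positive")
    sf = distance_d * (unit_length_p * 1e-3) / focal_f
    return CameraCalibration(sf=sf, method="intrinsics", distance_d=distance_d,
                             unit_length_p=unit_length_p, focal_f=focal_f)


def apply_calibration(traj: DisplacementTrajectory,
                      cal: CameraCalibration) -> DisplacementTrajectory:
    """Convert a pixel trajectory to millimeters (single application only)."""
    if traj.units != "pixel":
        raise UnitsError(f"trajectory already in {traj.units!r}; "
                         "calibration applies to pixel trajectories only")
    return replace(traj, ux=traj.ux * cal.sf, uy=traj.uy * cal.sf, units="mm")
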