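"""Flow displacement (jet eccentricity), rotational angle, and rotational speed.

Flow displacement (FD) is the distance between the lumen's geometric center
and the forward-velocity-weighted centroid ("center of velocity"), normalised
to the equivalent lumen diameter ``D_eq = 2*sqrt(area/pi)`` of the same frame
and expressed in percent.  The rotational angle (RA) is the direction of that
offset around the lumen center.  Because early-systolic aortic flow is mostly
laminar, frames with FD at or below a 12% gate carry no meaningful jet
direction: their RA is plotted as 0 but excluded from the rotational-angle
change (dRA) and rotational-speed (RS) computations.

Angle convention: 0 deg points to image "up" (-y, anterior on a standard
axial view), angles increase clockwise on screen (x right, y down), range
(-180, 180].  Only relative angles enter any reported metric, so the zero
reference is a pure convention; it is shared with the synthetic generator
through :func:`angle_to_unit` / :func:`offset_to_angle`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import MaskError, ValidationError
from .flow import PhaseLandmarks
from .io import MaskSeries, VelocitySeries, equivalent_diameter_mm

DEFAULT_FD_GATE_PCT = 12.0


def wrap_angle(angle_deg: float) -> float:
    """Map any angle to the (-180, 180] branch."""
    a = angle_deg % 360.0
    return a - 360.0 if a > 180.0 else a


def offset_to_angle(dx_mm: float, dy_mm: float) -> float:
    """Angle of an (x, y) offset: 0 at -y ("up"), clockwise positive."""
    return wrap_angle(math.degrees(math.atan2(dx_mm, -dy_mm)))


def angle_to_unit(angle_deg: float) -> tuple[float, float]:
    """Unit (dx, dy) vector for an angle; inverse of :func:`offset_to_angle`."""
    rad = math.radians(angle_deg)
    return math.sin(rad), -math.cos(rad)


@dataclass
class FDSeries:
    """Per-frame flow displacement (% of D_eq) and jet angle (degrees).

    ``fd`` is NaN where no forward pixels exist; ``angle`` holds 0 for gated
    frames (matching how gated phases are drawn in FD rotational-angle plots)
    but the ``gated`` flag is what downstream computations honour.
    """

    fd: np.ndarray
    angle: np.ndarray
    gated: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.gated = np.asarray(self.gated, dtype=bool)
        if not (self.fd.size == self.angle.size == self.gated.size):
            raise ValidationError("FDSeries arrays must have equal length")
        valid = self.fd[~np.isnan(self.fd)]
        if np.any(valid < 0):
            raise ValidationError("fd must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.fd.size


@dataclass
class RotationSummary:
    """Rotational speed between consecutive ungated frames, rev/s."""

    delta_ra: float | None
    rs_series: np.ndarray  # length n_frames-1; NaN where a pair is ineligible
    rsls_avg: float | None


# ---------------------------------------------------------------------------


def vessel_center(mask_frame: np.ndarray) -> tuple[float, float]:
    """Unweighted centroid of the lumen mask, as (x, y) in pixel units."""
    ys, xs = np.nonzero(mask_frame)
    if xs.size == 0:
        raise MaskError("mask frame has no true pixels")
    return float(xs.mean()), float(ys.mean())


def center_of_velocity(
    vel_frame: np.ndarray, mask_frame: np.ndarray, forward_sign: int
) -> tuple[float, float] | None:
    """Forward-velocity-weighted centroid (x, y), or None without forward flow."""
    ys, xs = np.nonzero(mask_frame)
    if xs.size == 0:
        raise MaskError("mask frame has no true pixels")
    w = np.maximum(forward_sign * vel_frame[ys, xs], 0.0)
    total = w.sum()
    if total == 0:
        return None
    return float((w * xs).sum() / total), float((w * ys).sum() / total)


def flow_displacement_frame(
    vel_frame: np.ndarray,
    mask_frame: np.ndarray,
    spacing: tuple[float, float],
    forward_sign: int,
    *,
    normalization: str = "diameter",
) -> tuple[float, float]:
    """FD (%) and jet angle (deg) for one frame.

    The centroid offset is converted to mm with the (possibly anisotropic)
    pixel spacing and normalised to the equivalent lumen diameter (or radius,
    with ``normalization="radius"``).  Returns ``(nan, nan)`` when the frame
    has no forward pixels.
    """
    sr, sc = spacing
    vc = vessel_center(mask_frame)
    cov = center_of_velocity(vel_frame, mask_frame, forward_sign)
    if cov is None:
        return math.nan, math.nan
    dx_mm = (cov[0] - vc[0]) * sc
    dy_mm = (cov[1] - vc[1]) * sr
    area_mm2 = float(mask_frame.sum()) * sr * sc
    d_eq = equivalent_diameter_mm(area_mm2)
    if normalization == "diameter":
        denom = d_eq
    elif normalization == "radius":
        denom = d_eq / 2.0
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    dist = math.hypot(dx_mm, dy_mm)
    fd = 100.0 * dist / denom
    angle = offset_to_angle(dx_mm, dy_mm) if dist > 0 else 0.0
    return fd, angle


def compute_fd_series(
    vel: VelocitySeries,
    masks: MaskSeries,
    *,
    normalization: str = "diameter",
) -> FDSeries:
    """FD and raw jet angle for every frame (no gating applied yet).

    Frames with no forward pixels are marked gated immediately.
    """
    fd = np.empty(vel.n_frames)
    angle = np.zeros(vel.n_frames)
    gated = np.zeros(vel.n_frames, dtype=bool)
    for i, (fr, m) in enumerate(zip(vel.frames, masks.frames)):
        f, a = flow_displacement_frame(
            fr.velocity, m, vel.pixel_spacing, vel.forward_sign, normalization=normalization
        )
        fd[i] = f
        if math.isnan(f):
            gated[i] = True
            angle[i] = 0.0
        else:
            angle[i] = a
    return FDSeries(fd=fd, angle=angle, gated=gated)


def fd_summaries(fds: FDSeries, lm: PhaseLandmarks) -> dict[str, float | None]:
    """Window means of FD: systole, late systole, diastole, and peak systole.

    NaN frames (no forward flow) are excluded from the means; a window with
    no valid frame yields ``None``.
    """

    def window_mean(window: tuple[int, int] | None) -> float | None:
        if window is None:
            return None
        vals = fds.fd[window[0] : window[1] + 1]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else None

    fdps = fds.fd[lm.peak_systole_idx]
    return {
        "fds_avg": window_mean(lm.systole_window),
        "fdls_avg": window_mean(lm.late_systole_window),
        "fdd_avg": window_mean(lm.diastole_window),
        "fdps": None if math.isnan(fdps) else float(fdps),
    }


def rotational_angle_series(fds: FDSeries, gate: float = DEFAULT_FD_GATE_PCT) -> FDSeries:
    """Apply the laminar-flow gate: frames with FD <= ``gate`` (%) get RA 0 and
    ``gated=True``; ungated frames keep their measured angle."""
    with np.errstate(invalid="ignore"):
        low = fds.fd <= gate
    gated = fds.gated | low | np.isnan(fds.fd)
    angle = np.where(gated, 0.0, fds.angle)
    return replace(fds, angle=angle, gated=gated)


def delta_ra(
    ra: FDSeries,
    lm: PhaseLandmarks,
    *,
    stabilization_threshold_deg: float = 10.0,
    stabilization_run: int = 2,
) -> float | None:
    """Rotational-angle change dRA = RA(end systole) - RA(stabilization), deg.

    The stabilization point is the first frame after peak systole where the
    absolute frame-to-frame RA change stays below
    ``stabilization_threshold_deg`` for ``stabilization_run`` consecutive
    frame pairs; differences use minimal wrap.  Gated frames are ineligible.
    Returns ``None`` (with a warning) when no stabilization point exists.
    """
    peak, end = lm.peak_systole_idx, lm.end_systole_idx
    idx = [i for i in range(peak + 1, end + 1) if not ra.gated[i]]
    if len(idx) < stabilization_run + 1:
        warnings.warn("too few ungated late-systolic frames for dRA", stacklevel=2)
        return None
    stab = None
    for k in range(len(idx) - stabilization_run):
        run = idx[k : k + stabilization_run + 1]
        if run[-1] - run[0] != stabilization_run:  # pairs must be frame-adjacent
            continue
        diffs = [abs(wrap_angle(ra.angle[run[j + 1]] - ra.angle[run[j]]))
                 for j in range(stabilization_run)]
        if all(d < stabilization_threshold_deg for d in diffs):
            stab = run[0]
            break
    if stab is None:
        warnings.warn("no stabilization point found after peak systole", stacklevel=2)
        return None
    if ra.gated[end]:
        warnings.warn("end-systolic frame is gated; dRA undefined", stacklevel=2)
        return None
    return wrap_angle(float(ra.angle[end] - ra.angle[stab]))


def rotational_speed(ra: FDSeries, lm: PhaseLandmarks, frame_dt: float) -> RotationSummary:
    """Rotational speed RS between consecutive ungated frames, rev/s.

    ``RS[i] = wrap(RA[i+1] - RA[i]) / (360 * frame_dt)``; pairs touching a
    gated frame are excluded (NaN), never zero-filled.  ``rsls_avg`` averages
    the eligible pairs inside late systole (peak to end systole); it is
    ``None`` when no pair is eligible.
    """
    if frame_dt <= 0:
        raise ValidationError(f"frame_dt must be > 0, got {frame_dt}")
    n = ra.n_frames
    rs = np.full(max(n - 1, 0), np.nan)
    for i in range(n - 1):
        if not ra.gated[i] and not ra.gated[i + 1]:
            rs[i] = wrap_angle(float(ra.angle[i + 1] - ra.angle[i])) / (360.0 * frame_dt)
    peak, end = lm.late_systole_window
    ls = rs[peak:end]  # pairs (i, i+1) fully inside [peak, end]
    ls = ls[~np.isnan(ls)]
    rsls = float(ls.mean()) if ls.size else None
    if rsls is None:
        warnings.warn("no eligible ungated frame pairs in late systole", stacklevel=2)
    d = delta_ra(ra, lm)
    return RotationSummary(delta_ra=d, rs_series=rs, rsls_avg=rsls)
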