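"""Flow curves, systolic landmarks, cycle volumes, and lumen-area metrics.

The per-pixel decomposition follows the sign of the through-plane velocity:
within the lumen, pixels whose signed velocity agrees with the ROI's
``forward_sign`` contribute to the forward rate, the rest to the retrograde
rate.  All volume integrals use the rectangle rule with the uniform frame
duration ``rr_interval / n_frames`` implied by retrospective gating (a
trapezoid variant is available via ``rule="trapezoid"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import CurveError, LandmarkError, MaskError, ShapeMismatchError, ValidationError
from .io import MaskSeries, VelocitySeries


@dataclass
class AreaSeries:
    """Lumen cross-section area per frame, cm^2."""

    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.size == 0 or np.any(self.areas <= 0):
            raise ValidationError("areas must be non-empty and strictly positive")


@dataclass
class FlowCurve:
    """Net/forward/retrograde flow rates (mL/s) sampled at frame times (s)."""

    times: np.ndarray  # s
    net_rate: np.ndarray  # mL/s, signed
    forward_rate: np.ndarray  # mL/s, >= 0
    retro_rate: np.ndarray  # mL/s, >= 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.net_rate = np.asarray(self.net_rate, dtype=float)
        self.forward_rate = np.asarray(self.forward_rate, dtype=float)
        self.retro_rate = np.asarray(self.retro_rate, dtype=float)
        n = self.times.size
        if not (self.net_rate.size == self.forward_rate.size == self.retro_rate.size == n):
            raise ShapeMismatchError("flow curve arrays must have equal length")
        if np.any(self.forward_rate < 0) or np.any(self.retro_rate < 0):
            raise ValidationError("forward/retro rates must be non-negative")
        if np.max(np.abs(self.net_rate - (self.forward_rate - self.retro_rate))) > 1e-9:
            raise ValidationError("net_rate must equal forward_rate - retro_rate")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PhaseLandmarks:
    """Frame-index landmarks of the cardiac cycle.

    ``systole_window`` and ``diastole_window`` are inclusive ``(start, stop)``
    frame ranges that partition the cycle; ``late_systole_window`` spans peak
    systole to end systole and is contained in systole.
    """

    peak_systole_idx: int
    end_systole_idx: int
    end_systole_time_s: float
    systole_window: tuple[int, int]
    late_systole_window: tuple[int, int]
    diastole_window: tuple[int, int] | None


@dataclass
class FlowMetrics:
    """Scalar outputs of the 2-D flow analysis; ``None`` marks a metric that
    could not be computed for this series (e.g. sFRR with zero forward flow)."""

    ff: float | None = None  # forward flow volume, mL
    bf: float | None = None  # backward flow volume, mL
    ffi: float | None = None  # ff / BSA, mL/m^2
    bfi: float | None = None  # bf / BSA, mL/m^2
    sff: float | None = None  # systolic forward flow, mL
    srf: float | None = None  # systolic retrograde flow, mL
    sfrr: float | None = None  # 100 * srf / sff, %
    rac: float | None = None  # relative area change, %
    area_max: float | None = None  # cm^2
    area_min: float | None = None  # cm^2
    fds_avg: float | None = None  # mean FD over systole, %
    fdls_avg: float | None = None  # mean FD over late systole, %
    fdd_avg: float | None = None  # mean FD over diastole, %
    fdps: float | None = None  # FD at peak systole, %
    delta_ra: float | None = None  # rotational angle change, degrees
    rsls_avg: float | None = None  # mean rotational speed in late systole, rev/s
    pwv: float | None = None  # pulse wave velocity, m/s

    def to_dict(self) -> dict[str, float | None]:
        return dict(vars(self))


# ---------------------------------------------------------------------------


def compute_area_series(masks: MaskSeries, spacing: tuple[float, float]) -> AreaSeries:
    """Lumen area per frame: true-pixel count x pixel area, reported in cm^2."""
    sr, sc = spacing
    areas = []
    for i, m in enumerate(masks.frames):
        n = int(m.sum())
        if n == 0:
            raise MaskError(f"mask frame {i} is empty")
        areas.append(n * sr * sc / 100.0)  # mm^2 -> cm^2
    return AreaSeries(areas=np.array(areas))


def relative_area_change(areas: AreaSeries) -> float:
    """RAC (%) = (maximal area - minimal area) / minimal area x 100."""
    amax = float(np.max(areas.areas))
    amin = float(np.min(areas.areas))
    return (amax - amin) / amin * 100.0


def compute_flow_curve(vel: VelocitySeries, masks: MaskSeries) -> FlowCurve:
    """Pixel-sign decomposition of the through-plane flow.

    Per frame, with ``s`` the ROI's forward sign and ``a`` the pixel area in
    cm^2: ``forward = sum(max(s*v, 0))*a`` and ``retro = sum(max(-s*v, 0))*a``
    (cm/s x cm^2 = mL/s).
    """
    if vel.n_frames != masks.n_frames:
        raise ShapeMismatchError(
            f"{vel.n_frames} velocity frames vs {masks.n_frames} mask frames"
        )
    sr, sc = vel.pixel_spacing
    a_pix = sr * sc / 100.0  # cm^2
    s = vel.forward_sign
    fwd, retro = [], []
    for fr, m in zip(vel.frames, masks.frames):
        v = s * fr.velocity[m]
        fwd.append(float(np.sum(np.maximum(v, 0.0))) * a_pix)
        retro.append(float(np.sum(np.maximum(-v, 0.0))) * a_pix)
    fwd_arr = np.array(fwd)
    retro_arr = np.array(retro)
    return FlowCurve(
        times=vel.trigger_times / 1000.0,
        net_rate=fwd_arr - retro_arr,
        forward_rate=fwd_arr,
        retro_rate=retro_arr,
    )


def detect_phase_landmarks(curve: FlowCurve, *, mode: str = "strict") -> PhaseLandmarks:
    """Locate peak systole and end systole on a net flow curve.

    Peak systole is the frame of maximal net rate.  End systole is the first
    linearly interpolated downward zero crossing of the net rate after the
    peak; ``end_systole_idx`` is the last frame at or before that crossing.
    Systole spans frames ``[0, end_systole_idx]`` (acquisition is R-wave
    triggered, so systole onset is frame 0), late systole spans
    ``[peak, end_systole_idx]``, diastole the remainder.

    With no crossing after the peak, ``mode="strict"`` raises
    :class:`LandmarkError`; ``mode="lenient"`` falls back to the post-peak
    frame of minimal net rate, with a warning.
    """
    net = curve.net_rate
    if net.size < 3 or np.max(net) <= 0:
        raise LandmarkError("curve must have a positive maximum")
    peak = int(np.argmax(net))

    end_idx = None
    end_time = None
    for i in range(peak, net.size - 1):
        if net[i] > 0 and net[i + 1] <= 0:
            if net[i + 1] == 0.0:
                end_idx, end_time = i + 1, float(curve.times[i + 1])
            else:
                frac = net[i] / (net[i] - net[i + 1])
                end_time = float(curve.times[i] + frac * (curve.times[i + 1] - curve.times[i]))
                end_idx = i
            break
    if end_idx is None:
        if mode == "strict":
            raise LandmarkError("no downward zero crossing of net flow after peak systole")
        warnings.warn(
            "no zero crossing after peak; using post-peak minimum as end systole",
            stacklevel=2,
        )
        end_idx = peak + int(np.argmin(net[peak:]))
        end_time = float(curve.times[end_idx])

    diastole = (end_idx + 1, net.size - 1) if end_idx + 1 <= net.size - 1 else None
    return PhaseLandmarks(
        peak_systole_idx=peak,
        end_systole_idx=end_idx,
        end_systole_time_s=end_time,
        systole_window=(0, end_idx),
        late_systole_window=(peak, end_idx),
        diastole_window=diastole,
    )


def _frame_dt_s(rr_interval_ms: float, n_frames: int) -> float:
    return rr_interval_ms / 1000.0 / n_frames


def cycle_volumes(
    curve: FlowCurve,
    rr_interval: float,
    bsa: float | None = None,
    *,
    rule: str = "rectangle",
) -> tuple[float, float, float | None, float | None]:
    """Forward/backward volumes over the full cycle, optionally BSA-indexed.

    Returns ``(ff, bf, ffi, bfi)`` in mL and mL/m^2; the indexed values are
    ``None`` when no BSA is given.
    """
    if bsa is not None and bsa <= 0:
        raise ValidationError(f"bsa must be > 0, got {bsa}")
    dt = _frame_dt_s(rr_interval, curve.n_frames)
    if rule == "rectangle":
        ff = float(np.sum(curve.forward_rate) * dt)
        bf = float(np.sum(curve.retro_rate) * dt)
    elif rule == "trapezoid":
        ff = float(np.trapezoid(curve.forward_rate, dx=dt))
        bf = float(np.trapezoid(curve.retro_rate, dx=dt))
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    ffi = ff / bsa if bsa is not None else None
    bfi = bf / bsa if bsa is not None else None
    return ff, bf, ffi, bfi


def systolic_flow_metrics(
    curve: FlowCurve, lm: PhaseLandmarks, rr_interval: float
) -> tuple[float, float, float | None]:
    """SFF, SRF (mL) over the systolic window and sFRR (%) = 100*SRF/SFF.

    sFRR is reported as ``None`` (with a warning) when SFF is zero.
    """
    dt = _frame_dt_s(rr_interval, curve.n_frames)
    lo, hi = lm.systole_window
    sl = slice(lo, hi + 1)
    sff = float(np.sum(curve.forward_rate[sl]) * dt)
    srf = float(np.sum(curve.retro_rate[sl]) * dt)
    if sff == 0:
        warnings.warn("systolic forward flow is zero; sFRR undefined", stacklevel=2)
        return sff, srf, None
    return sff, srf, 100.0 * srf / sff


def resample_curve(curve: FlowCurve, factor: int) -> FlowCurve:
    """Linearly resample a curve at ``factor`` x temporal resolution
    (for landmark-stability checks)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    t = np.linspace(curve.times[0], curve.times[-1], (curve.n_frames - 1) * factor + 1)
    fwd = np.interp(t, curve.times, curve.forward_rate)
    retro = np.interp(t, curve.times, curve.retro_rate)
    return FlowCurve(times=t, net_rate=fwd - retro, forward_rate=fwd, retro_rate=retro)


def analyze_series(
    vel: VelocitySeries,
    masks: MaskSeries,
    *,
    bsa: float | None = None,
    fd_gate: float = 12.0,
    landmark_mode: str = "strict",
):
    """Run the full single-series pipeline and return
    ``(FlowMetrics, per-frame DataFrame, PhaseLandmarks)``.

    Convenience orchestrator used by the CLI; combines the flow, area,
    displacement and rotation stages.
    """
    import pandas as pd

    from . import displacement as disp

    curve = compute_flow_curve(vel, masks)
    lm = detect_phase_landmarks(curve, mode=landmark_mode)
    areas = compute_area_series(masks, vel.pixel_spacing)
    ff, bf, ffi, bfi = cycle_volumes(curve, vel.rr_interval, bsa)
    sff, srf, sfrr = systolic_flow_metrics(curve, lm, vel.rr_interval)

    fds = disp.compute_fd_series(vel, masks)
    gated = disp.rotational_angle_series(fds, gate=fd_gate)
    summ = disp.fd_summaries(fds, lm)
    dt = _frame_dt_s(vel.rr_interval, vel.n_frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        delta = disp.delta_ra(gated, lm)
        rot = disp.rotational_speed(gated, lm, dt)

    metrics = FlowMetrics(
        ff=ff,
        bf=bf,
        ffi=ffi,
        bfi=bfi,
        sff=sff,
        srf=srf,
        sfrr=sfrr,
        rac=relative_area_change(areas),
        area_max=float(np.max(areas.areas)),
        area_min=float(np.min(areas.areas)),
        fds_avg=summ["fds_avg"],
        fdls_avg=summ["fdls_avg"],
        fdd_avg=summ["fdd_avg"],
        fdps=summ["fdps"],
        delta_ra=delta,
        rsls_avg=rot.rsls_avg,
    )
    frame_table = pd.DataFrame(
        {
            "time_s": curve.times,
            "net": curve.net_rate,
            "forward": curve.forward_rate,
            "retro": curve.retro_rate,
            "area_cm2": areas.areas,
            "fd_pct": fds.fd,
            "ra_deg": gated.angle,
        }
    )
    return metrics, frame_table, lm
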