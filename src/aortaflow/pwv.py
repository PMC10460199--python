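"""Transit-time pulse wave velocity by the half-maximum method.

The systolic upslope of the ascending and descending aortic flow curves is
timed at the instant the forward rate first reaches half of its peak
(linearly interpolated); PWV = arch path length / (t_half_desc - t_half_asc).
The half-maximum is taken on the forward rate by default, which is robust to
small retrograde components (``which="net"`` switches to the net rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CurveError, ValidationError
from .flow import FlowCurve
from .io import CenterlinePolyline


@dataclass(frozen=True)
class PwvResult:
    t_half_asc: float  # s
    t_half_desc: float  # s
    transit_time: float  # s
    path_length: float  # m
    pwv: float  # m/s


def half_max_time(
    curve: FlowCurve, *, which: str = "forward", min_prominence: float = 0.05
) -> float:
    """Time (s) at which the systolic upslope crosses 50% of the peak rate.

    The search runs from the start of the cycle and keeps the *last* upward
    crossing before the peak, so a small noise blip before the true upslope
    cannot capture the landmark.  Peaks smaller than ``min_prominence`` x max
    rate above the curve minimum are rejected.
    """
    if which == "forward":
        y = curve.forward_rate
    elif which == "net":
        y = curve.net_rate
    else:
        raise ValueError(f"unknown curve selector {which!r}")
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    if peak <= 0 or peak - np.min(y) < min_prominence * abs(peak):
        raise CurveError("no sufficiently prominent systolic peak")
    half = 0.5 * peak
    crossing = None
    for i in range(peak_idx):
        if y[i] < half <= y[i + 1]:
            frac = (half - y[i]) / (y[i + 1] - y[i])
            crossing = float(curve.times[i] + frac * (curve.times[i + 1] - curve.times[i]))
    if crossing is None:
        if y[0] >= half:
            raise CurveError("curve starts above half-maximum; no upslope crossing")
        raise CurveError("no upward half-maximum crossing before the peak")
    return crossing


def arch_length(centerline: CenterlinePolyline) -> float:
    """Polyline arc length in meters (points are in mm)."""
    seg = np.linalg.norm(np.diff(centerline.points, axis=0), axis=1)
    return float(seg.sum()) / 1000.0


def compute_pwv(
    asc: FlowCurve,
    desc: FlowCurve,
    length_m: float,
    *,
    which: str = "forward",
) -> PwvResult:
    """PWV between ascending and descending flow curves.

    Both curves must be positive-forward (the descending series is loaded with
    its own ``forward_sign``).  A non-positive transit time is rejected as
    non-physiological.
    """
    if length_m <= 0:
        raise ValidationError(f"path length must be > 0, got {length_m}")
    t_asc = half_max_time(asc, which=which)
    t_desc = half_max_time(desc, which=which)
    transit = t_desc - t_asc
    if transit <= 0:
        raise CurveError(
            f"non-physiological transit time {transit * 1000:.2f} ms "
            "(descending upslope must follow ascending)"
        )
    return PwvResult(
        t_half_asc=t_asc,
        t_half_desc=t_desc,
        transit_time=transit,
        path_length=length_m,
        pwv=length_m / transit,
    )
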