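"""Ground-truth generators for the flow pipeline and the cohort statistics.

The velocity-cine generator emulates what the analysis assumes about real
phase-contrast data: a systolic-pulse flow waveform carried by an eccentric
(optionally rotating) forward jet, a late-systolic retrograde crescent at the
lumen edge opposite the jet, a pulsatile lumen, a small retrograde diastolic
baseline, and additive Gaussian noise inside the lumen.  Every imposed
quantity is recorded in a :class:`GroundTruth` so recovery can be checked
without re-deriving it from the images.

Construction guarantees, frame by frame:

* the lumen mask is a rasterised disc of the frame's radius;
* the forward jet is a truncated Gaussian centred at the requested offset
  (a fraction of the frame's equivalent diameter, along the requested angle)
  and scaled so its pixel sum equals the waveform's forward rate exactly;
* the retrograde crescent is disjoint from the forward region and scaled so
  its pixel sum equals the frame's retrograde rate exactly — so integrating
  the noise-free fields reproduces the imposed curves to float precision.

All randomness flows through one ``numpy`` generator seeded explicitly; the
output is a pure function of parameters + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .displacement import angle_to_unit
from .errors import ParameterError
from .io import MaskSeries, VelocityFrame, VelocitySeries, equivalent_diameter_mm


@dataclass
class JetParams:
    """Parameters of one simulated velocity-cine acquisition.

    Defaults describe a healthy ascending aorta: RR 820 ms at 30 frames,
    ~287 ms of systole, peak flow sized to eject ~72 mL of systolic forward
    volume, lumen radius pulsing 13.3 -> 15.0 mm, centred laminar jet, no
    retrograde flow, no noise.
    """

    n_frames: int = 30
    grid: int = 96
    spacing: tuple[float, float] = (0.5, 0.5)  # mm (row, col)
    rr_interval_ms: float = 820.0
    systolic_fraction: float = 0.35  # fraction of RR occupied by systole
    peak_flow_ml_s: float = 500.0
    systolic_volume_ml: float | None = None  # overrides peak_flow when set
    diastolic_baseline_ml_s: float = -2.0  # net rate after end systole
    radius_mm: tuple[float, float] = (13.35, 15.0)  # (diastolic min, systolic max)
    offset_fraction: float | np.ndarray = 0.0  # of D_eq, per frame or scalar
    offset_angle_deg: float | np.ndarray = 0.0
    jet_sigma_fraction: float = 0.25  # Gaussian sigma / lumen radius
    retro_volume_ml: float = 0.0  # late-systolic retrograde target
    retro_edge_fraction: float = 0.65
    retro_half_angle_deg: float = 60.0
    noise_sd: float = 0.0  # cm/s, inside the lumen
    roi_label: str = "ascending"
    forward_sign: int = +1
    seed: int | None = None

    def __post_init__(self) -> None:
        frac = np.atleast_1d(np.asarray(self.offset_fraction, dtype=float))
        if np.any(frac >= 0.5):
            raise ParameterError("offset fractions must stay below 0.5 x D_eq")
        if self.noise_sd > 0 and self.seed is None:
            raise ParameterError("a seed is mandatory when noise_sd > 0")
        if not (0 < self.systolic_fraction < 1):
            raise ParameterError("systolic_fraction must be in (0, 1)")
        r_needed = max(self.radius_mm)
        half_extent = self.grid / 2 * min(self.spacing)
        if r_needed >= half_extent:
            raise ParameterError("lumen radius does not fit the grid")


@dataclass
class GroundTruth:
    """Everything the generator imposed, for recovery checks."""

    times_s: np.ndarray
    forward_rate: np.ndarray  # mL/s per frame
    retro_rate: np.ndarray  # mL/s per frame (>= 0)
    net_rate: np.ndarray
    fd_pct: np.ndarray  # imposed jet-centre offset, % of D_eq
    angle_deg: np.ndarray
    radius_mm: np.ndarray
    area_cm2: np.ndarray
    t_sys_s: float  # systolic duration (end-systole truth)
    t_half_s: float  # analytic half-maximum time of the upslope
    peak_flow_ml_s: float
    sff_ml: float  # discrete systolic forward volume
    srf_ml: float  # imposed systolic retrograde volume
    extras: dict = field(default_factory=dict)


def _per_frame(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.size != n:
        raise ParameterError(f"per-frame parameter has {arr.size} values for {n} frames")
    return arr.astype(float)


def _waveform(p: JetParams):
    """Frame times, systolic duration, peak flow, and per-frame rates."""
    n = p.n_frames
    dt = p.rr_interval_ms / 1000.0 / n
    t = np.arange(n) * dt
    t_sys = p.systolic_fraction * p.rr_interval_ms / 1000.0
    in_sys = t < t_sys
    shape = np.zeros(n)
    shape[in_sys] = np.sin(np.pi * t[in_sys] / t_sys) ** 2

    peak = p.peak_flow_ml_s
    if p.systolic_volume_ml is not None:
        discrete = float(np.sum(shape) * dt)
        if discrete <= 0:
            raise ParameterError("systolic window contains no frames")
        peak = p.systolic_volume_ml / discrete
    fwd = peak * shape

    retro = np.zeros(n)
    base = p.diastolic_baseline_ml_s
    if base < 0:
        retro[~in_sys] += -base
    elif base > 0:
        fwd = fwd + np.where(in_sys, 0.0, base)

    if p.retro_volume_ml > 0:
        t_peak = t_sys / 2.0
        window = in_sys & (t > t_peak)
        if not window.any():
            raise ParameterError("no frames in the late-systolic retro window")
        bump = np.zeros(n)
        bump[window] = np.sin(np.pi * (t[window] - t_peak) / (t_sys - t_peak)) ** 2
        scale = p.retro_volume_ml / (np.sum(bump) * dt)
        retro = retro + scale * bump
        if np.any(retro[window] >= fwd[window]):
            raise ParameterError(
                "retrograde target exceeds the forward flow available in the "
                "late-systolic window; net flow would reverse before end systole"
            )
    return t, t_sys, peak, fwd, retro


def simulate_velocity_series(
    p: JetParams,
) -> tuple[VelocitySeries, MaskSeries, GroundTruth]:
    """Generate one velocity-cine series with known ground truth."""
    rng = np.random.default_rng(p.seed)
    n = p.n_frames
    sr, sc = p.spacing
    a_pix_cm2 = sr * sc / 100.0
    t, t_sys, peak, fwd, retro = _waveform(p)

    # lumen radius pulses with the systolic shape
    r_min, r_max = p.radius_mm
    shape = np.where(t < t_sys, np.sin(np.pi * t / t_sys) ** 2, 0.0)
    radius = r_min + (r_max - r_min) * shape

    frac = _per_frame(p.offset_fraction, n)
    angle = _per_frame(p.offset_angle_deg, n)

    cy = cx = (p.grid - 1) / 2.0
    yy, xx = np.mgrid[0 : p.grid, 0 : p.grid]
    y_mm = (yy - cy) * sr
    x_mm = (xx - cx) * sc

    vel_frames: list[VelocityFrame] = []
    mask_frames: list[np.ndarray] = []
    fd_pct = np.zeros(n)
    areas = np.zeros(n)
    for i in range(n):
        r = radius[i]
        rad2 = x_mm**2 + y_mm**2
        mask = rad2 <= r * r
        area_mm2 = float(mask.sum()) * sr * sc
        areas[i] = area_mm2 / 100.0
        d_eq = equivalent_diameter_mm(area_mm2)

        ux, uy = angle_to_unit(angle[i])
        off_mm = frac[i] * d_eq
        jx_mm, jy_mm = off_mm * ux, off_mm * uy
        fd_pct[i] = 100.0 * frac[i]

        v = np.zeros((p.grid, p.grid))

        retro_mask = np.zeros_like(mask)
        if retro[i] > 0:
            # crescent at the lumen edge opposite the jet
            edge = mask & (rad2 > (p.retro_edge_fraction * r) ** 2)
            ax, ay = (-ux, -uy) if off_mm > 0 else angle_to_unit(angle[i] + 180.0)
            radial = np.sqrt(np.maximum(rad2, 1e-12))
            cosang = (x_mm * ax + y_mm * ay) / radial
            retro_mask = edge & (cosang >= math.cos(math.radians(p.retro_half_angle_deg)))
            if not retro_mask.any():
                raise ParameterError(f"frame {i}: retro crescent contains no pixels")
            v[retro_mask] = -retro[i] / (retro_mask.sum() * a_pix_cm2)

        if fwd[i] > 0:
            fwd_mask = mask & ~retro_mask
            sigma = p.jet_sigma_fraction * r
            g = np.exp(-(((x_mm - jx_mm) ** 2) + ((y_mm - jy_mm) ** 2)) / (2 * sigma**2))
            g = np.where(fwd_mask, g, 0.0)
            total = g.sum() * a_pix_cm2
            v = v + fwd[i] * g / total
        elif retro[i] > 0 and not (mask & ~retro_mask).any():
            raise ParameterError(f"frame {i}: retro region covers the whole lumen")

        if p.noise_sd > 0:
            v = v + np.where(mask, rng.normal(0.0, p.noise_sd, v.shape), 0.0)

        vel_frames.append(
            VelocityFrame(velocity=p.forward_sign * v, trigger_time=t[i] * 1000.0)
        )
        mask_frames.append(mask)

    series = VelocitySeries(
        frames=vel_frames,
        pixel_spacing=p.spacing,
        rr_interval=p.rr_interval_ms,
        roi_label=p.roi_label,
        forward_sign=p.forward_sign,
    )
    masks = MaskSeries(frames=mask_frames)
    dt = p.rr_interval_ms / 1000.0 / n
    gt = GroundTruth(
        times_s=t,
        forward_rate=fwd,
        retro_rate=retro,
        net_rate=fwd - retro,
        fd_pct=fd_pct,
        angle_deg=angle,
        radius_mm=radius,
        area_cm2=areas,
        t_sys_s=t_sys,
        t_half_s=t_sys / 4.0,  # sin^2 upslope reaches half-max at Ts/4
        peak_flow_ml_s=peak,
        sff_ml=float(np.sum(fwd[t < t_sys]) * dt),
        srf_ml=float(p.retro_volume_ml),
    )
    return series, masks, gt


def rotating_offset_trajectory(
    p: JetParams,
    *,
    fraction: float,
    rotation_rev_s: float,
    start_angle_deg: float = 0.0,
    window: str = "late_systole",
) -> JetParams:
    """Return params with an offset trajectory rotating at a constant rate.

    The jet sits at ``fraction`` of D_eq on every frame; its angle advances at
    ``rotation_rev_s`` through the chosen window (``"late_systole"`` rotates
    from peak systole onward, ``"all"`` through the whole cycle) and holds
    still elsewhere.
    """
    n = p.n_frames
    dt = p.rr_interval_ms / 1000.0 / n
    t = np.arange(n) * dt
    t_sys = p.systolic_fraction * p.rr_interval_ms / 1000.0
    if window == "all":
        t0 = 0.0
    elif window == "late_systole":
        t0 = t_sys / 2.0
    else:
        raise ParameterError(f"unknown rotation window {window!r}")
    angle = start_angle_deg + 360.0 * rotation_rev_s * np.maximum(t - t0, 0.0)
    return replace(p, offset_fraction=fraction, offset_angle_deg=angle)


def simulate_flow_pair(
    p: JetParams, delay_ms: float, desc_scale: float = 0.7
) -> tuple[
    tuple[VelocitySeries, MaskSeries, GroundTruth],
    tuple[VelocitySeries, MaskSeries, GroundTruth],
]:
    """Ascending series plus a delayed, scaled descending series.

    The descending waveform is the ascending one shifted by ``delay_ms`` and
    scaled by ``desc_scale``, stored with the descending sign convention
    (``forward_sign = -1``); the true transit time is exactly ``delay_ms``.
    """
    t_sys_ms = p.systolic_fraction * p.rr_interval_ms
    if not (0 <= delay_ms < t_sys_ms):
        raise ParameterError("delay must be non-negative and below the systolic duration")
    asc = simulate_velocity_series(p)

    # shift by expressing the delayed waveform through a phase offset of the
    # frame clock: evaluate the ascending waveform at (t - delay)
    n = p.n_frames
    dt_ms = p.rr_interval_ms / n
    desc_p = replace(
        p,
        roi_label="descending",
        forward_sign=-1,
        peak_flow_ml_s=p.peak_flow_ml_s * desc_scale,
        systolic_volume_ml=(
            None if p.systolic_volume_ml is None else p.systolic_volume_ml * desc_scale
        ),
        retro_volume_ml=0.0,
        seed=None if p.seed is None else p.seed + 1,
    )
    desc_series, desc_masks, desc_gt = _simulate_delayed(desc_p, delay_ms)
    return asc, (desc_series, desc_masks, desc_gt)


def _simulate_delayed(p: JetParams, delay_ms: float):
    """Simulate with the waveform evaluated at t - delay (zero before it)."""
    rng = np.random.default_rng(p.seed)
    base = simulate_velocity_series(replace(p, noise_sd=0.0, seed=None))
    series, masks, gt = base
    n = p.n_frames
    dt = p.rr_interval_ms / 1000.0 / n
    t = np.arange(n) * dt
    delay_s = delay_ms / 1000.0
    t_sys = gt.t_sys_s

    shifted = t - delay_s
    shape = np.where((shifted >= 0) & (shifted < t_sys), np.sin(np.pi * shifted / t_sys) ** 2, 0.0)
    fwd = gt.peak_flow_ml_s * shape
    retro = np.where(shifted >= t_sys, max(0.0, -p.diastolic_baseline_ml_s), 0.0)

    sr, sc = p.spacing
    a_pix_cm2 = sr * sc / 100.0
    cy = cx = (p.grid - 1) / 2.0
    yy, xx = np.mgrid[0 : p.grid, 0 : p.grid]
    y_mm = (yy - cy) * sr
    x_mm = (xx - cx) * sc

    vel_frames = []
    for i in range(n):
        mask = masks.frames[i]
        v = np.zeros((p.grid, p.grid))
        if fwd[i] > 0:
            sigma = p.jet_sigma_fraction * gt.radius_mm[i]
            g = np.where(mask, np.exp(-(x_mm**2 + y_mm**2) / (2 * sigma**2)), 0.0)
            v = fwd[i] * g / (g.sum() * a_pix_cm2)
        if retro[i] > 0:
            v = v - np.where(mask, retro[i] / (mask.sum() * a_pix_cm2), 0.0)
        if p.noise_sd > 0:
            v = v + np.where(mask, rng.normal(0.0, p.noise_sd, v.shape), 0.0)
        vel_frames.append(VelocityFrame(velocity=p.forward_sign * v, trigger_time=t[i] * 1000.0))

    out_series = VelocitySeries(
        frames=vel_frames,
        pixel_spacing=p.spacing,
        rr_interval=p.rr_interval_ms,
        roi_label=p.roi_label,
        forward_sign=p.forward_sign,
    )
    out_gt = replace(
        gt,
        forward_rate=fwd,
        retro_rate=retro,
        net_rate=fwd - retro,
        t_half_s=t_sys / 4.0 + delay_s,
        sff_ml=float(np.sum(fwd) * dt),
        extras={"delay_ms": delay_ms},
    )
    return out_series, masks, out_gt


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class CohortParams:
    """Cohort table generator following the composite PVO2 model.

    Covariate means/SDs default to the healthy-cohort values (n=169): forward
    flow index 42.7 +/- 6.5 mL/m^2, FDs_avg 17 +/- 6 %, LVEF 63 +/- 7 %, age
    44 +/- 13 y; PVO2 is the published linear combination plus Gaussian noise
    (6 mL/kg/min, giving R^2 around 0.25).
    """

    n: int = 169
    means: dict[str, float] = field(
        default_factory=lambda: {"ffi": 42.7, "fds_avg": 17.0, "lvef": 63.0}
    )
    sds: dict[str, float] = field(
        default_factory=lambda: {"ffi": 6.5, "fds_avg": 6.0, "lvef": 7.0}
    )
    coefs: dict[str, float] = field(
        default_factory=lambda: {"ffi": 0.443, "fds_avg": -0.261, "lvef": -0.172}
    )
    intercept: float = 20.729
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ParameterError("cohort size must be >= 20")
        if any(s <= 0 for s in self.sds.values()):
            raise ParameterError("covariate SDs must be > 0")


def simulate_cohort(p: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort table with decoy covariates and a high-risk label.

    Covariates are independent normals; ``pvo2`` follows the generating linear
    model with additive noise.  Decoys for selection tests: ``age`` and an
    age-correlated ``ao_max_area``, plus ``rac`` and ``decoy_noise`` (pure
    noise) — none of them enters the PVO2 model.  ``high_risk`` is
    ``pvo2 <= 14`` (the high-risk exercise-capacity stratum).
    """
    rng = np.random.default_rng(p.seed)
    n = p.n
    cov = {k: rng.normal(p.means[k], p.sds[k], n) for k in p.means}
    age = rng.normal(44.0, 13.0, n)
    df = pd.DataFrame(cov)
    df.insert(0, "id", [f"S{i:04d}" for i in range(n)])
    df["age"] = age
    df["sex"] = np.where(rng.random(n) < 96 / 169, "M", "F")
    df["bsa"] = np.clip(rng.normal(1.72, 0.19, n), 1.0, None)
    df["ao_max_area"] = 4.4 + 0.06 * age + rng.normal(0.0, 1.2, n)
    df["rac"] = np.clip(rng.normal(29.0, 16.0, n), 0.0, None)
    df["decoy_noise"] = rng.normal(0.0, 1.0, n)

    signal = p.intercept + sum(p.coefs[k] * cov[k] for k in p.coefs)
    pvo2 = signal + rng.normal(0.0, p.noise_sd, n)
    df["pvo2"] = np.clip(pvo2, 0.0, None)
    df["mets"] = df["pvo2"] / 3.5
    df["high_risk"] = (df["pvo2"] <= 14.0).astype(int)

    record = {
        "intercept": p.intercept,
        "coefs": dict(p.coefs),
        "noise_sd": p.noise_sd,
        "true_terms": sorted(p.coefs),
        "decoys": ["age", "ao_max_area", "rac", "decoy_noise"],
    }
    return df, record


def simulate_repeated_pairs(
    n: int, sigma_between: float, sigma_error: float, seed: int, mu: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Two repeated measurements per subject for agreement statistics.

    Subject truths are N(mu, sigma_between^2); each measurement adds
    independent N(0, sigma_error^2).
    """
    if sigma_between < 0 or sigma_error < 0:
        raise ParameterError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    truth = rng.normal(mu, sigma_between, n)
    m1 = truth + rng.normal(0.0, sigma_error, n)
    m2 = truth + rng.normal(0.0, sigma_error, n)
    return m1, m2
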