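"""Readers/writers and the core containers shared by every analysis stage.

Conventions
-----------
* Coordinates are 0-based with ``x`` = column and ``y`` = row; pixel centers sit
  at integer coordinates.  Centroids are reported in pixel units and converted
  to physical distances with ``pixel_spacing`` (mm/pixel, given as
  ``(row, col)``; anisotropic pixels are allowed and areas always use
  row-spacing x col-spacing).
* Through-plane velocities keep their acquisition sign (cm/s).
  ``forward_sign`` declares which sign is forward for the region of interest:
  +1 for the ascending aorta, -1 for the descending aorta imaged in the same
  plane.
* Image stacks are NIfTI volumes shaped ``(rows, cols, frames)`` with a JSON
  sidecar carrying timing, spacing, and scaling; tables are RFC-4180 CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    MaskError,
    MetadataError,
    ShapeMismatchError,
    TriggerTimeError,
    ValidationError,
)

SIDECAR_KEYS = (
    "rr_interval_ms",
    "trigger_times_ms",
    "pixel_spacing_mm",
    "velocity_scale_cm_per_s",
    "roi_label",
    "forward_sign",
)

MIN_FRAMES = 8


@dataclass(frozen=True)
class VelocityFrame:
    """One cardiac phase: a signed through-plane velocity field (cm/s)."""

    velocity: np.ndarray  # 2-D, cm/s, acquisition sign
    trigger_time: float  # ms from the R-wave


@dataclass
class VelocitySeries:
    """Time-resolved velocity maps covering one cardiac cycle."""

    frames: list[VelocityFrame]
    pixel_spacing: tuple[float, float]  # mm per pixel, (row, col)
    rr_interval: float  # ms
    roi_label: str  # "ascending" | "descending"
    forward_sign: int  # +1 or -1

    def __post_init__(self) -> None:
        if len(self.frames) < MIN_FRAMES:
            raise ValidationError(
                f"need >= {MIN_FRAMES} frames, got {len(self.frames)}"
            )
        if self.forward_sign not in (+1, -1):
            raise ValidationError(f"forward_sign must be +1 or -1, got {self.forward_sign}")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValidationError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        tt = self.trigger_times
        if np.any(np.diff(tt) <= 0):
            raise TriggerTimeError("trigger times must be strictly increasing")
        if tt[-1] >= self.rr_interval:
            raise TriggerTimeError(
                f"last trigger time {tt[-1]} ms must be < rr_interval {self.rr_interval} ms"
            )
        shape = self.frames[0].velocity.shape
        for i, fr in enumerate(self.frames):
            if fr.velocity.ndim != 2 or fr.velocity.shape != shape:
                raise ShapeMismatchError(f"frame {i} shape {fr.velocity.shape} != {shape}")
            if not np.all(np.isfinite(fr.velocity)):
                raise ValidationError(f"frame {i} contains non-finite velocities")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def trigger_times(self) -> np.ndarray:
        return np.array([f.trigger_time for f in self.frames], dtype=float)

    @property
    def frame_duration_ms(self) -> float:
        """Uniform frame duration implied by retrospective gating."""
        return self.rr_interval / self.n_frames

    def stack(self) -> np.ndarray:
        """All frames as a ``(rows, cols, frames)`` array."""
        return np.stack([f.velocity for f in self.frames], axis=-1)


@dataclass
class MaskSeries:
    """Per-frame boolean lumen masks aligned with a :class:`VelocitySeries`."""

    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        shape = self.frames[0].shape
        for i, m in enumerate(self.frames):
            if m.dtype != bool:
                self.frames[i] = m = m.astype(bool)
            if m.shape != shape:
                raise ShapeMismatchError(f"mask frame {i} shape {m.shape} != {shape}")
            if not m.any():
                raise MaskError(f"mask frame {i} has no true pixels")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        return np.stack(self.frames, axis=-1)


@dataclass(frozen=True)
class CenterlinePolyline:
    """Ordered 3-D centerline points in mm (e.g. the aortic arch)."""

    points: np.ndarray  # (n, 3), mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValidationError("centerline needs >= 2 points of 3 coordinates")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValidationError("consecutive centerline points must be distinct")
        object.__setattr__(self, "points", pts)


@dataclass
class SubjectRecord:
    """One row of the cohort table; optional fields are ``None`` when absent."""

    id: str
    age: float
    sex: str
    bsa: float  # m^2
    lvef: float  # %
    height: float | None = None  # cm
    weight: float | None = None  # kg
    pvo2: float | None = None  # mL/kg/min
    mets: float | None = None
    ve_vco2_slope: float | None = None
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.bsa > 0):
            raise ValidationError(f"subject {self.id}: bsa must be > 0, got {self.bsa}")
        if not (0 < self.lvef <= 100):
            raise ValidationError(f"subject {self.id}: lvef must be in (0, 100], got {self.lvef}")
        if self.pvo2 is not None and self.pvo2 < 0:
            raise ValidationError(f"subject {self.id}: pvo2 must be >= 0, got {self.pvo2}")


# ---------------------------------------------------------------------------
# image stacks + sidecar


def save_velocity_series(
    series: VelocitySeries,
    masks: MaskSeries,
    image_stack_path: str | Path,
    sidecar_path: str | Path,
    mask_stack_path: str | Path,
) -> None:
    """Write a series as velocity NIfTI + mask NIfTI + JSON sidecar.

    Velocities are stored divided by ``velocity_scale_cm_per_s`` (1.0 here, so
    the round trip is bit-exact in float64).
    """
    affine = np.diag([series.pixel_spacing[0], series.pixel_spacing[1], 1.0, 1.0])
    vol = series.stack().astype(np.float64)
    img = nib.Nifti1Image(vol, affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(image_stack_path))

    mimg = nib.Nifti1Image(masks.stack().astype(np.uint8), affine)
    nib.save(mimg, str(mask_stack_path))

    sidecar = {
        "rr_interval_ms": series.rr_interval,
        "trigger_times_ms": list(series.trigger_times),
        "pixel_spacing_mm": list(series.pixel_spacing),
        "velocity_scale_cm_per_s": 1.0,
        "roi_label": series.roi_label,
        "forward_sign": series.forward_sign,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def load_velocity_series(
    image_stack_path: str | Path,
    sidecar_path: str | Path,
    mask_stack_path: str | Path,
) -> tuple[VelocitySeries, MaskSeries]:
    """Load and validate a velocity stack, its masks, and the JSON sidecar."""
    try:
        sidecar = json.loads(Path(sidecar_path).read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - malformed file
        raise MetadataError(f"sidecar {sidecar_path} is not valid JSON: {exc}") from exc
    missing = [k for k in SIDECAR_KEYS if k not in sidecar]
    if missing:
        raise MetadataError(f"sidecar missing keys: {missing}")

    vol = np.asarray(nib.load(str(image_stack_path)).get_fdata(dtype=np.float64))
    mvol = np.asarray(nib.load(str(mask_stack_path)).get_fdata(dtype=np.float64))
    if vol.ndim != 3:
        raise ShapeMismatchError(f"velocity stack must be 3-D, got shape {vol.shape}")
    if mvol.shape != vol.shape:
        raise ShapeMismatchError(f"mask stack shape {mvol.shape} != velocity {vol.shape}")

    triggers = np.asarray(sidecar["trigger_times_ms"], dtype=float)
    if triggers.shape[0] != vol.shape[-1]:
        raise ShapeMismatchError(
            f"sidecar has {triggers.shape[0]} trigger times for {vol.shape[-1]} frames"
        )

    scale = float(sidecar["velocity_scale_cm_per_s"])
    frames = [
        VelocityFrame(velocity=vol[..., i] * scale, trigger_time=float(triggers[i]))
        for i in range(vol.shape[-1])
    ]
    series = VelocitySeries(
        frames=frames,
        pixel_spacing=tuple(float(s) for s in sidecar["pixel_spacing_mm"]),
        rr_interval=float(sidecar["rr_interval_ms"]),
        roi_label=str(sidecar["roi_label"]),
        forward_sign=int(sidecar["forward_sign"]),
    )
    masks = MaskSeries(frames=[mvol[..., i] > 0.5 for i in range(mvol.shape[-1])])
    return series, masks


# ---------------------------------------------------------------------------
# tables

REQUIRED_COHORT_COLUMNS = ("id", "age", "sex", "bsa", "lvef")
OPTIONAL_NUMERIC_COLUMNS = ("height", "weight", "pvo2", "mets", "ve_vco2_slope")


def load_cohort_table(csv_path: str | Path) -> list[SubjectRecord]:
    """Read a subject-level CSV into typed records.

    Required columns: ``id, age, sex, bsa, lvef``.  Known optional columns are
    mapped onto record fields; any other numeric column (flow metrics such as
    ``ffi`` or ``fds_avg``) lands in ``record.extras``.  Empty cells become
    ``None``/absent, never zero.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"cohort table missing required column(s): {missing}")

    numeric_cols = [c for c in df.columns if c not in ("id", "sex")]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise MetadataError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        df[col] = coerced

    records = []
    extra_cols = [c for c in numeric_cols if c not in REQUIRED_COHORT_COLUMNS + OPTIONAL_NUMERIC_COLUMNS]
    for _, row in df.iterrows():
        def opt(col: str) -> float | None:
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        extras = {c: float(row[c]) for c in extra_cols if not pd.isna(row[c])}
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                bsa=float(row["bsa"]),
                lvef=float(row["lvef"]),
                height=opt("height"),
                weight=opt("weight"),
                pvo2=opt("pvo2"),
                mets=opt("mets"),
                ve_vco2_slope=opt("ve_vco2_slope"),
                extras=extras,
            )
        )
    return records


def save_cohort_table(records: Sequence[SubjectRecord], csv_path: str | Path) -> None:
    """Write records back to CSV (inverse of :func:`load_cohort_table`)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "bsa": r.bsa,
            "lvef": r.lvef,
        }
        for col in OPTIONAL_NUMERIC_COLUMNS:
            v = getattr(r, col)
            if v is not None:
                row[col] = v
        row.update(r.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records (including extras) into a DataFrame for the stats stage."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "bsa": r.bsa,
            "lvef": r.lvef,
            "height": r.height,
            "weight": r.weight,
            "pvo2": r.pvo2,
            "mets": r.mets,
            "ve_vco2_slope": r.ve_vco2_slope,
        }
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def load_centerline(csv_path: str | Path) -> CenterlinePolyline:
    """Read an ``x_mm,y_mm,z_mm`` CSV into a centerline polyline."""
    df = pd.read_csv(csv_path)
    cols = ["x_mm", "y_mm", "z_mm"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise MetadataError(f"centerline CSV missing column(s): {missing}")
    return CenterlinePolyline(points=df[cols].to_numpy(dtype=float))


def save_centerline(line: CenterlinePolyline, csv_path: str | Path) -> None:
    pd.DataFrame(line.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(csv_path, index=False)


def equivalent_diameter_mm(area_mm2: float) -> float:
    """Diameter of the circle with the given area (the FD normaliser)."""
    return 2.0 * math.sqrt(area_mm2 / math.pi)
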