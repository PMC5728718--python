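"""Readers and writers for the package's plain-text interchange formats.

Formats:

* trace CSV — ``position_um,intensity_au``, one row per sample;
* polyline CSV — ``x_px,y_px``;
* EM annotation CSV (long) — one row per vesicle (or one vesicle-free
  row per section) with columns ``section_index, thickness_nm, has_dp,
  terminal_area_nm2, vesicle_id, x_nm, y_nm, diameter_nm,
  membrane_distance_nm, tethered, dp_contact, dp_distance_nm``;
* ephys event CSV — ``event_time_s,amplitude_pA``; trace CSV —
  ``time_s,current_pA``; train CSV — ``pulse_index,amplitude_pA``.

Images are single-channel TIFF read through tifffile.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .em import SectionAnnotation, VesicleRecord
from .ephys import CurrentTrace, EvokedTrain, MiniEventSeries
from .linescan import LineScanProfile

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_polyline_csv",
    "read_image",
    "read_em_annotations",
    "write_em_annotations",
    "read_current_trace",
    "read_event_series",
    "read_evoked_train",
    "write_metrics_csv",
]


def _require(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")


def read_trace_csv(path, meta: dict | None = None) -> LineScanProfile:
    df = pd.read_csv(path)
    _require(df, {"position_um", "intensity_au"}, path)
    pos = df["position_um"].to_numpy(float)
    step = float(np.median(np.diff(pos))) if pos.size > 1 else 1.0
    return LineScanProfile(
        positions=pos,
        intensities=df["intensity_au"].to_numpy(float),
        pixel_size=step,
        meta=meta or {"source": str(path)},
    )


def write_trace_csv(profile: LineScanProfile, path) -> None:
    pd.DataFrame(
        {"position_um": profile.positions, "intensity_au": profile.intensities}
    ).to_csv(path, index=False)


def read_polyline_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    _require(df, {"x_px", "y_px"}, path)
    return df[["x_px", "y_px"]].to_numpy(float)


def read_image(path) -> np.ndarray:
    import tifffile

    img = np.asarray(tifffile.imread(path), dtype=float)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, got shape {img.shape}")
    return img


def read_em_annotations(path) -> list[SectionAnnotation]:
    """Read a long-format annotation CSV into per-section annotations."""
    df = pd.read_csv(path)
    _require(df, {"section_index", "has_dp", "terminal_area_nm2"}, path)
    sections = []
    for idx, sub in df.groupby("section_index", sort=True):
        first = sub.iloc[0]
        vesicles = []
        for _, row in sub.iterrows():
            if "vesicle_id" not in sub.columns or pd.isna(row.get("vesicle_id")):
                continue
            vesicles.append(
                VesicleRecord(
                    center=(float(row.get("x_nm", math.nan)), float(row.get("y_nm", math.nan))),
                    diameter=float(row.get("diameter_nm", 30.0)),
                    membrane_distance=float(row.get("membrane_distance_nm", math.nan)),
                    tethered=bool(row.get("tethered", False)),
                    dp_contact=bool(row.get("dp_contact", False)),
                    dp_distance=float(row.get("dp_distance_nm", math.nan)),
                )
            )
        sections.append(
            SectionAnnotation(
                index=int(idx),
                has_dp=bool(first["has_dp"]),
                terminal_area=float(first["terminal_area_nm2"]),
                thickness=float(first.get("thickness_nm", 40.0)),
                vesicles=vesicles,
            )
        )
    return sections


def write_em_annotations(sections: list[SectionAnnotation], path) -> None:
    rows = []
    for s in sections:
        common = {
            "section_index": s.index,
            "thickness_nm": s.thickness,
            "has_dp": s.has_dp,
            "terminal_area_nm2": s.terminal_area,
        }
        if not s.vesicles:
            rows.append({**common, "vesicle_id": np.nan})
        for j, v in enumerate(s.vesicles):
            rows.append(
                {
                    **common,
                    "vesicle_id": j,
                    "x_nm": v.center[0],
                    "y_nm": v.center[1],
                    "diameter_nm": v.diameter,
                    "membrane_distance_nm": v.membrane_distance,
                    "tethered": v.tethered,
                    "dp_contact": v.dp_contact,
                    "dp_distance_nm": v.dp_distance,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_current_trace(path) -> CurrentTrace:
    df = pd.read_csv(path)
    _require(df, {"time_s", "current_pA"}, path)
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return CurrentTrace(times=t, current=df["current_pA"].to_numpy(float), sampling_rate=fs)


def read_event_series(path, duration: float | None = None) -> MiniEventSeries:
    df = pd.read_csv(path)
    _require(df, {"event_time_s", "amplitude_pA"}, path)
    t = df["event_time_s"].to_numpy(float)
    if duration is None:
        duration = float(t[-1]) if t.size else 0.0
    return MiniEventSeries(t, df["amplitude_pA"].to_numpy(float), duration)


def read_evoked_train(path, interpulse_interval: float = 0.05) -> EvokedTrain:
    df = pd.read_csv(path)
    _require(df, {"pulse_index", "amplitude_pA"}, path)
    df = df.sort_values("pulse_index")
    return EvokedTrain(df["amplitude_pA"].to_numpy(float), interpulse_interval)


def write_metrics_csv(rows: list[dict], path, columns: list[str] | None = None) -> None:
    """Write per-record metrics; emits a header-only file for empty input."""
    df = pd.DataFrame(rows, columns=columns if (columns and not rows) else None)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
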