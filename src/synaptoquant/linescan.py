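"""Fluorescence line-scan quantification along neurites.

The central statistic is synaptic enrichment (% ΔF/F): a sliding window
(2 μm by default) identifies every local fluorescence peak and trough
along the profile, and enrichment is the percent excess of the mean peak
value over the mean trough value.  High enrichment means the reporter is
concentrated in puncta (presynaptic clusters); low enrichment means it is
diffusely distributed along the neurite.  The module also counts puncta
above a threshold and integrates intensity per unit neurite length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LineScanProfile",
    "ExtremaSet",
    "EnrichmentResult",
    "PunctaSet",
    "extract_profile",
    "find_extrema",
    "synaptic_enrichment",
    "classify_distribution",
    "count_puncta",
    "intensity_per_length",
]

#: Default sliding-window width for extrema detection, micrometers.
DEFAULT_WINDOW_UM = 2.0

_REL_TOL = 1e-9


@dataclass(frozen=True)
class LineScanProfile:
    """Evenly sampled 1D fluorescence trace along a neurite.

    Parameters
    ----------
    positions : array of float
        Sample positions in micrometers, strictly increasing with a
        constant step equal to ``pixel_size``.  Positions are 0-based and
        refer to sample centers.
    intensities : array of float
        Fluorescence in arbitrary units; finite and non-negative.
    pixel_size : float
        Micrometers per sample.
    meta : dict
        Free-form labels (animal id, neuron, genotype, reporter).
    """

    positions: np.ndarray
    intensities: np.ndarray
    pixel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.ndim != 1 or inten.shape != pos.shape:
            raise ValueError("positions and intensities must be 1D and equal length")
        if pos.size < 2:
            raise ValueError("profile needs at least 2 samples")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        scale = max(abs(self.pixel_size), 1.0)
        if not np.allclose(steps, self.pixel_size, rtol=_REL_TOL, atol=_REL_TOL * scale):
            raise ValueError("sampling step must be uniform and equal to pixel_size")
        if not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def length_um(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class ExtremaSet:
    """Alternating local peaks and troughs found by the sliding window."""

    peak_positions: np.ndarray
    peak_values: np.ndarray
    trough_positions: np.ndarray
    trough_values: np.ndarray
    window: float

    def __post_init__(self):
        for name in ("peak_positions", "peak_values", "trough_positions", "trough_values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.peak_positions.shape != self.peak_values.shape:
            raise ValueError("peak arrays must match in length")
        if self.trough_positions.shape != self.trough_values.shape:
            raise ValueError("trough arrays must match in length")
        # strict alternation along position
        tagged = sorted(
            [(p, "P") for p in self.peak_positions] + [(p, "T") for p in self.trough_positions]
        )
        for (a, ta), (b, tb) in zip(tagged, tagged[1:]):
            if ta == tb:
                raise ValueError(f"extrema do not alternate near position {a:.4g}")

    @property
    def n_peaks(self) -> int:
        return self.peak_positions.size

    @property
    def n_troughs(self) -> int:
        return self.trough_positions.size


@dataclass(frozen=True)
class EnrichmentResult:
    """Synaptic enrichment (% ΔF/F) and the derived phenotype call."""

    delta_f_over_f_percent: float
    n_peaks: int
    n_troughs: int
    classification: str  # punctate | diffuse | indeterminate


@dataclass(frozen=True)
class PunctaSet:
    """Peaks exceeding a threshold, as a punctum count plus per-punctum data."""

    count: int
    punctum_positions: np.ndarray
    punctum_peak_values: np.ndarray
    threshold_used: float

    def __post_init__(self):
        object.__setattr__(self, "punctum_positions", np.asarray(self.punctum_positions, float))
        object.__setattr__(self, "punctum_peak_values", np.asarray(self.punctum_peak_values, float))
        if self.count != self.punctum_positions.size or self.count != self.punctum_peak_values.size:
            raise ValueError("count must equal number of punctum positions/values")


def extract_profile(
    image: np.ndarray,
    polyline: Sequence[Sequence[float]],
    half_width: float,
    step: float,
    pixel_size: float,
) -> LineScanProfile:
    """Sample a 2D image along a polyline into a uniform 1D profile.

    Emulates a segmented line scan: the image is sampled by bilinear
    interpolation at equal arc-length intervals of ``step`` (micrometers)
    along the polyline, averaging across the perpendicular band of
    ``±half_width`` pixels at each sample point.

    Parameters
    ----------
    image : 2D array
        Grayscale intensity grid indexed as ``image[row, col]``.
    polyline : sequence of (x_px, y_px)
        Ordered vertices in pixel coordinates; ``x`` is the column and
        ``y`` the row.
    half_width : float
        Half-width of the perpendicular averaging band, in pixels.
    step : float
        Sampling interval along the line, micrometers.
    pixel_size : float
        Micrometers per image pixel.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    verts = np.asarray(polyline, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 2:
        raise ValueError("polyline must have at least 2 (x, y) vertices")
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if step <= 0 or pixel_size <= 0:
        raise ValueError("step and pixel_size must be > 0")
    nrow, ncol = img.shape
    for i, (x, y) in enumerate(verts):
        if not (0 <= x <= ncol - 1 and 0 <= y <= nrow - 1):
            raise ValueError(f"polyline vertex {i} at ({x}, {y}) lies outside the image")

    seg = np.diff(verts, axis=0)
    seg_len_px = np.hypot(seg[:, 0], seg[:, 1])
    arc_px = float(seg_len_px.sum())
    if arc_px == 0:
        raise ValueError("polyline has zero length")
    arc_um = arc_px * pixel_size
    n = int(np.floor(arc_um / step + 1e-9)) + 1
    s_um = np.arange(n) * step
    s_px = s_um / pixel_size

    # point and tangent at each arc length
    cum = np.concatenate([[0.0], np.cumsum(seg_len_px)])
    idx = np.clip(np.searchsorted(cum, s_px, side="right") - 1, 0, len(seg_len_px) - 1)
    frac = (s_px - cum[idx]) / seg_len_px[idx]
    pts = verts[idx] + frac[:, None] * seg[idx]
    tang = seg[idx] / seg_len_px[idx, None]
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    n_off = 2 * int(round(half_width)) + 1
    offsets = np.linspace(-half_width, half_width, n_off) if half_width > 0 else np.array([0.0])
    band = pts[None, :, :] + offsets[:, None, None] * normal[None, :, :]  # (off, n, 2)
    rows = band[..., 1].ravel()
    cols = band[..., 0].ravel()
    vals = ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")
    profile = vals.reshape(len(offsets), n).mean(axis=0)
    profile = np.maximum(profile, 0.0)
    return LineScanProfile(positions=s_um, intensities=profile, pixel_size=step)


def _window_candidates(x: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray]:
    """Window-maximum / window-minimum candidate masks (ties included)."""
    size = 2 * h + 1
    maxf = ndimage.maximum_filter1d(x, size=size, mode="nearest")
    minf = ndimage.minimum_filter1d(x, size=size, mode="nearest")
    return x >= maxf, x <= minf


def _leftmost_of_plateau(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep a candidate only at the leftmost index of its equal-value run."""
    keep = mask.copy()
    same_as_left = np.zeros_like(mask)
    same_as_left[1:] = x[1:] == x[:-1]
    keep &= ~same_as_left
    return keep


def _enforce_alternation(
    x: np.ndarray, peak_idx: list[int], trough_idx: list[int]
) -> tuple[list[int], list[int]]:
    """Merge candidate lists into a strictly alternating peak/trough sequence.

    Between two consecutive same-type candidates the opposite extremum of
    the raw samples strictly between them is inserted when it is strictly
    more extreme than both; otherwise the less extreme (or later, on ties)
    candidate is dropped.
    """
    events = sorted([(i, "P") for i in peak_idx] + [(i, "T") for i in trough_idx])
    out: list[tuple[int, str]] = []
    for i, t in events:
        if not out or out[-1][1] != t:
            out.append((i, t))
            continue
        j = out[-1][0]
        between = x[j + 1 : i]
        if between.size:
            if t == "P":
                m = j + 1 + int(np.argmin(between))
                if x[m] < min(x[j], x[i]):
                    out.append((m, "T"))
                    out.append((i, "P"))
                    continue
            else:
                m = j + 1 + int(np.argmax(between))
                if x[m] > max(x[j], x[i]):
                    out.append((m, "P"))
                    out.append((i, "T"))
                    continue
        # no separating extremum: keep the more extreme candidate (leftmost on ties)
        if (t == "P" and x[i] > x[j]) or (t == "T" and x[i] < x[j]):
            out[-1] = (i, t)
    # drop degenerate adjacent pairs where peak fails to exceed trough
    changed = True
    while changed:
        changed = False
        for k in range(len(out) - 1):
            (i, ti), (j, tj) = out[k], out[k + 1]
            hi, lo = (i, j) if ti == "P" else (j, i)
            if x[hi] <= x[lo]:
                del out[k : k + 2]
                changed = True
                break
    return [i for i, t in out if t == "P"], [i for i, t in out if t == "T"]


def find_extrema(profile: LineScanProfile, window: float = DEFAULT_WINDOW_UM) -> ExtremaSet:
    """Locate alternating local peaks and troughs with a sliding window.

    A sample is a peak (trough) candidate iff it is ≥ (≤) every other
    sample within ``±window/2`` of its position.  Plateau ties go to the
    leftmost sample; candidates that are simultaneously window-maximum
    and window-minimum (zero local contrast) are discarded, as are
    candidates within ``window/2`` of either trace end.  Alternation is
    then enforced (see :func:`_enforce_alternation`).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    x = profile.intensities
    pos = profile.positions
    px = profile.pixel_size
    half = window / 2.0
    h = int(np.floor(half / px + 1e-9))
    if h < 1:
        raise ValueError("window spans fewer than 2 samples at this pixel size")
    if x.size < int(np.floor(window / px)):
        raise ValueError("profile shorter than the sliding window")

    peak_mask, trough_mask = _window_candidates(x, h)
    dual = peak_mask & trough_mask
    peak_mask &= ~dual
    trough_mask &= ~dual
    peak_mask = _leftmost_of_plateau(x, peak_mask)
    trough_mask = _leftmost_of_plateau(x, trough_mask)

    eps = 1e-9 * max(window, 1.0)
    interior = (pos - pos[0] >= half - eps) & (pos[-1] - pos >= half - eps)
    peak_idx = np.nonzero(peak_mask & interior)[0].tolist()
    trough_idx = np.nonzero(trough_mask & interior)[0].tolist()

    peaks, troughs = _enforce_alternation(x, peak_idx, trough_idx)
    return ExtremaSet(
        peak_positions=pos[peaks],
        peak_values=x[peaks],
        trough_positions=pos[troughs],
        trough_values=x[troughs],
        window=window,
    )


def synaptic_enrichment(
    extrema: ExtremaSet,
    cutoff_percent: float | None = None,
) -> EnrichmentResult:
    """Compute synaptic enrichment as % ΔF/F from peak and trough values.

    ΔF/F% = 100 × (mean(F_peak) − mean(F_trough)) / mean(F_trough).
    With no peaks the trace carries no punctate signal: the result is 0%
    and the classification is ``indeterminate``.
    """
    from .config import DEFAULT_CUTOFF_PCT

    if cutoff_percent is None:
        cutoff_percent = DEFAULT_CUTOFF_PCT
    if extrema.n_peaks == 0:
        return EnrichmentResult(0.0, 0, extrema.n_troughs, "indeterminate")
    mean_peak = float(np.mean(extrema.peak_values))
    mean_trough = float(np.mean(extrema.trough_values)) if extrema.n_troughs else mean_peak
    if mean_trough <= 0:
        raise ValueError("mean trough fluorescence must be positive (non-physical baseline)")
    dff = 100.0 * (mean_peak - mean_trough) / mean_trough
    cls = "punctate" if dff >= cutoff_percent else "diffuse"
    return EnrichmentResult(dff, extrema.n_peaks, extrema.n_troughs, cls)


def classify_distribution(enrichment: EnrichmentResult, cutoff: float) -> str:
    """Score a neuron as 'punctate' or 'diffuse' at an enrichment cutoff (%)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return "punctate" if enrichment.delta_f_over_f_percent >= cutoff else "diffuse"


_REL_SPEC = re.compile(r"^\s*mean\s*\+\s*([0-9.]+)\s*\*?\s*sd\s*$", re.IGNORECASE)


def resolve_threshold(profile: LineScanProfile, threshold_spec: float | str) -> float:
    """Resolve an absolute or 'mean+k*sd' threshold spec to fluorescence units."""
    if isinstance(threshold_spec, str):
        m = _REL_SPEC.match(threshold_spec)
        if not m:
            raise ValueError(f"unrecognized threshold spec {threshold_spec!r}")
        k = float(m.group(1))
        sd = float(np.std(profile.intensities))
        if sd == 0:
            raise ValueError("relative threshold undefined on a zero-variance trace")
        return float(np.mean(profile.intensities)) + k * sd
    thr = float(threshold_spec)
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    return thr


def count_puncta(
    profile: LineScanProfile,
    threshold_spec: float | str = "mean+2sd",
    window: float = DEFAULT_WINDOW_UM,
) -> PunctaSet:
    """Count fluorescence peaks above a threshold (puncta).

    Puncta are the sliding-window peaks of :func:`find_extrema` whose
    peak value strictly exceeds the resolved threshold.
    """
    thr = resolve_threshold(profile, threshold_spec)
    ext = find_extrema(profile, window=window)
    keep = ext.peak_values > thr
    return PunctaSet(
        count=int(keep.sum()),
        punctum_positions=ext.peak_positions[keep],
        punctum_peak_values=ext.peak_values[keep],
        threshold_used=thr,
    )


def intensity_per_length(profile: LineScanProfile) -> float:
    """Total integrated intensity normalized to neurite length (AU/μm)."""
    span = profile.length_um
    if span <= 0:
        raise ValueError("profile spans zero length")
    total = float(np.trapezoid(profile.intensities, profile.positions))
    return total / span
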