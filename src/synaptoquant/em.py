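"""Serial-section electron-microscopy synapse morphometry.

Operates on per-section annotations (not raw micrographs): each 40 nm
ultrathin section carries a dense-projection (DP) flag, the
cross-sectional area of the presynaptic terminal, and a list of vesicle
records.  A synapse is the maximal run of DP-containing sections plus
flanking DP-free sections; DP runs separated by fewer than two empty
sections are merged, since a synapse boundary requires the flanking
empties to exist.  From a reconstruction the module computes terminal
area, DP length in profiles, vesicle counts and density, docking
classification (membrane contact, with the 1–4 nm tethered-vesicle
exclusion), docked vesicles within a radius of the DP, and undocked
vesicles contacting the DP per profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VesicleRecord",
    "SectionAnnotation",
    "SynapseReconstruction",
    "SynapseMetrics",
    "delimit_synapses",
    "terminal_area_mean",
    "dp_length",
    "classify_docked",
    "vesicle_density",
    "docked_near_dp",
    "undocked_touching_dp",
    "compute_metrics",
]

#: Default ultrathin-section thickness, nanometers.
SECTION_THICKNESS_NM = 40.0
#: Default search radius around the dense projection for docked vesicles, nm.
DP_RADIUS_NM = 100.0
#: Membrane-distance band (nm) in which a visible tether excludes docking.
TETHER_BAND_NM = (1.0, 4.0)

NM2_PER_UM2 = 1e6


@dataclass
class VesicleRecord:
    """One annotated synaptic vesicle within a section plane.

    ``membrane_distance`` and ``dp_distance`` are measured from the
    vesicle's outer edge (0 = contact).  ``dp_distance`` may be NaN when
    the section has no dense projection.
    """

    center: tuple[float, float]
    diameter: float = 30.0
    membrane_distance: float = math.nan
    tethered: bool = False
    dp_contact: bool = False
    dp_distance: float = math.nan

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("vesicle diameter must be > 0")
        if not math.isnan(self.membrane_distance) and self.membrane_distance < 0:
            raise ValueError("membrane_distance must be >= 0")
        if not math.isnan(self.dp_distance):
            if self.dp_distance < 0:
                raise ValueError("dp_distance must be >= 0")
            if self.dp_distance == 0:
                self.dp_contact = True


@dataclass
class SectionAnnotation:
    """Annotations for one serial section."""

    index: int
    has_dp: bool
    terminal_area: float = 0.0  # nm^2
    thickness: float = SECTION_THICKNESS_NM
    dp_outline: np.ndarray | None = None  # (k, 2) polygon, nm
    vesicles: list[VesicleRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("section thickness must be > 0")
        if self.terminal_area < 0:
            raise ValueError("terminal_area must be >= 0")
        if self.dp_outline is not None and not self.has_dp:
            raise ValueError("section with a DP outline must have has_dp=True")


@dataclass
class SynapseReconstruction:
    """Ordered sections of one synapse plus the DP-containing span.

    ``dp_span`` is a half-open absolute-index interval from the first to
    one past the last DP-containing section.  For merged DP runs the span
    may contain interior DP-free gap sections; those do not count toward
    DP length.
    """

    sections: list[SectionAnnotation]
    dp_span: tuple[int, int]

    def __post_init__(self):
        idx = [s.index for s in self.sections]
        if any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("synapse sections must be consecutive")
        lo, hi = self.dp_span
        if not any(s.has_dp for s in self.sections):
            raise ValueError("synapse must contain a dense projection")
        if not (self._section(lo).has_dp and self._section(hi - 1).has_dp):
            raise ValueError("dp_span must start and end on DP-containing sections")

    def _section(self, index: int) -> SectionAnnotation:
        off = index - self.sections[0].index
        return self.sections[off]

    @property
    def dp_sections(self) -> list[SectionAnnotation]:
        return [s for s in self.sections if s.has_dp]


@dataclass(frozen=True)
class SynapseMetrics:
    """All per-synapse morphometric quantities."""

    terminal_area_mean: float  # nm^2
    dp_length_profiles: int
    dp_length_nm: float
    total_vesicles: int
    docked_vesicles: int
    vesicle_density: float  # vesicles per um^2
    docked_within_100nm: int
    undocked_touching_dp_per_profile: tuple[int, ...]

    def __post_init__(self):
        if self.docked_vesicles > self.total_vesicles:
            raise ValueError("docked count cannot exceed total")
        if self.docked_within_100nm > self.docked_vesicles:
            raise ValueError("docked-near-DP count cannot exceed docked count")


def delimit_synapses(
    series: Sequence[SectionAnnotation],
    flank: int = 1,
    merge_gap: int = 2,
) -> list[SynapseReconstruction]:
    """Split a serial-section series into synapse reconstructions.

    Maximal runs of DP-containing sections become ``dp_span``s; runs
    separated by fewer than ``merge_gap`` DP-free sections merge into one
    synapse (the gap sections included).  Each synapse then takes
    ``flank`` DP-free sections on each side where available (truncated at
    the series ends).  Returned synapses are disjoint and ordered.
    """
    sections = list(series)
    idx = [s.index for s in sections]
    for a, b in zip(idx, idx[1:]):
        if b - a != 1:
            raise ValueError(f"section indices must be consecutive; gap between {a} and {b}")
    flags = [bool(s.has_dp) for s in sections]

    # maximal DP runs as [start, end) offsets
    runs: list[list[int]] = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    # merge runs separated by fewer than merge_gap empty sections
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    out = []
    for start, end in merged:
        lo = max(0, start - flank)
        hi = min(len(sections), end + flank)
        out.append(
            SynapseReconstruction(
                sections=sections[lo:hi],
                dp_span=(idx[start], idx[end - 1] + 1),
            )
        )
    return out


def terminal_area_mean(synapse: SynapseReconstruction) -> float:
    """Mean cross-sectional terminal area (nm²) over DP sections plus flanks."""
    areas = np.array([s.terminal_area for s in synapse.sections], dtype=float)
    if np.any(areas < 0):
        raise ValueError("terminal areas must be >= 0")
    return float(areas.mean())


def dp_length(synapse: SynapseReconstruction) -> tuple[int, float]:
    """Dense-projection length as (number of DP profiles, total nm).

    Only sections in which the DP is observed count; interior gap
    sections of a merged run do not.
    """
    dps = synapse.dp_sections
    return len(dps), float(sum(s.thickness for s in dps))


def classify_docked(vesicle: VesicleRecord, contact_tolerance: float = 0.0) -> str:
    """Classify a vesicle as 'docked' or 'undocked'.

    Docked means the vesicle contacts the plasma membrane
    (``membrane_distance`` ≤ ``contact_tolerance``, default exact
    contact).  A vesicle held 1–4 nm off the membrane by a visible tether
    is explicitly not docked, regardless of tolerance.
    """
    d = vesicle.membrane_distance
    if math.isnan(d):
        raise ValueError("vesicle has no membrane_distance annotation")
    lo, hi = TETHER_BAND_NM
    if vesicle.tethered and lo <= d <= hi:
        return "undocked"
    return "docked" if d <= contact_tolerance else "undocked"


def _docked_mask(synapse: SynapseReconstruction, contact_tolerance: float) -> list[list[bool]]:
    return [
        [classify_docked(v, contact_tolerance) == "docked" for v in s.vesicles]
        for s in synapse.sections
    ]


def vesicle_density(synapse: SynapseReconstruction) -> float:
    """Vesicles per μm² of mean terminal cross-section."""
    area_nm2 = terminal_area_mean(synapse)
    if area_nm2 <= 0:
        raise ValueError("terminal area must be positive to compute density")
    total = sum(len(s.vesicles) for s in synapse.sections)
    return total / (area_nm2 / NM2_PER_UM2)


def docked_near_dp(
    synapse: SynapseReconstruction,
    radius: float = DP_RADIUS_NM,
    contact_tolerance: float = 0.0,
) -> int:
    """Count docked vesicles within ``radius`` nm of the dense projection.

    Straight-line in-plane distance from the vesicle's outer edge to the
    nearest DP boundary point, summed over DP-containing sections.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n = 0
    for s in synapse.dp_sections:
        for v in s.vesicles:
            if classify_docked(v, contact_tolerance) == "docked":
                if math.isnan(v.dp_distance):
                    raise ValueError(
                        f"docked vesicle in section {s.index} lacks a dp_distance annotation"
                    )
                if v.dp_distance <= radius:
                    n += 1
    return n


def undocked_touching_dp(
    synapse: SynapseReconstruction, contact_tolerance: float = 0.0
) -> tuple[list[int], int]:
    """Undocked vesicles contacting the DP, per DP-containing profile.

    Returns the per-profile counts (in section order) and their sum.
    """
    counts = []
    for s in synapse.dp_sections:
        c = sum(
            1
            for v in s.vesicles
            if v.dp_contact and classify_docked(v, contact_tolerance) == "undocked"
        )
        counts.append(c)
    return counts, sum(counts)


def compute_metrics(
    synapse: SynapseReconstruction,
    radius: float = DP_RADIUS_NM,
    contact_tolerance: float = 0.0,
) -> SynapseMetrics:
    """Assemble the full morphometric summary for one synapse."""
    area = terminal_area_mean(synapse)
    n_profiles, nm = dp_length(synapse)
    docked = sum(sum(row) for row in _docked_mask(synapse, contact_tolerance))
    total = sum(len(s.vesicles) for s in synapse.sections)
    per_profile, _ = undocked_touching_dp(synapse, contact_tolerance)
    return SynapseMetrics(
        terminal_area_mean=area,
        dp_length_profiles=n_profiles,
        dp_length_nm=nm,
        total_vesicles=total,
        docked_vesicles=docked,
        vesicle_density=vesicle_density(synapse) if area > 0 else 0.0,
        docked_within_100nm=docked_near_dp(synapse, radius, contact_tolerance),
        undocked_touching_dp_per_profile=tuple(per_profile),
    )
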