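"""Synthetic data generators with the statistical structure the analyses assume.

No imaging, EM, or electrophysiology data accompany the quantification
procedures this package implements, so every analysis stage is exercised
on simulated inputs with known ground truth:

* line scans — a Poisson process of Gaussian puncta on a flat background;
  the "diffuse" phenotype redistributes a fraction of punctum mass
  uniformly along the neurite (mass is conserved, matching the
  observation that loss of punctate signal is accompanied by a rise in
  extrasynaptic signal, not by loss of reporter);
* EM reconstructions — one contiguous dense-projection run centered in a
  section series, vesicles clustered around the DP with exponentially
  decaying distances, and docked / tethered / free membrane-distance
  classes drawn with known fractions;
* mini trains — homogeneous Poisson event times with lognormal
  amplitudes, optionally rendered into a noisy current trace;
* evoked trains — geometric per-pulse retention with multiplicative
  unit-mean lognormal noise;
* paralysis assays — per-animal paralysis times for a cholinesterase
  inhibitor time course, counted per plate.

Every generator is deterministic under its seed and returns the ground
truth needed for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import SectionAnnotation, VesicleRecord
from .ephys import CurrentTrace, EvokedTrain, MiniEventSeries
from .linescan import LineScanProfile

__all__ = [
    "LineScanParams",
    "EMSynapseParams",
    "gen_linescan",
    "gen_em_synapse",
    "gen_mini_train",
    "gen_mini_trace",
    "gen_evoked_train",
    "gen_paralysis_assay",
]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV."""
    if cv <= 0:
        return np.full(size, mean, dtype=float)
    s2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


@dataclass
class LineScanParams:
    """Study conditions for synthetic neurite line scans.

    Defaults describe a typical synaptic-vesicle reporter along a ~40 μm
    neurite segment: about one punctum every 2 μm, diffraction-limited
    punctum width (σ 0.3 μm), punctum amplitude a few-fold over the
    extrasynaptic background, and modest acquisition noise.
    ``diffuse_fraction`` interpolates between a fully punctate (0) and a
    fully delocalized (1) reporter by redistributing that fraction of
    every punctum's mass uniformly along the trace.
    """

    length: float = 40.0  # um
    pixel_size: float = 0.1  # um
    punctum_rate: float = 0.5  # puncta per um
    punctum_amplitude: float = 8.0  # AU, mean
    punctum_amplitude_cv: float = 0.3
    punctum_sigma: float = 0.3  # um
    background: float = 2.0  # AU
    diffuse_fraction: float = 0.0
    noise_sd: float = 0.5  # AU
    seed: int = 0

    def __post_init__(self):
        if self.length <= 0 or self.pixel_size <= 0:
            raise ValueError("length and pixel_size must be > 0")
        if not 0.0 <= self.diffuse_fraction <= 1.0:
            raise ValueError("diffuse_fraction must lie in [0, 1]")
        if min(self.punctum_rate, self.punctum_sigma, self.background) < 0 or self.noise_sd < 0:
            raise ValueError("rates, widths, background and noise must be >= 0")


def gen_linescan(params: LineScanParams) -> tuple[LineScanProfile, dict]:
    """Simulate a line-scan profile; returns (profile, ground truth).

    Puncta are placed by a Poisson process (kept ≥4σ from the trace ends
    so the analytic punctum mass lies on the trace); each contributes a
    Gaussian of mass ``(1 − diffuse_fraction) × A σ √(2π)`` and the
    diffuse fraction of the total mass is spread uniformly.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.length / p.pixel_size)) + 1
    x = np.arange(n) * p.pixel_size
    trace = np.full(n, p.background, dtype=float)

    n_puncta = rng.poisson(p.punctum_rate * p.length)
    margin = 4.0 * p.punctum_sigma
    lo, hi = margin, max(margin, p.length - margin)
    centers = np.sort(rng.uniform(lo, hi, n_puncta))
    amps = _lognormal(rng, p.punctum_amplitude, p.punctum_amplitude_cv, n_puncta)

    total_mass = 0.0
    for c, a in zip(centers, amps):
        mass = a * p.punctum_sigma * math.sqrt(2.0 * math.pi)
        total_mass += mass
        trace += (1.0 - p.diffuse_fraction) * a * np.exp(
            -0.5 * ((x - c) / p.punctum_sigma) ** 2
        )
    trace += p.diffuse_fraction * total_mass / p.length
    if p.noise_sd > 0:
        trace += rng.normal(0.0, p.noise_sd, n)
    trace = np.maximum(trace, 0.0)
    profile = LineScanProfile(
        positions=x,
        intensities=trace,
        pixel_size=p.pixel_size,
        meta={"source": "synthetic", "diffuse_fraction": p.diffuse_fraction},
    )
    truth = {
        "punctum_positions": centers,
        "punctum_amplitudes": amps,
        "total_punctum_mass": total_mass,
        "label": "diffuse" if p.diffuse_fraction >= 0.5 else "punctate",
    }
    return profile, truth


@dataclass
class EMSynapseParams:
    """Study conditions for one synthetic serial-section synapse.

    Defaults emulate a cholinergic dorsal-cord terminal: 40 nm sections,
    a dense projection spanning a few profiles, ~0.25 μm² terminal
    cross-sections, ~30 nm vesicles clustered around the DP with
    exponentially decaying in-plane distance, and a small docked pool at
    the plasma membrane.
    """

    n_sections: int = 9
    dp_run_length: int = 3
    terminal_area_mean: float = 250_000.0  # nm^2 (0.25 um^2)
    terminal_area_sd: float = 50_000.0
    n_vesicles_per_section: float = 30.0  # Poisson mean
    docked_fraction: float = 0.10
    tethered_fraction: float = 0.10
    dp_cluster_scale: float = 150.0  # nm
    vesicle_diameter: float = 30.0  # nm
    dp_contact_snap: float = 5.0  # nm: distances below this are annotated as contact
    thickness: float = 40.0  # nm
    seed: int = 0

    def __post_init__(self):
        if self.dp_run_length > self.n_sections - 2:
            raise ValueError("dp_run_length must leave at least one DP-free section per side")
        for f in (self.docked_fraction, self.tethered_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_sections, self.dp_run_length, self.dp_cluster_scale, self.thickness) <= 0:
            raise ValueError("geometry parameters must be positive")


def gen_em_synapse(params: EMSynapseParams) -> tuple[list[SectionAnnotation], dict]:
    """Simulate an annotated section series; returns (sections, ground truth)."""
    p = params
    rng = np.random.default_rng(p.seed)
    dp_start = (p.n_sections - p.dp_run_length) // 2
    dp_end = dp_start + p.dp_run_length

    sections: list[SectionAnnotation] = []
    n_docked_true = 0
    n_total = 0
    docked_per_section: list[int] = []
    total_per_section: list[int] = []
    for i in range(p.n_sections):
        has_dp = dp_start <= i < dp_end
        area = max(float(rng.normal(p.terminal_area_mean, p.terminal_area_sd)), 1.0)
        side = math.sqrt(area)
        vesicles = []
        sec_docked = sec_total = 0
        for _ in range(rng.poisson(p.n_vesicles_per_section)):
            center = (float(rng.uniform(0, side)), float(rng.uniform(0, side)))
            u = rng.uniform()
            if u < p.docked_fraction:
                mdist, teth = 0.0, False
                n_docked_true += 1
                sec_docked += 1
            elif u < p.docked_fraction + p.tethered_fraction:
                mdist, teth = float(rng.uniform(1.0, 4.0)), True
            else:
                mdist, teth = float(rng.uniform(5.0, 300.0)), False
            if has_dp:
                dpd = float(rng.exponential(p.dp_cluster_scale))
                if dpd < p.dp_contact_snap:
                    dpd = 0.0
            else:
                dpd = math.nan
            vesicles.append(
                VesicleRecord(
                    center=center,
                    diameter=p.vesicle_diameter,
                    membrane_distance=mdist,
                    tethered=teth,
                    dp_contact=(dpd == 0.0),
                    dp_distance=dpd,
                )
            )
            n_total += 1
            sec_total += 1
        docked_per_section.append(sec_docked)
        total_per_section.append(sec_total)
        sections.append(
            SectionAnnotation(
                index=i,
                has_dp=has_dp,
                terminal_area=area,
                thickness=p.thickness,
                vesicles=vesicles,
            )
        )
    truth = {
        "dp_run_length": p.dp_run_length,
        "dp_span": (dp_start, dp_end),
        "n_docked": n_docked_true,
        "n_vesicles": n_total,
        "docked_per_section": docked_per_section,
        "total_per_section": total_per_section,
        "docked_fraction": p.docked_fraction,
    }
    return sections, truth


def gen_mini_train(
    rate: float,
    amp_mean: float = 20.0,
    amp_cv: float = 0.3,
    duration: float = 60.0,
    seed: int = 0,
) -> MiniEventSeries:
    """Homogeneous Poisson mini events with lognormal amplitudes."""
    if rate < 0 or duration <= 0:
        raise ValueError("rate must be >= 0 and duration > 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.unique(rng.uniform(0.0, duration, n))
    amps = _lognormal(rng, amp_mean, amp_cv, times.size)
    return MiniEventSeries(times, amps, duration)


def gen_mini_trace(
    events: MiniEventSeries,
    sampling_rate: float = 1000.0,
    noise_sd: float = 1.0,
    baseline: float = 0.0,
    decay_tau: float = 0.005,
    polarity: str = "negative",
    seed: int = 0,
) -> CurrentTrace:
    """Render a mini event series into a noisy current trace.

    Each event contributes an instant-rise exponential-decay transient
    whose peak equals the event amplitude; Gaussian noise is added.
    """
    rng = np.random.default_rng(seed)
    n = int(round(events.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    x = np.full(n, baseline, dtype=float)
    kernel_len = int(round(8 * decay_tau * sampling_rate)) + 1
    kernel = np.exp(-np.arange(kernel_len) / (decay_tau * sampling_rate))
    sign = -1.0 if polarity == "negative" else 1.0
    for et, a in zip(events.event_times, events.amplitudes):
        i0 = int(round(et * sampling_rate))
        if i0 >= n:
            continue
        k = kernel[: n - i0]
        x[i0 : i0 + k.size] += sign * a * k
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return CurrentTrace(times=t, current=x, sampling_rate=sampling_rate)


def gen_evoked_train(
    first_amp: float = 2000.0,
    retention: float = 0.8,
    n_pulses: int = 5,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> EvokedTrain:
    """Geometrically depressing evoked train: amp_i = A·r^(i−1)·noise.

    Noise is multiplicative lognormal with unit mean, so normalized
    amplitudes are unbiased for the geometric decay.
    """
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    amps = first_amp * retention ** np.arange(n_pulses, dtype=float)
    if noise_cv > 0:
        amps = amps * _lognormal(rng, 1.0, noise_cv, n_pulses)
    return EvokedTrain(amps)


def gen_paralysis_assay(
    times: np.ndarray | None = None,
    n_plates: int = 3,
    n_per_plate: int = 25,
    paralysis_t50: float = 60.0,
    paralysis_spread: float = 20.0,
    condition: str = "wild_type",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an aldicarb paralysis time course, counted per plate.

    Each animal draws a paralysis time from a normal distribution
    (``t50`` minutes, SD ``spread``); at each observation time the
    number still moving is counted on each plate of ``n_per_plate``
    animals.  Returns the long-format assay table
    (``condition, plate, time_min, n_moving, n_total``).
    """
    if times is None:
        times = np.arange(0.0, 121.0, 15.0)
    rng = np.random.default_rng(seed)
    rows = []
    for plate in range(n_plates):
        t_par = rng.normal(paralysis_t50, paralysis_spread, n_per_plate)
        for t in times:
            rows.append(
                {
                    "condition": condition,
                    "plate": plate,
                    "time_min": float(t),
                    "n_moving": int(np.sum(t_par > t)),
                    "n_total": n_per_plate,
                }
            )
    return pd.DataFrame(rows)
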