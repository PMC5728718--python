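# Methods

This note records the models and procedures synaptoquant implements,
the parameter defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical decisions taken
where the underlying protocol leaves room.

## Line-scan enrichment

A line-scan profile is a uniformly sampled 1D trace F(x) (μm, AU).
Extraction from a 2D image samples the image by bilinear interpolation
at equal arc-length steps along a user polyline, averaging across a
perpendicular band of ±`half_width` pixels; the band statistic is the
mean (the standard segmented-line behavior), not the max.

**Extrema.** A sample is a peak (trough) candidate iff it is ≥ (≤)
every other sample within ±window/2 of its position; the default window
is 2 μm. Three cleanup rules make the statistic well defined on
arbitrary traces:

* plateau ties resolve to the leftmost sample of an equal-value run
  (determinism);
* samples that are simultaneously window-maximum and window-minimum
  (zero local contrast, e.g. a flat trace) are no extremum at all;
* candidates within window/2 of either trace end are discarded —
  incomplete windows are not comparable.

Candidates are then forced to strictly alternate: between two
consecutive peaks the minimal intervening sample becomes the trough if
it is strictly below both (symmetrically for troughs); otherwise the
less extreme candidate is dropped (leftmost wins ties). Any residual
adjacent peak/trough pair with equal values is removed. The
implementation (vectorized min/max filters) is checked against an
exhaustive O(n·w) brute-force oracle.

**Enrichment.** ΔF/F% = 100·(mean peak − mean trough)/mean trough,
pooling all peaks and all troughs. An alternative convention pairs each
peak with its flanking troughs; pooling is the default because the
statistic's inputs are simply "all peak values and trough values". A
trace with no peaks is scored 0% and classified *indeterminate*. A
non-positive mean trough is rejected as a non-physical baseline.
ΔF/F is invariant under multiplicative rescaling of the trace and is
diluted by additive offsets, which is the reason it is preferred over
raw peak intensity for clustering phenotypes.

**Classification and cutoff.** Punctate iff ΔF/F ≥ cutoff. Visual
scoring protocols do not state a numeric criterion, so the default
cutoff (287.2%) was calibrated once as the midpoint between the mean
enrichment of the punctate (diffuse_fraction 0) and diffuse
(diffuse_fraction 0.9) generator populations at their default
conditions (`scripts/calibrate_cutoff.py`); the two distributions do
not overlap there (punctate ≥ 303%, diffuse ≤ 88% over 200 seeds
each). The cutoff is a config value and should be recalibrated for
other reporters.

**Puncta.** Peaks whose value strictly exceeds a threshold; default
threshold mean + 2·SD of the trace (robust across reporters with
different brightness); absolute AU thresholds are accepted. A relative
threshold on a zero-variance trace is an error. Puncta counts are
non-increasing in threshold, and puncta closer than the window merge —
both properties are tested.

**Intensity per length** is the trapezoidal integral of F over x
divided by the x-span, in AU/μm.

## EM morphometry

Inputs are per-section annotation tables, not micrographs; vesicle and
DP annotation is assumed done (blinded, by hand, or by any upstream
tool). Sections are 0-based and 40 nm thick by default.

* **Delimitation.** A synapse = maximal run of DP-containing sections
  plus one DP-free flanking section per side (config `flank`, default
  1 — "two flanking sections … from either side" is read as one per
  side, two total, consistent with the terminal-area definition). DP
  runs separated by fewer than 2 empty sections merge, because a
  boundary requires the flanking empties to exist. `dp_span` runs from
  the first to the last DP section; for merged runs it may contain gap
  sections, which never count toward DP length.
* **Terminal area** = arithmetic mean of the cross-sectional area over
  all sections of the synapse (DP sections plus flanks), nm².
* **DP length** = number of sections in which the DP is observed
  (and × thickness for nm).
* **Docking.** Docked iff the vesicle's outer edge contacts the plasma
  membrane (membrane_distance ≤ tolerance, default 0 nm). A vesicle
  1–4 nm from the membrane with a visible tether is *undocked*
  regardless of tolerance — tethered and docked pools are
  morphologically distinct states. Distances are annotation-level; when
  computed from geometry, the outer edge is center distance minus
  radius, floored at 0.
* **Density** = total vesicles across the synapse's sections divided by
  the mean terminal area in μm².
* **DP proximity.** Docked vesicles within `radius` (default 100 nm) of
  the DP, by straight-line in-plane distance from the vesicle's outer
  edge to the nearest DP boundary point, summed over DP sections. An
  along-membrane geodesic is a plausible alternative metric; the
  straight-line choice is recorded in config by being the only
  implemented default, and annotation-level distances make the package
  agnostic to how they were measured.
* **Undocked-on-DP** = per DP section, undocked vesicles whose outer
  edge touches the DP.

Docked + undocked partition every section's vesicles; density equals
count/area by construction; both are asserted on every generated
synapse.

## Electrophysiology

Currents are body-wall-muscle voltage-clamp recordings (−60 mV holding,
1 kHz digitization); synaptic events are inward and analyzed as
positive magnitudes (config `polarity`).

**Mini detection.** Baseline = centered running median (0.5 s window),
deviation = rectified baseline-subtracted trace. The noise scale is the
Gaussian-consistent robust SD, 1.4826 × MAD, estimated on a boxcar-
smoothed (3 ms) copy of the deviation; an event requires the smoothed
deviation to exceed `k_mad` × scale (default 3.5) for at least 3 ms.
The width requirement is what separates synaptic transients (which at
τ ≈ 5 ms decay stay suprathreshold for ≥10 ms) from single-sample noise
excursions; without it a 3.5 σ threshold at 1 kHz fires on noise many
times per minute. Amplitude is the peak of the *unsmoothed* deviation
within the suprathreshold run, so smoothing does not attenuate it.
Onsets closer than the refractory interval (5 ms) merge. The detector
is validated purely by parameter recovery on synthetic traces
(sensitivity ≥ 95%, false positives < 5% at 20 pA events over 1 pA
noise); absolute event counts on real recordings depend on detector
settings and are not a comparable quantity across implementations.

**Mini statistics.** Frequency = count/duration; amplitude = arithmetic
mean, NaN-flagged when no events.

**Trains.** Amplitudes are normalized to the first pulse (first element
exactly 1; first amplitude must be positive). Depression index = last
normalized amplitude; for geometric per-pulse retention r and 5 pulses
it equals r⁴ (0.4096 at r = 0.8). When measuring trains from raw
traces, the amplitude is the peak deviation within 25 ms after each
stimulus (half the 50 ms interpulse interval), baseline re-anchored to
the sample preceding the pulse.

## Synthetic generators

The generators define the study conditions under which the pipeline is
validated; their defaults are fixed and are not tuned per test.

* **Line scans** (40 μm, 0.1 μm/px): puncta by a Poisson process
  (0.5/μm), Gaussian profiles (σ 0.3 μm), lognormal amplitudes (mean
  8 AU, CV 0.3) on background 2 AU, Gaussian noise SD 0.5 AU. The
  diffuse phenotype redistributes a fraction of every punctum's mass
  uniformly along the trace — mass is conserved, matching the
  observation that weakened puncta coincide with increased
  extrasynaptic signal rather than reporter loss. Puncta are placed
  ≥4σ from the trace ends so the noiseless integral equals
  background×length + total punctum mass to quadrature accuracy
  (asserted within 1%). Not emulated: optics PSF, photobleaching,
  camera shot noise, neurite curvature.
* **EM synapses**: 9 sections, one central DP run (3 profiles),
  terminal areas ~N(0.25 μm², 0.05 μm²) clipped positive, per-section
  vesicle counts Poisson(30), docked fraction 0.10 (membrane distance
  0), tethered fraction 0.10 (uniform 1–4 nm with tether), remainder
  uniform 5–300 nm; DP distances exponential (scale 150 nm), snapped to
  contact below 5 nm — annotation resolution; exponential draws are
  never exactly 0. Not emulated: section loss/folds, anisotropic
  shrinkage, 3D vesicle positions across sections.
* **Minis**: homogeneous Poisson times, lognormal amplitudes
  parameterized by mean and CV (positivity); trace rendering uses an
  instant-rise, exponential-decay (τ 5 ms) transient at 1 kHz with
  white Gaussian noise. Real minis have finite rise times and
  correlated noise; at 1 kHz the rise is sub-sample, so this is not a
  loss of realism for the detector's validation regime.
* **Evoked trains**: amp_i = A·r^(i−1) with multiplicative unit-mean
  lognormal noise, so normalized amplitudes are unbiased for the
  geometric profile.
* **Paralysis assays**: per-animal paralysis times ~N(t50, spread)
  counted on plates of 25; used to exercise the time-course
  aggregation, not to model aldicarb pharmacology.

Every generator takes an integer seed and is bit-reproducible under it.
Passing recovery tests on these generators demonstrates that the
quantification rules are implemented correctly, not that they are
robust to every artifact of real data.

## Statistics

Penetrance uses the Wilson score interval (well-behaved at 0% and
100%). Aldicarb time courses average the fraction moving across plates
(the plate is the independent replication unit; animals within a plate
share exposure), with SEM across plates. Group comparisons delegate to
standard implementations: Student's t-test (equal variances, matching
the stated protocol), one-way ANOVA with Tukey HSD, or two-way ANOVA
(type II, OLS) with Tukey on cell means; significance bands are
* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001. The two-group path's
type-I error is verified by simulation to sit at the nominal 5% (2,000
null datasets, n = 20/group).

## Problem sizes and numerical choices

Oracle-equivalence checks run on 100 random 500-sample traces and
1,000 random section series; parameter-recovery checks use 200
generator seeds (EM, mini rates) and 10 one-minute traces for the
event detector — sizes at which binomial/LLN error bands are a few
percent, matching the stated tolerances. Floating-point position
comparisons use a 1e-9 relative tolerance; uniform-sampling validation
likewise. Window half-widths convert to samples by floor(half/px + ε)
so that an exact half-window distance counts as inside. The running
median uses a centered window with partial windows at the trace ends.

## Known limitations

* The extrema statistic is sensitive to the window relative to punctum
  spacing: puncta closer than ~window/2 merge into one peak (visible in
  the README example); this mirrors the behavior of any plot-profile
  peak counter and is a property of the statistic, not a bug.
* The enrichment cutoff is calibrated to the synthetic conditions;
  different reporters/neurons need recalibration.
* The mini detector is validated in a high-SNR regime (20 pA / 1 pA);
  near-threshold amplitudes will trade sensitivity against false
  positives in the usual way.
* Two-way ANOVA assumes a balanced-ish design; severely unbalanced
  tables should be interpreted with care (type II sums of squares).
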