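# synaptoquant

Quantification of presynaptic phenotypes in *C. elegans* neurons, built
for studies that score synaptic-vesicle and active-zone protein
distribution by fluorescence line scans, reconstruct synapses from
serial-section electron microscopy, and measure transmission at the
neuromuscular junction by voltage clamp. The package implements the
quantification rules of that workflow as a tested pipeline, together
with synthetic-data generators so that every stage can be exercised and
validated without any microscope, EM, or rig data.

## What it computes

**Synaptic enrichment (% ΔF/F).** Along a neurite intensity profile
F(x), a sliding window (2 μm default) identifies every local peak value
F_peak and trough value F_trough. Enrichment is

    ΔF/F (%) = 100 · (⟨F_peak⟩ − ⟨F_trough⟩) / ⟨F_trough⟩

High ΔF/F means the reporter is concentrated in puncta (a punctate,
clustered distribution); low ΔF/F means it has spread along the
neurite (diffuse). Animals are classified punctate/diffuse at a
configurable cutoff, and penetrance per genotype is the fraction of
diffuse animals with a Wilson 95% interval. Puncta are peaks above a
threshold (absolute, or mean + k·SD); total intensity per neurite
length is the trapezoidal integral divided by the span.

**EM morphometry.** Input is per-section annotations of 40 nm serial
sections. A synapse is a maximal run of dense-projection (DP)
sections plus one DP-free flanking section per side; DP runs separated
by a single empty section merge. Per synapse: mean terminal
cross-sectional area, DP length in profiles (and nm), vesicle count and
density (vesicles/μm²), docked vesicles (outer edge contacting the
plasma membrane — vesicles held 1–4 nm off the membrane by a visible
tether are explicitly *not* docked), docked vesicles within 100 nm of
the DP, and undocked vesicles contacting the DP per profile.

**Electrophysiology.** Miniature postsynaptic currents are detected by
a robust threshold detector (running-median baseline, 3.5 × robust SD)
and summarized as frequency (Hz) and mean amplitude (pA). Evoked
five-pulse 20 Hz trains are normalized to the first pulse; the
depression index is the last normalized amplitude
(aₙ/a₁; retention r per pulse gives r⁴ for five pulses).

**Statistics.** Student's t-test, one-way ANOVA, or two-way ANOVA with
Tukey's post-hoc test; SEM error bars; aldicarb paralysis time courses
as fraction moving per time point averaged across plates.

## Worked example

```python
from synaptoquant import (
    count_puncta, find_extrema, intensity_per_length, penetrance,
    synaptic_enrichment,
)
from synaptoquant.synthetic import LineScanParams, gen_linescan

profile, truth = gen_linescan(LineScanParams(seed=1))  # 40 um punctate trace
enrichment = synaptic_enrichment(find_extrema(profile))
print(f"dF/F = {enrichment.delta_f_over_f_percent:.1f}%  ->  {enrichment.classification}")
print(f"puncta above 5 AU: {count_puncta(profile, 5.0).count} "
      f"(generator placed {truth['punctum_positions'].size})")
print(f"intensity per um: {intensity_per_length(profile):.2f} AU/um")
```

prints

```
dF/F = 584.7%  ->  punctate
puncta above 5 AU: 10 (generator placed 17)
intensity per um: 4.50 AU/um
```

The trace is strongly punctate (ΔF/F ≈ 585%, far above the 287% default
cutoff). Ten of the seventeen generated puncta survive the 5 AU
threshold as distinct peaks: puncta that land closer together than the
2 μm window merge into a single peak, and dim ones fall below
threshold — the same behavior a peak counter shows on real images.
The same generators drive the other stages, e.g. a fully diffuse cohort
scores 100% penetrance (Wilson CI [0.886, 1.000], n = 30).

The CLI mirrors the library:

```bash
synaptoquant simulate linescan --seed 7 --n 10 --out traces/
synaptoquant linescan --traces traces/ --out metrics.csv
synaptoquant em --annotations annotations.csv --radius-nm 100 --out em_metrics.csv
synaptoquant ephys --mode train --in train.csv --out train_metrics.csv
```

## Scope

Inputs are traces, annotation tables, and event/train lists — the
package does not segment raw micrographs, detect vesicles in EM images,
or fit event kinetics; see `docs/methods.md` for the model, parameter
defaults, and limitations.
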