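"""Line-scan profile extraction, extrema detection, and enrichment metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptoquant.linescan import (
    LineScanProfile,
    classify_distribution,
    count_puncta,
    extract_profile,
    find_extrema,
    intensity_per_length,
    synaptic_enrichment,
)

from .conftest import gaussian_trace
from .oracles import brute_extrema


def make_profile(values, pixel=0.1):
    v = np.asarray(values, float)
    return LineScanProfile(np.arange(v.size) * pixel, v, pixel)


class TestProfileInvariants:
    def test_rejects_nonuniform_sampling(self):
        with pytest.raises(ValueError, match="uniform"):
            LineScanProfile(np.array([0.0, 0.1, 0.3]), np.ones(3), 0.1)

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_profile([1.0, -0.5, 2.0])

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            make_profile([1.0, np.nan, 2.0])


class TestExtractProfile:
    def test_constant_image(self):
        img = np.full((40, 60), 7.0)
        prof = extract_profile(img, [(5, 20), (50, 20)], half_width=2, step=0.2,
                               pixel_size=0.1)
        assert np.allclose(prof.intensities, 7.0)
        assert prof.pixel_size == 0.2

    def test_iso_line_of_vertical_gradient(self):
        img = np.arange(40, dtype=float)[:, None] * np.ones((1, 60))
        prof = extract_profile(img, [(5, 10), (50, 10)], half_width=0, step=0.1,
                               pixel_size=0.1)
        assert np.allclose(prof.intensities, 10.0)

    def test_gaussian_spot_maximum(self):
        rows, cols = np.mgrid[0:80, 0:80]
        amp, bg, sigma = 50.0, 5.0, 4.0
        img = bg + amp * np.exp(-((rows - 40.0) ** 2 + (cols - 40.0) ** 2) / (2 * sigma**2))
        prof = extract_profile(img, [(10, 40), (70, 40)], half_width=0, step=0.1,
                               pixel_size=0.1)
        imax = int(np.argmax(prof.intensities))
        # center lies 30 px = 3.0 um along the line
        assert prof.positions[imax] == pytest.approx(3.0, abs=prof.pixel_size)
        assert prof.intensities[imax] == pytest.approx(bg + amp, rel=0.01)

    def test_vertex_outside_image_names_offender(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="vertex 1"):
            extract_profile(img, [(2, 2), (20, 2)], half_width=0, step=0.1, pixel_size=0.1)

    def test_zero_length_polyline(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="zero length"):
            extract_profile(img, [(2, 2), (2, 2)], half_width=0, step=0.1, pixel_size=0.1)


class TestFindExtrema:
    def test_flat_trace_has_no_extrema(self):
        ext = find_extrema(make_profile(np.full(200, 5.0)))
        assert ext.n_peaks == 0 and ext.n_troughs == 0

    def test_single_bump_one_peak(self):
        prof = gaussian_trace(centers=[5.0], amplitude=10.0, background=2.0,
                              sigma=0.3, length=10.0, pixel=0.1)
        ext = find_extrema(prof, window=2.0)
        assert ext.n_peaks == 1
        assert ext.peak_positions[0] == pytest.approx(5.0, abs=0.05)
        assert ext.peak_values[0] == pytest.approx(12.0, rel=1e-6)

    def test_window_too_narrow_errors(self):
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            find_extrema(make_profile(np.arange(50.0)), window=0.05)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(10.0, 2.0, 300).clip(min=0)
        prof = make_profile(x)
        ext = find_extrema(prof, window=2.0)
        pk, tr = brute_extrema(prof.positions, x, window=2.0)
        assert np.array_equal(ext.peak_positions, prof.positions[pk])
        assert np.array_equal(ext.trough_positions, prof.positions[tr])

    def test_alternation_and_dominance_invariants(self, rng):
        x = rng.normal(10.0, 3.0, 500).clip(min=0)
        ext = find_extrema(make_profile(x), window=2.0)
        merged = sorted(
            [(p, "P", v) for p, v in zip(ext.peak_positions, ext.peak_values)]
            + [(p, "T", v) for p, v in zip(ext.trough_positions, ext.trough_values)]
        )
        for (_pa, ta, va), (_pb, tb, vb) in zip(merged, merged[1:]):
            assert ta != tb
            hi, lo = (va, vb) if ta == "P" else (vb, va)
            assert hi > lo
        half = ext.window / 2
        pos0, pos1 = 0.0, (len(x) - 1) * 0.1
        for p in np.r_[ext.peak_positions, ext.trough_positions]:
            assert pos0 + half - 1e-9 <= p <= pos1 - half + 1e-9


class TestEnrichment:
    def test_noiseless_punctate_trace_300pct(self, punctate_trace):
        enr = synaptic_enrichment(find_extrema(punctate_trace), cutoff_percent=50.0)
        assert enr.delta_f_over_f_percent == pytest.approx(300.0, rel=0.01)
        assert enr.classification == "punctate"

    def test_empty_extrema_indeterminate(self):
        enr = synaptic_enrichment(find_extrema(make_profile(np.full(100, 5.0))))
        assert enr.delta_f_over_f_percent == 0.0
        assert enr.classification == "indeterminate"

    @given(
        c=st.floats(0.1, 50.0),
        b=st.floats(0.1, 20.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance_and_offset_dilution(self, c, b):
        base = gaussian_trace(centers=[3, 6.5, 10, 13.5, 17])
        scaled = LineScanProfile(base.positions, base.intensities * c, base.pixel_size)
        shifted = LineScanProfile(base.positions, base.intensities + b, base.pixel_size)
        d0 = synaptic_enrichment(find_extrema(base)).delta_f_over_f_percent
        dc = synaptic_enrichment(find_extrema(scaled)).delta_f_over_f_percent
        db = synaptic_enrichment(find_extrema(shifted)).delta_f_over_f_percent
        assert dc == pytest.approx(d0, rel=1e-9)
        assert db < d0

    def test_amplitude_monotonicity_noiseless(self):
        prev = -1.0
        for amp in (1.0, 3.0, 6.0, 12.0):
            prof = gaussian_trace(centers=[3, 6.5, 10, 13.5, 17], amplitude=amp)
            d = synaptic_enrichment(find_extrema(prof)).delta_f_over_f_percent
            assert d >= prev
            prev = d


class TestClassify:
    def test_cutoff_calls(self):
        from synaptoquant.linescan import EnrichmentResult

        high = EnrichmentResult(300.0, 5, 4, "punctate")
        low = EnrichmentResult(0.0, 5, 4, "diffuse")
        assert classify_distribution(high, 50.0) == "punctate"
        assert classify_distribution(low, 50.0) == "diffuse"

    def test_cutoff_must_be_positive(self):
        from synaptoquant.linescan import EnrichmentResult

        with pytest.raises(ValueError):
            classify_distribution(EnrichmentResult(10.0, 1, 1, "punctate"), 0.0)


class TestCountPuncta:
    def test_five_bumps_absolute_threshold(self):
        prof = gaussian_trace(centers=[3, 6.5, 10, 13.5, 17], amplitude=10.0,
                              background=1.0)
        assert count_puncta(prof, 5.0).count == 5
        assert count_puncta(prof, 20.0).count == 0

    def test_flat_trace_has_no_puncta(self):
        prof = make_profile(np.full(300, 5.0))
        assert count_puncta(prof, 4.5).count == 0

    def test_relative_threshold_on_zero_variance_errors(self):
        prof = make_profile(np.full(300, 5.0))
        with pytest.raises(ValueError, match="zero-variance"):
            count_puncta(prof, "mean+2sd")

    def test_count_non_increasing_in_threshold(self, rng):
        x = rng.normal(10, 3, 400).clip(min=0)
        prof = make_profile(x)
        counts = [count_puncta(prof, thr).count for thr in np.linspace(5, 25, 9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestIntensityPerLength:
    def test_constant_and_ramp(self):
        assert intensity_per_length(make_profile(np.full(101, 7.0))) == pytest.approx(7.0)
        ramp = make_profile(np.linspace(0, 10, 101))
        assert intensity_per_length(ramp) == pytest.approx(5.0)

    def test_gaussian_bump_closed_form(self):
        amp, sigma = 10.0, 0.3
        prof = gaussian_trace(centers=[5.0], amplitude=amp, background=0.0,
                              sigma=sigma, length=10.0)
        expected = amp * sigma * np.sqrt(2 * np.pi) / 10.0
        assert intensity_per_length(prof) == pytest.approx(expected, rel=0.01)

    def test_resampling_invariance(self):
        coarse = gaussian_trace(centers=[5.0], length=10.0, pixel=0.1)
        fine = gaussian_trace(centers=[5.0], length=10.0, pixel=0.05)
        a, b = intensity_per_length(coarse), intensity_per_length(fine)
        assert a == pytest.approx(b, rel=0.01)
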