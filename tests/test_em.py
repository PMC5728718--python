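"""Serial-section synapse delimitation, docking rules, and morphometrics."""

import math

import numpy as np
import pytest

from synaptoquant.em import (
    SectionAnnotation,
    VesicleRecord,
    classify_docked,
    compute_metrics,
    delimit_synapses,
    docked_near_dp,
    dp_length,
    terminal_area_mean,
    undocked_touching_dp,
    vesicle_density,
)
from synaptoquant.synthetic import EMSynapseParams, gen_em_synapse

from .oracles import brute_delimit


def sections_from_flags(flags, area=1000.0):
    return [SectionAnnotation(index=i, has_dp=bool(f), terminal_area=area)
            for i, f in enumerate(flags)]


def vesicle(membrane_distance, tethered=False, dp_contact=False, dp_distance=math.nan):
    return VesicleRecord(center=(0.0, 0.0), membrane_distance=membrane_distance,
                         tethered=tethered, dp_contact=dp_contact, dp_distance=dp_distance)


class TestDelimit:
    def test_single_run_with_flanks(self):
        syns = delimit_synapses(sections_from_flags([0, 0, 1, 1, 0, 0]))
        assert len(syns) == 1
        assert syns[0].dp_span == (2, 4)
        assert [s.index for s in syns[0].sections] == [1, 2, 3, 4]

    def test_no_dense_projections(self):
        assert delimit_synapses(sections_from_flags([0, 0, 0, 0])) == []

    def test_single_gap_merges(self):
        syns = delimit_synapses(sections_from_flags([1, 0, 1]))
        assert len(syns) == 1
        assert syns[0].dp_span == (0, 3)
        assert [s.index for s in syns[0].sections] == [0, 1, 2]

    def test_two_gap_splits(self):
        syns = delimit_synapses(sections_from_flags([1, 0, 0, 1]))
        assert len(syns) == 2
        # flanks are disjoint
        assert [s.index for s in syns[0].sections] == [0, 1]
        assert [s.index for s in syns[1].sections] == [2, 3]

    def test_nonconsecutive_indices_error(self):
        secs = sections_from_flags([1, 1])
        secs[1].index = 5
        with pytest.raises(ValueError, match="gap between 0 and 5"):
            delimit_synapses(secs)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_run_gap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        flags = rng.random(rng.integers(1, 50)) < 0.4
        syns = delimit_synapses(sections_from_flags(flags))
        expected = brute_delimit(list(flags))
        assert len(syns) == len(expected)
        for syn, (lo, hi, dp_lo, dp_hi) in zip(syns, expected):
            assert [s.index for s in syn.sections] == list(range(lo, hi))
            assert syn.dp_span == (dp_lo, dp_hi)


class TestAreasAndLength:
    def test_terminal_area_mean(self):
        secs = sections_from_flags([0, 1, 0])
        for s, a in zip(secs, (100.0, 200.0, 300.0)):
            s.terminal_area = a
        syn = delimit_synapses(secs)[0]
        assert terminal_area_mean(syn) == pytest.approx(200.0)

    def test_dp_length_counts_profiles(self):
        syn = delimit_synapses(sections_from_flags([0, 1, 1, 1, 0]))[0]
        assert dp_length(syn) == (3, 120.0)
        single = delimit_synapses(sections_from_flags([0, 1, 0]))[0]
        assert dp_length(single) == (1, 40.0)

    def test_dp_length_excludes_merged_gap(self):
        syn = delimit_synapses(sections_from_flags([1, 0, 1]))[0]
        assert dp_length(syn) == (2, 80.0)


class TestDockingRule:
    def test_membrane_contact_is_docked(self):
        assert classify_docked(vesicle(0.0)) == "docked"

    def test_tethered_within_band_not_docked(self):
        assert classify_docked(vesicle(2.0, tethered=True)) == "undocked"

    def test_far_vesicle_undocked(self):
        assert classify_docked(vesicle(50.0)) == "undocked"

    def test_untethered_near_vesicle_needs_contact(self):
        # 2 nm off the membrane without a tether is still not contact
        assert classify_docked(vesicle(2.0, tethered=False)) == "undocked"
        assert classify_docked(vesicle(2.0, tethered=False), contact_tolerance=3.0) == "docked"

    def test_tether_rule_overrides_tolerance(self):
        assert classify_docked(vesicle(2.0, tethered=True), contact_tolerance=3.0) == "undocked"


class TestDensityAndDP:
    def _synapse(self, vesicles_per_section, area=500_000.0, flags=(0, 1, 0)):
        secs = sections_from_flags(list(flags), area=area)
        for s, vs in zip(secs, vesicles_per_section):
            s.vesicles = vs
        return delimit_synapses(secs)[0]

    def test_density_division(self):
        vs = [vesicle(50.0) for _ in range(50)]
        syn = self._synapse([[], vs, []], area=500_000.0)  # 0.5 um^2
        assert vesicle_density(syn) == pytest.approx(100.0)

    def test_density_zero_vesicles(self):
        syn = self._synapse([[], [], []])
        assert vesicle_density(syn) == 0.0

    def test_density_scales_inversely_with_area(self):
        vs = [vesicle(50.0) for _ in range(40)]
        d1 = vesicle_density(self._synapse([[], vs, []], area=250_000.0))
        d4 = vesicle_density(self._synapse([[], vs, []], area=1_000_000.0))
        assert d1 == pytest.approx(4 * d4)

    def test_docked_near_dp_radius_filter(self):
        vs = [vesicle(0.0, dp_distance=d) for d in (10.0, 60.0, 150.0)]
        syn = self._synapse([[], vs, []])
        assert docked_near_dp(syn, radius=100.0) == 2
        assert docked_near_dp(syn, radius=5.0) == 0
        counts = [docked_near_dp(syn, radius=r) for r in (5, 50, 100, 200)]
        assert counts == sorted(counts)

    def test_docked_missing_dp_distance_errors(self):
        syn = self._synapse([[], [vesicle(0.0)], []])
        with pytest.raises(ValueError, match="dp_distance"):
            docked_near_dp(syn)

    def test_undocked_touching_dp(self):
        vs = [vesicle(50.0, dp_contact=True) for _ in range(3)]
        vs += [vesicle(50.0, dp_contact=False) for _ in range(5)]
        syn = self._synapse([[], vs, []])
        assert undocked_touching_dp(syn) == ([3], 3)

    def test_docked_vesicle_excluded_from_dp_touch_count(self):
        vs = [vesicle(0.0, dp_contact=True, dp_distance=0.0)]
        syn = self._synapse([[], vs, []])
        assert undocked_touching_dp(syn) == ([0], 0)

    def test_dp_section_without_vesicles(self):
        syn = delimit_synapses(sections_from_flags([0, 1, 0]))[0]
        assert undocked_touching_dp(syn) == ([0], 0)


class TestGeneratedSynapses:
    def test_partition_docked_plus_undocked(self):
        sections, truth = gen_em_synapse(EMSynapseParams(seed=7))
        syn = delimit_synapses(sections)[0]
        m = compute_metrics(syn)
        docked = undocked = 0
        for s in syn.sections:
            for v in s.vesicles:
                if classify_docked(v) == "docked":
                    docked += 1
                else:
                    undocked += 1
        assert docked + undocked == m.total_vesicles
        included = [s.index for s in syn.sections]
        assert m.docked_vesicles == docked == sum(
            truth["docked_per_section"][i] for i in included
        )

    def test_density_consistency_invariant(self):
        for seed in range(20):
            sections, _ = gen_em_synapse(EMSynapseParams(seed=seed))
            syn = delimit_synapses(sections)[0]
            m = compute_metrics(syn)
            expected = m.total_vesicles / (m.terminal_area_mean / 1e6)
            assert m.vesicle_density == pytest.approx(expected, rel=1e-9)

    def test_dp_length_recovery(self):
        sections, truth = gen_em_synapse(EMSynapseParams(dp_run_length=3, seed=3))
        syn = delimit_synapses(sections)[0]
        assert dp_length(syn) == (3, 120.0)
        assert syn.dp_span == truth["dp_span"]
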