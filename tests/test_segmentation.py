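"""State calling, run merging, size/marker/density filters and recovery."""

import numpy as np
import pytest

from ycnv.probe_map import ProbeManifest
from ycnv.segmentation import (
    SegmentationParams,
    call_states,
    density_filter,
    moving_average,
    segment,
)
from ycnv.synthetic import CNVEvent, IntensityModel, simulate_sample
from ycnv.evaluate import event_probe_range


def make_manifest(n, spacing=1000, start=10_000):
    pos = start + spacing * np.arange(n)
    return ProbeManifest(
        probe_ids=np.array([f"p{i}" for i in range(n)], dtype=object),
        positions=pos,
        probe_classes=np.array(["CN"] * n, dtype=object),
    )


class TestCallStates:
    @pytest.mark.parametrize(
        "value,expected",
        [(-0.47, 0), (0.04, 1), (-2.02, -1), (-1.245, 0), (-0.215, 0)],
    )
    def test_threshold_contract_with_ties_normal(self, value, expected):
        states = call_states(np.full(20, value), SegmentationParams())
        assert (states == expected).all()

    def test_unsmoothed_equals_direct_thresholding(self, rng):
        params = SegmentationParams(smooth_window=1)
        profile = rng.normal(-0.47, 0.6, size=500)
        states = call_states(profile, params)
        assert ((profile < params.loss_threshold) == (states == -1)).all()
        assert ((profile > params.gain_threshold) == (states == 1)).all()

    def test_even_smooth_window_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(smooth_window=4)


class TestMovingAverage:
    def test_constant_invariant(self):
        assert np.allclose(moving_average(np.full(10, 3.3), 5), 3.3)

    def test_matches_bruteforce_loop(self, rng):
        v = rng.normal(size=57)
        for w in (1, 3, 5, 7):
            got = moving_average(v, w)
            h = w // 2
            expected = [
                v[max(0, i - h) : min(len(v), i + h + 1)].mean()
                for i in range(len(v))
            ]
            assert np.allclose(got, expected)


class TestSegment:
    def test_21_gain_probes_over_35kb_single_segment(self):
        # mirrors a 35-kb duplication carrying 21 probes
        man = make_manifest(60, spacing=35_000 // 20)
        profile = np.full(60, -0.47)
        profile[20:41] = 0.04
        params = SegmentationParams()
        segs = segment(call_states(profile, params), man, profile, params)
        assert len(segs) == 1
        s = segs[0]
        assert s.state == "gain"
        assert (s.first_index, s.last_index) == (20, 40)
        assert s.n_markers == 21
        assert s.span == 35_001
        assert s.mean_log2 == pytest.approx(0.04)

    def test_two_gain_probes_fail_min_markers(self):
        man = make_manifest(40, spacing=3000)
        profile = np.full(40, -0.47)
        profile[10:12] = 0.04
        params = SegmentationParams()
        assert segment(call_states(profile, params), man, profile, params) == []

    def test_three_loss_probes_over_4kb_fail_min_size(self):
        man = make_manifest(40, spacing=2000)
        profile = np.full(40, -0.47)
        profile[10:13] = -2.02  # spans 4001 bp < 5 kb
        params = SegmentationParams()
        assert segment(call_states(profile, params), man, profile, params) == []

    def test_gap_tolerance_merges_single_discordant_probe(self):
        man = make_manifest(60, spacing=3000)
        profile = np.full(60, -0.47)
        profile[10:30] = -2.02
        profile[20] = -0.47  # lone discordant probe inside the run
        params = SegmentationParams(smooth_window=1, max_gap=1)
        segs = segment(call_states(profile, params), man, profile, params)
        assert len(segs) == 1
        assert (segs[0].first_index, segs[0].last_index) == (10, 29)

    def test_same_state_segments_never_adjacent_within_gap(self, rng):
        man = make_manifest(400, spacing=3000)
        profile = rng.normal(-0.47, 0.9, size=400)
        params = SegmentationParams(smooth_window=1)
        segs = segment(call_states(profile, params), man, profile, params)
        by_state = {}
        for s in segs:
            by_state.setdefault(s.state, []).append(s)
        for group in by_state.values():
            group.sort(key=lambda s: s.first_index)
            for a, b in zip(group, group[1:]):
                assert b.first_index - a.last_index - 1 > params.max_gap

    def test_monotone_in_min_markers_and_min_size(self, rng):
        man = make_manifest(500, spacing=3000)
        profile = rng.normal(-0.47, 0.8, size=500)
        prev = None
        for mm in (1, 3, 6, 10):
            params = SegmentationParams(min_markers=mm, smooth_window=1)
            n = len(segment(call_states(profile, params), man, profile, params))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for kb in (1.0, 5.0, 20.0, 60.0):
            params = SegmentationParams(min_size_kb=kb, smooth_window=1)
            n = len(segment(call_states(profile, params), man, profile, params))
            if prev is not None:
                assert n <= prev
            prev = n


class TestDensityFilter:
    def test_sparse_segment_removed(self):
        man = make_manifest(10, spacing=100_000)
        profile = np.full(10, -2.02)
        params = SegmentationParams(smooth_window=1)
        segs = segment(call_states(profile, params), man, profile, params)
        assert len(segs) == 1
        assert segs[0].density < 0.1
        assert density_filter(segs, min_density=0.1) == []

    def test_reference_scale_q_arm_deletion_retained(self):
        # 338 probes over 782 kb -> 0.43 probes/kb, far above the default
        man = make_manifest(400, spacing=782_000 // 337)
        profile = np.full(400, -0.47)
        profile[30 : 30 + 338] = -2.02
        params = SegmentationParams()
        segs = density_filter(
            segment(call_states(profile, params), man, profile, params),
            params.min_density,
        )
        assert len(segs) == 1
        assert segs[0].n_markers == 338

    def test_empty_input_empty_output(self):
        assert density_filter([], 0.05) == []


class TestNoiseFreeExactness:
    def test_zero_noise_segments_equal_implanted_events(
        self, manifest_real, seg_params
    ):
        model = IntensityModel(sigma=0.0)
        pos = manifest_real.positions
        # placed clear of the female-background hot intervals, which lift
        # zero-copy probes off the deletion mean
        events = [
            CNVEvent("deletion", int(pos[2000]), int(pos[2060])),
            CNVEvent("duplication", int(pos[900]), int(pos[1050])),
        ]
        profile = simulate_sample(manifest_real, model, "male", events, seed=0)
        segs = segment(
            call_states(profile, seg_params), manifest_real, profile, seg_params
        )
        got = sorted((s.first_index, s.last_index, s.state) for s in segs)
        want = sorted(
            event_probe_range(e, manifest_real)
            + (("loss" if e.kind == "deletion" else "gain"),)
            for e in events
        )
        assert got == want
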