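"""Trajectory linking, onset detection, normalization, phases, dwell."""

import itertools

import numpy as np
import pytest

from conftest import make_object
from decondenseq.segmentation import SegmentationConfig, extract_objects, \
    segment_livecell
from decondenseq.synthetic import TimelapseParams, make_decondensation_timelapse
from decondenseq.timecourse import (
    AmbiguousSceneError,
    AreaCurve,
    NoMitosisError,
    PhaseSequence,
    PhaseThresholds,
    aggregate_curves,
    classify_phases,
    detect_anaphase_onset,
    dwell_times,
    estimate_interphase_reference,
    fit_expansion_rate,
    link_objects,
    normalize_area_curve,
)


def segment_lapse(lapse, min_area=50):
    cfg = SegmentationConfig(to_8bit=False)
    return [
        extract_objects(segment_livecell(f, cfg), min_area, frame_index=i)
        for i, f in enumerate(lapse)
    ]


class TestLinkObjects:
    def test_static_object_full_length(self):
        frames = [[make_object(100, (10, 10), f)] for f in range(8)]
        traj = link_objects(frames)
        assert len(traj) == 8
        assert all(len(objs) == 1 for objs in traj.frames)

    def test_split_reported_at_onset(self, clean_lapse):
        lapse, truth = clean_lapse
        traj = link_objects(segment_lapse(lapse))
        onset = truth.info["onset_frame"]
        assert all(len(traj.frames[f]) == 1 for f in range(onset))
        assert all(len(traj.frames[f]) == 2 for f in range(onset, len(traj)))

    def test_assignment_matches_two_permutation_oracle(self):
        # two objects drifting; identity must minimize summed displacement
        rng = np.random.default_rng(0)
        pos = [np.array([[10.0, 10.0], [10.0, 30.0]])]
        for _ in range(9):
            pos.append(pos[-1] + rng.normal(0, 1.5, (2, 2)))
        frames = [
            [make_object(60 + i, tuple(p[i]), f) for i in range(2)]
            for f, p in enumerate(pos)
        ]
        traj = link_objects(frames)
        for f in range(1, len(traj)):
            prev = traj.frames[f - 1]
            cur = traj.frames[f]
            best = min(
                itertools.permutations(cur),
                key=lambda perm: sum(
                    np.hypot(p.centroid[0] - q.centroid[0],
                             p.centroid[1] - q.centroid[1])
                    for p, q in zip(prev, perm)
                ),
            )
            assert [o.centroid for o in cur] == [o.centroid for o in best]

    def test_too_many_objects_raise_with_areas(self):
        frames = [[make_object(a, (10, 10 * i)) for i, a in enumerate((90, 80, 70))]]
        with pytest.raises(AmbiguousSceneError, match=r"\[90, 80, 70\]"):
            link_objects(frames)


class TestOnsetDetection:
    def test_ground_truth_onset(self, clean_lapse):
        lapse, truth = clean_lapse
        traj = link_objects(segment_lapse(lapse))
        assert detect_anaphase_onset(traj) == truth.info["onset_frame"]

    def test_single_object_lapse_raises(self):
        frames = [[make_object(100, (10, 10), f)] for f in range(10)]
        with pytest.raises(NoMitosisError):
            detect_anaphase_onset(link_objects(frames))

    def test_one_frame_flicker_ignored(self):
        # spurious 2-object frame at 6, true persistent split at 10
        frames = []
        for f in range(15):
            if f == 6:
                frames.append([make_object(50, (10, 8), f),
                               make_object(50, (10, 14), f)])
            elif f < 10:
                frames.append([make_object(100, (10, 10), f)])
            else:
                frames.append([make_object(55, (10, 6), f),
                               make_object(55, (10, 16), f)])
        traj = link_objects(frames)
        assert detect_anaphase_onset(traj, persistence=2) == 10

    def test_tiny_blob_not_a_daughter(self):
        frames = []
        for f in range(12):
            if f < 5:
                frames.append([make_object(100, (10, 10), f)])
            elif f < 8:  # a noise blob far below the daughter fraction
                frames.append([make_object(100, (10, 10), f),
                               make_object(5, (30, 30), f)])
            else:
                frames.append([make_object(48, (10, 6), f),
                               make_object(48, (10, 16), f)])
        traj = link_objects(frames)
        assert detect_anaphase_onset(traj, min_daughter_frac=0.2) == 8


class TestNormalization:
    def test_arithmetic(self):
        frames = [[make_object(a, (5, 5), f)]
                  for f, a in enumerate((100, 110, 121))]
        traj = link_objects(frames, frame_interval_min=3.0)
        curve = normalize_area_curve(traj, onset=0)
        assert curve.time_min.tolist() == [0.0, 3.0, 6.0]
        assert curve.normalized_area.tolist() == [1.0, 1.10, 1.21]

    def test_unit_at_onset_exact(self, clean_lapse):
        lapse, truth = clean_lapse
        traj = link_objects(segment_lapse(lapse))
        onset = detect_anaphase_onset(traj)
        curve = normalize_area_curve(traj, onset)
        assert curve.normalized_area[curve.time_min == 0.0][0] == 1.0

    def test_zero_rate_curve_flat_within_2pct(self):
        params = TimelapseParams(expansion_rate_per_min=0.0, seed=13,
                                 noise_sd=0.0)
        lapse, _ = make_decondensation_timelapse(params)
        traj = link_objects(segment_lapse(lapse))
        onset = detect_anaphase_onset(traj)
        curve = normalize_area_curve(traj, onset)
        post = curve.normalized_area[curve.time_min >= 0]
        assert np.abs(post - 1.0).max() < 0.02

    def test_slope_recovery_noise_free(self):
        params = TimelapseParams(expansion_rate_per_min=0.05, seed=14,
                                 noise_sd=0.0, blur_sigma_px=1.0)
        lapse, _ = make_decondensation_timelapse(params)
        traj = link_objects(segment_lapse(lapse))
        curve = normalize_area_curve(traj, detect_anaphase_onset(traj))
        assert fit_expansion_rate(curve) == pytest.approx(0.05, rel=0.10)

    def test_zero_area_at_onset_raises(self):
        frames = [[] for _ in range(3)]
        traj = link_objects(frames)
        with pytest.raises(ValueError):
            normalize_area_curve(traj, 0)


class TestPhases:
    def test_rule_arithmetic(self):
        # onset 10, anaphase window 2 frames: 10-11 anaphase, 12+ telophase
        ref = 1000.0
        frames = []
        for f in range(16):
            if f < 10:
                frames.append([make_object(300, (10, 10), f)])
            else:
                frames.append([make_object(200, (10, 6), f),
                               make_object(200, (10, 16), f)])
        traj = link_objects(frames, frame_interval_min=3.0)
        th = PhaseThresholds(interphase_reference_area_px2=ref)
        seq = classify_phases(traj, th, onset=10)
        assert seq.labels[:10] == ["metaphase"] * 10
        assert seq.labels[10:12] == ["anaphase"] * 2
        assert seq.labels[12:] == ["telophase"] * 4

    def test_all_interphase(self):
        frames = [[make_object(900, (10, 10), f)] for f in range(6)]
        traj = link_objects(frames)
        th = PhaseThresholds(interphase_reference_area_px2=1000.0)
        assert classify_phases(traj, th).labels == ["interphase"] * 6

    def test_exit_to_interphase(self):
        frames = []
        for f in range(10):
            area = 300 + 80 * f  # daughters grow past the exit fraction
            frames.append([make_object(area, (10, 6), f),
                           make_object(area, (10, 16), f)])
        traj = link_objects(frames)
        th = PhaseThresholds(interphase_reference_area_px2=1000.0)
        seq = classify_phases(traj, th, onset=0)
        # exit when a daughter reaches 0.8 * 1000 = 800 -> f >= 6.25 -> frame 7
        assert seq.labels[2:7] == ["telophase"] * 5
        assert seq.labels[7:] == ["interphase"] * 3

    def test_agreement_with_generator_truth(self):
        params = TimelapseParams(
            n_frames=20, onset_frame=5, initial_area_px2=800.0,
            expansion_rate_per_min=0.15, seed=15, noise_sd=0.0,
            blur_sigma_px=1.0, image_size_px=(224, 224),
        )
        lapse, truth = make_decondensation_timelapse(params)
        traj = link_objects(segment_lapse(lapse), params.frame_interval_min)
        onset = detect_anaphase_onset(traj)
        th = PhaseThresholds(
            interphase_reference_area_px2=truth.info[
                "interphase_reference_area_px2"
            ]
        )
        seq = classify_phases(traj, th, onset=onset)
        agree = np.mean(
            [a == b for a, b in zip(seq.labels, truth.info["phase_truth"])]
        )
        assert agree >= 0.9


class TestDwellAndAggregation:
    def test_dwell_arithmetic(self):
        labels = ["metaphase"] * 2 + ["anaphase"] * 2 + ["telophase"] * 4 + \
            ["interphase"]
        seq = PhaseSequence(labels, frame_interval_min=3.0)
        d = dwell_times(seq)
        assert d["telophase"] == 12.0
        assert d["anaphase"] == 6.0

    def test_no_telophase_zero(self):
        seq = PhaseSequence(["interphase"] * 4, frame_interval_min=3.0)
        assert dwell_times(seq).get("telophase", 0.0) == 0.0

    def test_identical_curves_zero_sem(self):
        c = AreaCurve(np.array([0.0, 3.0]), np.array([1.0, 1.2]))
        agg = aggregate_curves([c] * 5)
        assert (agg["sem"] == 0.0).all()
        assert (agg["n"] == 5).all()

    def test_two_curve_sem(self):
        c1 = AreaCurve(np.array([3.0]), np.array([1.0]))
        c2 = AreaCurve(np.array([3.0]), np.array([2.0]))
        agg = aggregate_curves([c1, c2])
        assert agg["mean"].iloc[0] == pytest.approx(1.5)
        assert agg["sem"].iloc[0] == pytest.approx(0.5)

    def test_single_curve_flagged(self):
        c = AreaCurve(np.array([0.0, 3.0]), np.array([1.0, 1.1]))
        agg = aggregate_curves([c])
        assert (agg["n"] == 1).all()
        assert (agg["sem"] == 0.0).all()
        assert agg["mean"].tolist() == [1.0, 1.1]


def test_interphase_reference_estimate():
    frames = [[make_object(a, (5, 5), f)]
              for f, a in enumerate((990, 1010, 1000, 995, 1005, 400))]
    traj = link_objects(frames)
    assert estimate_interphase_reference(traj) == 1000.0
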