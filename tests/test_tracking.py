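import numpy as np
import pytest

from alveotrack import (ChannelRole, Contour, TrackPolicy,
                        default_track_policy, features_match,
                        filter_by_temporal_consistency, link_tracks)
from alveotrack.tracking import Rejection


def _c(area, centroid, role="interstitial", frame=0):
    return Contour(polygon=((0, 0), (1, 0), (1, 1)), area=float(area),
                   centroid=centroid, role=ChannelRole(role),
                   frame_index=frame)


ALV = TrackPolicy(role=ChannelRole.INTERSTITIAL, area_tolerance_rel=0.3,
                  centroid_radius=15)
NEU = TrackPolicy(role=ChannelRole.NEUTROPHIL, area_tolerance_abs=50,
                  centroid_radius=15)


class TestFeaturesMatch:
    def test_alveolar_relative_tolerance(self):
        # |1000-1200| = 200 <= 0.3*1200 and 3 px <= 15 px
        assert features_match(_c(1000, (0, 0)), _c(1200, (3, 0)), ALV)

    def test_alveolar_relative_tolerance_exceeded(self):
        # |1000-1500| = 500 > 0.3*1500 = 450
        assert not features_match(_c(1000, (0, 0)), _c(1500, (3, 0)), ALV)

    def test_identical_contours_match(self):
        c = _c(500, (10, 10))
        assert features_match(c, c, ALV)

    def test_centroid_radius_gates_neutrophils(self):
        a = _c(100, (0, 0), role="neutrophil")
        b = _c(100, (50, 0), role="neutrophil")
        assert not features_match(a, b, NEU)

    def test_neutrophil_absolute_tolerance(self):
        a = _c(100, (0, 0), role="neutrophil")
        assert features_match(a, _c(149, (3, 0), role="neutrophil"), NEU)
        assert not features_match(a, _c(151, (3, 0), role="neutrophil"), NEU)

    def test_role_mismatch_rejected(self):
        with pytest.raises(ValueError, match="role mismatch"):
            features_match(_c(10, (0, 0)), _c(10, (0, 0), role="neutrophil"),
                           ALV)


class TestTemporalFilter:
    def test_stable_blob_kept_everywhere(self):
        frames = [[], [], [], [],
                  [_c(500, (20, 20), frame=4)],
                  [_c(510, (21, 20), frame=5)],
                  [_c(505, (22, 21), frame=6)],
                  [], [], []]
        out = filter_by_temporal_consistency(frames, ALV)
        assert [len(f) for f in out] == [0, 0, 0, 0, 1, 1, 1, 0, 0, 0]

    def test_one_frame_transient_removed(self):
        frames = [[] for _ in range(10)]
        frames[5] = [_c(500, (20, 20), frame=5)]
        rejections: list[Rejection] = []
        out = filter_by_temporal_consistency(frames, ALV, rejections)
        assert all(len(f) == 0 for f in out)
        assert len(rejections) == 1
        assert rejections[0].frame_index == 5

    def test_one_matching_neighbor_suffices(self):
        # frame 1's blob matches frame 0 but not frame 2: still kept
        frames = [[_c(500, (20, 20), frame=0)],
                  [_c(520, (21, 20), frame=1)],
                  [_c(5000, (100, 100), frame=2)]]
        out = filter_by_temporal_consistency(frames, ALV)
        assert len(out[1]) == 1

    def test_single_pass_is_idempotent(self):
        # matching is symmetric, so a removed feature can never have been
        # another feature's only validator: one pass reaches the fixed point
        rng = np.random.default_rng(11)
        frames = [
            [_c(rng.integers(100, 1000), tuple(rng.uniform(0, 60, 2)),
                frame=t) for _ in range(rng.integers(0, 4))]
            for t in range(10)
        ]
        once = filter_by_temporal_consistency(frames, ALV)
        twice = filter_by_temporal_consistency(once, ALV)
        assert once == twice

    def test_boundary_frames_check_single_neighbor(self):
        frames = [[_c(500, (20, 20), frame=0)],
                  [_c(505, (20, 20), frame=1)]]
        out = filter_by_temporal_consistency(frames, ALV)
        assert [len(f) for f in out] == [1, 1]

    def test_output_is_per_frame_subset(self):
        rng = np.random.default_rng(3)
        frames = [
            [_c(rng.integers(100, 1000), tuple(rng.uniform(0, 100, 2)),
                frame=t) for _ in range(rng.integers(0, 5))]
            for t in range(8)
        ]
        out = filter_by_temporal_consistency(frames, ALV)
        for kept, orig in zip(out, frames):
            assert all(c in orig for c in kept)
            # order preserved
            idx = [orig.index(c) for c in kept]
            assert idx == sorted(idx)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError, match=">=2 frames"):
            filter_by_temporal_consistency([[]], ALV)

    def test_default_policies(self):
        assert default_track_policy("interstitial").centroid_radius == 20
        assert default_track_policy("neutrophil").centroid_radius == 15


class TestLinkTracks:
    def test_persistent_blob_keeps_one_id(self):
        frames = [[_c(500, (20 + t, 20), frame=t)] for t in range(5)]
        ids = link_tracks(frames, ALV)
        assert {i for frame in ids for i in frame} == {0}

    def test_new_appearance_gets_new_id(self):
        frames = [[_c(500, (20, 20), frame=0)],
                  [_c(500, (21, 20), frame=1),
                   _c(480, (120, 120), frame=1)]]
        ids = link_tracks(frames, ALV)
        assert ids[0] == [0]
        assert sorted(ids[1]) == [0, 1]
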