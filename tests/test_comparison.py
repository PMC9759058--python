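import numpy as np
import pytest

from alveotrack import (apply_offset, compare_experiments,
                        cycle_difference_chart, detect_cycles,
                        distribution_summary, estimate_offset, slope_chart)
from alveotrack.features import RespiratoryCycle
from tests.conftest import make_stats, sine_stats


def _cycles(bounds):
    return [RespiratoryCycle(cycle_index=k, start_frame=a, end_frame=b,
                             min_alveolar_pct=0.0, max_alveolar_pct=1.0)
            for k, (a, b) in enumerate(bounds)]


class TestApplyOffset:
    def test_zero_offset_identity(self):
        stats = make_stats([1.0, 2.0, 3.0])
        assert apply_offset(stats, 0) == stats

    def test_positive_offset_drops_leading_frames(self):
        stats = make_stats(np.arange(10, dtype=float))
        out = apply_offset(stats, 3)
        assert len(out) == 7
        assert out[0].frame_index == 0
        assert out[0].alveolar_area_pct == 3.0

    def test_negative_offset_drops_trailing_frames(self):
        stats = make_stats(np.arange(10, dtype=float))
        out = apply_offset(stats, -4)
        assert len(out) == 6
        assert out[-1].alveolar_area_pct == 5.0

    def test_offset_at_series_length_rejected(self):
        stats = make_stats([1.0] * 5)
        with pytest.raises(ValueError):
            apply_offset(stats, 5)


class TestSlopeChart:
    def test_constant_feature(self):
        stats = make_stats([7.0] * 16)
        cycles = _cycles([(0, 8), (8, 16)])
        assert slope_chart(stats, cycles, "alveolar_area_pct") == (7.0, 7.0)

    def test_linear_ramp_closed_form(self):
        # feature = t over frames 0..15, cycles [0,8) and [8,16):
        # means are 3.5 and 11.5
        stats = make_stats(np.arange(16, dtype=float))
        cycles = _cycles([(0, 8), (8, 16)])
        start, end = slope_chart(stats, cycles, "alveolar_area_pct")
        assert (start, end) == (3.5, 11.5)

    def test_single_cycle_start_equals_end(self):
        stats = make_stats([3.0] * 8)
        start, end = slope_chart(stats, _cycles([(0, 8)]),
                                 "alveolar_area_pct")
        assert start == end

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            slope_chart(make_stats([1.0] * 8), _cycles([(0, 8)]), "bogus")


class TestDistributionSummary:
    def test_simple_sequence(self):
        s = distribution_summary(make_stats([1, 2, 3, 4, 5]),
                                 "alveolar_area_pct")
        assert s.median == 3 and s.mean == 3
        assert s.min == 1 and s.max == 5

    def test_constant(self):
        s = distribution_summary(make_stats([4.0] * 6), "alveolar_area_pct")
        assert (s.min, s.q25, s.median, s.q75, s.max, s.mean) == (4,) * 6

    def test_interpolated_quantile(self):
        # [0,0,0,10]: q75 position 0.75*3 = 2.25 -> 0 + 0.25*10 = 2.5
        s = distribution_summary(make_stats([0, 0, 0, 10]),
                                 "alveolar_area_pct")
        assert s.mean == 2.5
        assert s.q75 == 2.5
        assert s.median == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distribution_summary([], "alveolar_area_pct")


class TestCycleDifferenceChart:
    def test_identical_series_all_zero(self):
        stats = sine_stats()
        cycles = detect_cycles(stats)
        d = cycle_difference_chart(stats, cycles, stats, cycles,
                                   "alveolar_area_pct")
        assert d == [0.0] * len(cycles)

    def test_constant_difference(self):
        a = make_stats([5.0] * 32)
        b = make_stats([2.0] * 32)
        ca = _cycles([(0, 8), (8, 16), (16, 24), (24, 32)])
        d = cycle_difference_chart(a, ca, b, ca, "alveolar_area_pct")
        assert d == [3.0, 3.0, 3.0, 3.0]

    def test_length_is_min_cycle_count(self):
        a = make_stats([5.0] * 40)
        b = make_stats([2.0] * 24)
        ca = _cycles([(i * 8, (i + 1) * 8) for i in range(5)])
        cb = _cycles([(i * 8, (i + 1) * 8) for i in range(3)])
        assert len(cycle_difference_chart(a, ca, b, cb,
                                          "alveolar_area_pct")) == 3

    def test_symmetric_in_arguments(self):
        a = sine_stats(mean=10.0)
        b = sine_stats(mean=12.0, amplitude=4.0)
        ca, cb = detect_cycles(a), detect_cycles(b)
        ab = cycle_difference_chart(a, ca, b, cb, "alveolar_area_pct")
        ba = cycle_difference_chart(b, cb, a, ca, "alveolar_area_pct")
        assert ab == ba


class TestCompareExperiments:
    def test_self_comparison_identities(self):
        stats = sine_stats()
        res = compare_experiments(stats, stats, 0)
        for f, diffs in res.cycle_differences.items():
            assert all(d == 0.0 for d in diffs)
        for f, pairs in res.slope_pairs.items():
            assert pairs["A"] == pairs["B"]

    def test_zero_offset_invariance(self):
        stats = sine_stats()
        cycles = detect_cycles(stats)
        shifted = apply_offset(stats, 0)
        assert slope_chart(stats, cycles, "neutrophil_area_pct") == \
            slope_chart(shifted, detect_cycles(shifted),
                        "neutrophil_area_pct")

    def test_estimate_offset_recovers_phase_shift(self):
        a = sine_stats(n=96)
        b = sine_stats(n=96)[5:]  # b lags: dropping 5 more frames aligns
        # estimate_offset should report the shift that re-aligns b with a,
        # modulo the 16-frame period
        off = estimate_offset(a, b)
        assert (off - 11) % 16 == 0 or (off + 5) % 16 == 0
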