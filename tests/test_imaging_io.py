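import numpy as np
import pytest
import tifffile

from alveotrack import (ChannelRole, ChannelSeries, combine_channels,
                        load_channel_series, read_feature_table,
                        save_channel_series, split_composite,
                        write_feature_table)
from tests.conftest import make_stats


def _write_frames(directory, arrays, names=None):
    directory.mkdir(parents=True, exist_ok=True)
    names = names or [f"f_{i:03d}.tif" for i in range(len(arrays))]
    for name, arr in zip(names, arrays):
        tifffile.imwrite(directory / name, arr)


class TestLoadChannelSeries:
    def test_orders_and_sizes_padded_sequence(self, tmp_path):
        frames = [np.full((64, 64), i, np.uint8) for i in range(10)]
        _write_frames(tmp_path, frames)
        series = load_channel_series(tmp_path, "interstitial", "*.tif")
        assert series.n_frames == 10
        assert (series.height, series.width) == (64, 64)
        assert [int(f[0, 0]) for f in series] == list(range(10))

    def test_numeric_not_lexicographic_order(self, tmp_path):
        # f_10 sorts before f_2 lexicographically; numeric order must win
        _write_frames(tmp_path,
                      [np.full((8, 8), 2, np.uint8),
                       np.full((8, 8), 10, np.uint8)],
                      names=["f_2.tif", "f_10.tif"])
        series = load_channel_series(tmp_path, "interstitial", "*.tif")
        assert [int(f[0, 0]) for f in series] == [2, 10]

    def test_inconsistent_geometry_rejected(self, tmp_path):
        _write_frames(tmp_path, [np.zeros((64, 64), np.uint8),
                                 np.zeros((32, 32), np.uint8)])
        with pytest.raises(ValueError, match="inconsistent frame geometry"):
            load_channel_series(tmp_path, "interstitial", "*.tif")

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no frames found"):
            load_channel_series(tmp_path, "interstitial", "*.tif")

    def test_duplicate_index_rejected(self, tmp_path):
        _write_frames(tmp_path, [np.zeros((8, 8), np.uint8)] * 2,
                      names=["a_1.tif", "b_1.tif"])
        with pytest.raises(ValueError, match="ambiguous frame order"):
            load_channel_series(tmp_path, "interstitial", "*.tif")

    def test_16bit_rescaled_on_flag_else_rejected(self, tmp_path):
        arr = np.zeros((8, 8), np.uint16)
        arr[0, 0] = 65535
        arr[0, 1] = 32768
        _write_frames(tmp_path, [arr])
        with pytest.raises(ValueError, match="rescale_16bit"):
            load_channel_series(tmp_path, "interstitial", "*.tif")
        series = load_channel_series(tmp_path, "interstitial", "*.tif",
                                     rescale_16bit=True)
        assert series.frames[0, 0, 0] == 255
        assert series.frames[0, 0, 1] == 128

    def test_save_load_round_trip_identity(self, tmp_path, small_scene):
        _, inter, _, _ = small_scene
        save_channel_series(inter, tmp_path / "out", fmt="png")
        back = load_channel_series(tmp_path / "out", "interstitial", "*.png")
        np.testing.assert_array_equal(back.frames, inter.frames)


class TestCombineChannels:
    def _series(self, frames, role):
        return ChannelSeries(role=role, frames=np.asarray(frames, np.uint8))

    def test_color_assignment_and_losslessness(self):
        rng = np.random.default_rng(0)
        i = rng.integers(0, 256, (3, 16, 16)).astype(np.uint8)
        n = rng.integers(0, 256, (3, 16, 16)).astype(np.uint8)
        rgb = combine_channels(self._series(i, "interstitial"),
                               self._series(n, "neutrophil"))
        np.testing.assert_array_equal(rgb[..., 2], i)   # interstitium blue
        np.testing.assert_array_equal(rgb[..., 0], n)   # neutrophils red
        assert not rgb[..., 1].any()                    # green reserved
        back_i, back_n = split_composite(rgb)
        np.testing.assert_array_equal(back_i, i)
        np.testing.assert_array_equal(back_n, n)

    def test_single_pixel_examples(self):
        i = np.zeros((1, 8, 8), np.uint8)
        n = np.zeros((1, 8, 8), np.uint8)
        i[0, 3, 3] = 200
        n[0, 0, 0] = 255
        rgb = combine_channels(self._series(i, "interstitial"),
                               self._series(n, "neutrophil"))
        assert tuple(rgb[0, 3, 3]) == (0, 0, 200)
        assert tuple(rgb[0, 0, 0]) == (255, 0, 0)
        all_zero = combine_channels(
            self._series(np.zeros((1, 8, 8), np.uint8), "interstitial"),
            self._series(np.zeros((1, 8, 8), np.uint8), "neutrophil"))
        assert not all_zero.any()

    def test_misaligned_series_rejected(self):
        a = self._series(np.zeros((2, 8, 8), np.uint8), "interstitial")
        b = self._series(np.zeros((3, 8, 8), np.uint8), "neutrophil")
        with pytest.raises(ValueError, match="not aligned"):
            combine_channels(a, b)


class TestFeatureTable:
    def test_round_trip_and_shape(self, tmp_path):
        stats = make_stats([1.5, 2.25, 3.125, 4.0625, 5.0])
        path = write_feature_table(stats, tmp_path / "features.csv")
        assert (tmp_path / "features.json").exists()
        df = read_feature_table(path)
        assert len(df) == 5
        np.testing.assert_allclose(df["alveolar_area_pct"],
                                   [1.5, 2.25, 3.125, 4.0625, 5.0],
                                   atol=1e-6)

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_feature_table([], tmp_path / "features.csv")
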