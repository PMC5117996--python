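"""Blending, chunked compositing and pyramid conformance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msemstitch.model import TileRecord
from msemstitch.render import (
    ChunkStore,
    _level_dims,
    blend_weight_map,
    build_pyramid,
    composite_mosaic,
    pyramid_tile_path,
)


class TestBlendWeightMap:
    @given(w=st.integers(4, 200), h=st.integers(4, 200))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_positive_normalised_and_flip_symmetric(self, w, h):
        wm = blend_weight_map((w, h))
        assert wm.shape == (h, w)
        assert wm.min() > 0
        assert wm.max() == pytest.approx(1.0)
        assert np.allclose(wm, wm[::-1, :])
        assert np.allclose(wm, wm[:, ::-1])

    def test_center_max_corner_min(self):
        wm = blend_weight_map((31, 21))
        assert wm[10, 15] == wm.max()
        assert wm[0, 0] == wm.min()


class TestPyramidTilePath:
    @pytest.mark.parametrize(
        "zoom, x, y, max_zoom, expected",
        [
            (10, 5, 2, 10, "0/2/2_5_0.png"),
            (0, 0, 0, 10, "10/0/0_0_10.png"),
            (3, 7, 1, 4, "1/1/1_7_1.png"),
        ],
    )
    def test_template(self, zoom, x, y, max_zoom, expected):
        assert pyramid_tile_path(zoom, x, y, max_zoom) == expected

    def test_out_of_range_zoom_rejected(self):
        with pytest.raises(ValueError):
            pyramid_tile_path(5, 0, 0, 4)
        with pytest.raises(ValueError):
            pyramid_tile_path(-1, 0, 0, 4)

    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 40), st.integers(0, 40)),
            min_size=2, max_size=30, unique=True,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_injective(self, coords):
        paths = [pyramid_tile_path(z, x, y, 6) for z, x, y in coords]
        assert len(set(paths)) == len(paths)


def tile_from(arr, tid="a", pos=(0, 0)):
    h, w = arr.shape
    return TileRecord(tid, 0, 0, np.array(pos, float), (w, h), arr)


@pytest.fixture()
def texture():
    rng = np.random.default_rng(0)
    return rng.integers(0, 256, size=(600, 700), dtype=np.uint8)


class TestCompositeMosaic:
    def test_single_tile_bit_exact(self, tmp_path, texture):
        img = texture[:100, :120]
        t = tile_from(img)
        store = composite_mosaic([t], {"a": np.zeros(2)}, tmp_path / "m", chunk_size=256)
        assert (store.width, store.height) == (120, 100)
        assert np.array_equal(store.read_region(0, 0, 120, 100), img)

    def test_registered_overlap_blends_to_source(self, tmp_path, texture):
        a = tile_from(texture[0:100, 0:120].copy(), "a", (0, 0))
        b = tile_from(texture[0:100, 90:210].copy(), "b", (90, 0))
        store = composite_mosaic(
            [a, b], {"a": np.zeros(2), "b": np.array([90.0, 0.0])}, tmp_path / "m",
            chunk_size=512,
        )
        assert np.array_equal(store.read_region(0, 0, 210, 100), texture[0:100, 0:210])

    def test_uncovered_pixels_take_background(self, tmp_path, texture):
        a = tile_from(texture[:50, :60].copy(), "a", (0, 0))
        b = tile_from(texture[:50, :60].copy(), "b", (200, 0))
        store = composite_mosaic(
            [a, b], {"a": np.zeros(2), "b": np.array([200.0, 0.0])}, tmp_path / "m",
            chunk_size=512, background=7,
        )
        gap = store.read_region(100, 0, 150, 50)
        assert (gap == 7).all()

    def test_chunking_is_seamless(self, tmp_path, texture):
        # one tile spanning several chunks reads back identically
        t = tile_from(texture[:300, :300].copy())
        store = composite_mosaic([t], {"a": np.zeros(2)}, tmp_path / "m", chunk_size=300)
        store2 = composite_mosaic([t], {"a": np.zeros(2)}, tmp_path / "m2", chunk_size=2048)
        assert np.array_equal(
            store.read_region(0, 0, 300, 300), store2.read_region(0, 0, 300, 300)
        )

    def test_empty_tile_set_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            composite_mosaic([], {}, tmp_path / "m")

    def test_mosaic_matches_scene_outside_artifacts(self, tmp_path, mfov19):
        store = composite_mosaic(
            mfov19.tiles, mfov19.true_positions, tmp_path / "m", chunk_size=1024
        )
        ox, oy = (int(v) for v in store.origin)
        full = store.read_region(0, 0, store.width, store.height).astype(float)
        sub = mfov19.scene[oy : oy + store.height, ox : ox + store.width].astype(float)
        covered = np.zeros(full.shape, bool)
        w, h = mfov19.tiles[0].frame_size
        for tid, p in mfov19.true_positions.items():
            x, y = int(p[0]) - ox, int(p[1]) - oy
            covered[y : y + h, x : x + w] = True
        assert np.abs(full - sub)[covered].mean() < 1.0


class TestBuildPyramid:
    def make_store(self, tmp_path, arr, chunk=512):
        t = tile_from(arr, "a")
        return composite_mosaic([t], {"a": np.zeros(2)}, tmp_path / "m", chunk_size=max(chunk, arr.shape[1], arr.shape[0]))

    def test_512_square_has_two_levels(self, tmp_path, texture):
        store = self.make_store(tmp_path, texture[:512, :512].copy())
        layout = build_pyramid(store, tmp_path / "p")
        assert layout.max_zoom == 1
        assert layout.levels == [(1, 1), (2, 2)]
        assert (tmp_path / "p" / "0/1/1_1_0.png").is_file()
        assert (tmp_path / "p" / "1/0/0_0_1.png").is_file()

    def test_constant_mosaic_stays_constant(self, tmp_path):
        arr = np.full((300, 520), 91, dtype=np.uint8)
        store = self.make_store(tmp_path, arr)
        layout = build_pyramid(store, tmp_path / "p")
        import imageio.v3 as iio

        for zoom, (nx, ny) in enumerate(layout.levels):
            dims = _level_dims(store.width, store.height, 256)
            w, h, _, _ = dims[layout.max_zoom - zoom]
            for ty in range(ny):
                for tx in range(nx):
                    img = iio.imread(tmp_path / "p" / pyramid_tile_path(zoom, tx, ty, layout.max_zoom))
                    vx = min(256, w - tx * 256)
                    vy = min(256, h - ty * 256)
                    assert (img[:vy, :vx] == 91).all()

    @pytest.mark.parametrize("size", [(256, 256), (512, 512), (1000, 700)])
    def test_level_counts_follow_ceil_halving(self, tmp_path, texture, size):
        w, h = size
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
        store = self.make_store(tmp_path, arr, chunk=1024)
        layout = build_pyramid(store, tmp_path / "p")
        for (nx0, ny0), (nx1, ny1) in zip(layout.levels, layout.levels[1:]):
            assert nx0 == -(-nx1 // 2) and ny0 == -(-ny1 // 2)
        assert layout.levels[0] == (1, 1)

    def test_mean_intensity_conserved_across_levels(self, tmp_path):
        rng = np.random.default_rng(2)
        arr = rng.integers(0, 256, size=(700, 1000), dtype=np.uint8)
        store = self.make_store(tmp_path, arr, chunk=1024)
        layout = build_pyramid(store, tmp_path / "p")
        import imageio.v3 as iio

        dims = _level_dims(store.width, store.height, 256)
        means = []
        for zoom in range(layout.max_zoom + 1):
            w, h, nx, ny = dims[layout.max_zoom - zoom]
            tot = cnt = 0
            for ty in range(ny):
                for tx in range(nx):
                    img = iio.imread(
                        tmp_path / "p" / pyramid_tile_path(zoom, tx, ty, layout.max_zoom)
                    ).astype(float)
                    vx = min(256, w - tx * 256)
                    vy = min(256, h - ty * 256)
                    tot += img[:vy, :vx].sum()
                    cnt += vx * vy
            means.append(tot / cnt)
        for parent, child in zip(means, means[1:]):
            assert abs(parent - child) <= 0.5

    def test_full_resolution_round_trip(self, tmp_path, texture):
        arr = texture[:300, :400].copy()
        store = self.make_store(tmp_path, arr, chunk=512)
        layout = build_pyramid(store, tmp_path / "p")
        import imageio.v3 as iio

        tile = iio.imread(tmp_path / "p" / pyramid_tile_path(layout.max_zoom, 1, 0, layout.max_zoom))
        assert np.array_equal(tile, store.read_region(256, 0, 512, 256))
        assert (tile[:, 144:] == 0).all()  # background padding
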