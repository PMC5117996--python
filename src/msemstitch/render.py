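"""Mosaic compositing and tiled-pyramid export.

Registered tiles are composited with distance-feathered linear blending
into a chunked on-disk store (real mosaics exceed memory), then exported as
a web-map pyramid of 256x256 PNG tiles: the full-resolution level is
partitioned into tiles, and each coarser zoom level is formed by grouping
2x2 child tiles and block-averaging 512x512 -> 256x256, doubling the pixel
size per level, until a level fits in a single tile.  Tile files follow the
path scheme ``(maxzoom-zoom)/y/y_x_(maxzoom-zoom).png``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .model import TileRecord

__all__ = [
    "PyramidLayout",
    "ChunkStore",
    "blend_weight_map",
    "composite_mosaic",
    "build_pyramid",
    "pyramid_tile_path",
]


@dataclass
class PyramidLayout:
    tile_size: int
    max_zoom: int
    levels: list[tuple[int, int]]  # per zoom (ascending): (tile_count_x, tile_count_y)
    path_template: str = "(maxzoom-zoom)/y/y_x_(maxzoom-zoom).png"


def pyramid_tile_path(zoom: int, x: int, y: int, max_zoom: int) -> str:
    """Relative path of a pyramid tile: ``(maxzoom-zoom)/y/y_x_(maxzoom-zoom).png``."""
    if not (0 <= zoom <= max_zoom):
        raise ValueError(f"zoom {zoom} outside [0, {max_zoom}]")
    if x < 0 or y < 0:
        raise ValueError("tile coordinates must be non-negative")
    inv = max_zoom - zoom
    return f"{inv}/{y}/{y}_{x}_{inv}.png"


def blend_weight_map(frame_size: tuple[int, int]) -> np.ndarray:
    """Feathering weights: normalised distance to the nearest tile edge.

    Strictly positive in the interior, maximal at the centre, symmetric
    under horizontal and vertical flips; weights are renormalised per pixel
    at composite time.
    """
    w, h = frame_size
    if w <= 0 or h <= 0:
        raise ValueError("frame_size must be positive")
    ix = np.arange(w, dtype=float)
    iy = np.arange(h, dtype=float)
    dx = np.minimum(ix + 1.0, w - ix)
    dy = np.minimum(iy + 1.0, h - iy)
    weight = np.minimum(dy[:, None], dx[None, :])
    return weight / weight.max()


class ChunkStore:
    """Chunked 2D uint8 image stored as a directory of .npy chunk files.

    Missing chunks read as the background value, so sparse mosaics cost no
    space.  ``meta.json`` records the canvas size, chunk size, background
    and the global coordinate of the canvas origin.
    """

    def __init__(self, path: Path, width: int, height: int, chunk_size: int,
                 background: int = 0, origin: tuple[float, float] = (0.0, 0.0)):
        self.path = Path(path)
        self.width = int(width)
        self.height = int(height)
        self.chunk_size = int(chunk_size)
        self.background = int(background)
        self.origin = (float(origin[0]), float(origin[1]))

    @classmethod
    def create(cls, path, width, height, chunk_size, background=0, origin=(0.0, 0.0)):
        store = cls(path, width, height, chunk_size, background, origin)
        store.path.mkdir(parents=True, exist_ok=True)
        with open(store.path / "meta.json", "w", encoding="utf-8") as fh:
            json.dump(
                dict(width=store.width, height=store.height, chunk_size=store.chunk_size,
                     background=store.background, origin=list(store.origin)),
                fh,
            )
        return store

    @classmethod
    def open(cls, path) -> "ChunkStore":
        path = Path(path)
        with open(path / "meta.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(path, meta["width"], meta["height"], meta["chunk_size"],
                   meta.get("background", 0), tuple(meta.get("origin", (0.0, 0.0))))

    def _chunk_path(self, cy: int, cx: int) -> Path:
        return self.path / f"chunk_{cy}_{cx}.npy"

    def write_chunk(self, cy: int, cx: int, data: np.ndarray) -> None:
        np.save(self._chunk_path(cy, cx), np.ascontiguousarray(data, dtype=np.uint8))

    def read_region(self, x0: int, y0: int, x1: int, y1: int) -> np.ndarray:
        """Read a rectangle in canvas coordinates; out-of-canvas and missing
        chunks read as background."""
        out = np.full((y1 - y0, x1 - x0), self.background, dtype=np.uint8)
        cs = self.chunk_size
        if x1 <= 0 or y1 <= 0 or x0 >= self.width or y0 >= self.height:
            return out
        for cy in range(max(0, y0) // cs, (min(y1, self.height) - 1) // cs + 1):
            for cx in range(max(0, x0) // cs, (min(x1, self.width) - 1) // cs + 1):
                p = self._chunk_path(cy, cx)
                if not p.is_file():
                    continue
                chunk = np.load(p)
                gy0, gx0 = cy * cs, cx * cs
                ry0, ry1 = max(y0, gy0), min(y1, gy0 + chunk.shape[0])
                rx0, rx1 = max(x0, gx0), min(x1, gx0 + chunk.shape[1])
                if ry1 > ry0 and rx1 > rx0:
                    out[ry0 - y0 : ry1 - y0, rx0 - x0 : rx1 - x0] = chunk[
                        ry0 - gy0 : ry1 - gy0, rx0 - gx0 : rx1 - gx0
                    ]
        return out


def composite_mosaic(
    tiles: Sequence[TileRecord],
    positions: Mapping[str, np.ndarray],
    out_store: str | Path,
    chunk_size: int = 2048,
    background: int = 0,
) -> ChunkStore:
    """Blend all tiles into a chunked mosaic.

    Every output pixel is the weight-normalised sum over covering tiles,
    sum(w I) / sum(w), with the feathered weight map; uncovered pixels take
    the background value.  Tile placements are rounded to integer pixels
    (consistent with integer-shift alignment).  Processing is chunk by
    chunk, so peak memory is O(chunk area) regardless of canvas size.
    """
    if not tiles:
        raise ValueError("cannot composite an empty tile set")
    fw, fh = tiles[0].frame_size
    if chunk_size < max(fw, fh):
        raise ValueError(f"chunk_size {chunk_size} smaller than tile frame {tiles[0].frame_size}")
    placed = [
        (t, int(round(positions[t.tile_id][0])), int(round(positions[t.tile_id][1])))
        for t in tiles
    ]
    min_x = min(px for _, px, _ in placed)
    min_y = min(py for _, _, py in placed)
    width = max(px + fw for _, px, _ in placed) - min_x
    height = max(py + fh for _, _, py in placed) - min_y

    store = ChunkStore.create(out_store, width, height, chunk_size, background, (min_x, min_y))
    weights = blend_weight_map((fw, fh))

    ncx = (width - 1) // chunk_size + 1
    ncy = (height - 1) // chunk_size + 1
    # bin tiles by the chunks they touch
    bins: dict[tuple[int, int], list[tuple[TileRecord, int, int]]] = {}
    for t, px, py in placed:
        x, y = px - min_x, py - min_y
        for cy in range(y // chunk_size, (y + fh - 1) // chunk_size + 1):
            for cx in range(x // chunk_size, (x + fw - 1) // chunk_size + 1):
                bins.setdefault((cy, cx), []).append((t, x, y))

    for (cy, cx), members in sorted(bins.items()):
        gy0, gx0 = cy * chunk_size, cx * chunk_size
        ch = min(chunk_size, height - gy0)
        cw = min(chunk_size, width - gx0)
        acc = np.zeros((ch, cw), dtype=np.float64)
        wacc = np.zeros((ch, cw), dtype=np.float64)
        for t, x, y in members:
            ry0, ry1 = max(gy0, y), min(gy0 + ch, y + fh)
            rx0, rx1 = max(gx0, x), min(gx0 + cw, x + fw)
            if ry1 <= ry0 or rx1 <= rx0:
                continue
            img = t.image().astype(np.float64)
            wsub = weights[ry0 - y : ry1 - y, rx0 - x : rx1 - x]
            acc[ry0 - gy0 : ry1 - gy0, rx0 - gx0 : rx1 - gx0] += wsub * img[
                ry0 - y : ry1 - y, rx0 - x : rx1 - x
            ]
            wacc[ry0 - gy0 : ry1 - gy0, rx0 - gx0 : rx1 - gx0] += wsub
        out = np.full((ch, cw), background, dtype=np.uint8)
        covered = wacc > 0
        out[covered] = np.clip(np.round(acc[covered] / wacc[covered]), 0, 255).astype(np.uint8)
        store.write_chunk(cy, cx, out)
    return store


def _write_png(path: Path, data: np.ndarray) -> None:
    import imageio.v3 as iio

    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.ascontiguousarray(data, dtype=np.uint8))


def _level_dims(width: int, height: int, tile_size: int) -> list[tuple[int, int, int, int]]:
    """Valid pixel dims and tile counts per level, finest first, until one tile."""
    dims = []
    w, h = width, height
    while True:
        nx = (w - 1) // tile_size + 1
        ny = (h - 1) // tile_size + 1
        dims.append((w, h, nx, ny))
        if nx == 1 and ny == 1:
            break
        w = (w + 1) // 2
        h = (h + 1) // 2
    return dims


def build_pyramid(
    mosaic_store: ChunkStore | str | Path,
    out_dir: str | Path,
    tile_size: int = 256,
    background: int = 0,
) -> PyramidLayout:
    """Export the mosaic as a tiled pyramid of PNG files.

    The finest level partitions the mosaic into ``tile_size`` squares (edge
    tiles padded with background).  Each coarser level averages 2x2 blocks
    of child pixels; blocks straddling the valid-content boundary average
    only their valid pixels, so mean intensity over the valid area is
    conserved to within rounding.  A ``manifest.json`` and a minimal HTML
    stub for slippy-map viewers are written alongside the tiles.
    """
    if not isinstance(mosaic_store, ChunkStore):
        mosaic_store = ChunkStore.open(mosaic_store)
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create pyramid output directory {out_dir}: {exc}") from exc

    dims = _level_dims(mosaic_store.width, mosaic_store.height, tile_size)
    max_zoom = len(dims) - 1  # dims[0] is the finest level = zoom max_zoom

    # finest level straight from the chunk store
    w, h, nx, ny = dims[0]
    for ty in range(ny):
        for tx in range(nx):
            data = mosaic_store.read_region(
                tx * tile_size, ty * tile_size, (tx + 1) * tile_size, (ty + 1) * tile_size
            )
            _write_png(out_dir / pyramid_tile_path(max_zoom, tx, ty, max_zoom), data)

    # coarser levels from the children below
    for lev in range(1, len(dims)):
        zoom = max_zoom - lev
        cw, chh, cnx, cny = dims[lev - 1]  # child level valid dims
        w, h, nx, ny = dims[lev]
        for ty in range(ny):
            for tx in range(nx):
                block = np.full((2 * tile_size, 2 * tile_size), background, dtype=np.uint8)
                valid = np.zeros((2 * tile_size, 2 * tile_size), dtype=bool)
                for oy in (0, 1):
                    for ox in (0, 1):
                        cxt, cyt = 2 * tx + ox, 2 * ty + oy
                        if cxt >= cnx or cyt >= cny:
                            continue
                        child = out_dir / pyramid_tile_path(zoom + 1, cxt, cyt, max_zoom)
                        import imageio.v3 as iio

                        img = iio.imread(child)
                        block[
                            oy * tile_size : (oy + 1) * tile_size,
                            ox * tile_size : (ox + 1) * tile_size,
                        ] = img
                        # valid content extent inside this child tile
                        vx = min(tile_size, cw - cxt * tile_size)
                        vy = min(tile_size, chh - cyt * tile_size)
                        valid[
                            oy * tile_size : oy * tile_size + vy,
                            ox * tile_size : ox * tile_size + vx,
                        ] = True
                f = block.astype(np.float64)
                num = (
                    f[0::2, 0::2] * valid[0::2, 0::2]
                    + f[1::2, 0::2] * valid[1::2, 0::2]
                    + f[0::2, 1::2] * valid[0::2, 1::2]
                    + f[1::2, 1::2] * valid[1::2, 1::2]
                )
                cnt = (
                    valid[0::2, 0::2].astype(int)
                    + valid[1::2, 0::2]
                    + valid[0::2, 1::2]
                    + valid[1::2, 1::2]
                )
                down = np.full((tile_size, tile_size), background, dtype=np.uint8)
                nz = cnt > 0
                down[nz] = np.clip(np.round(num[nz] / cnt[nz]), 0, 255).astype(np.uint8)
                _write_png(out_dir / pyramid_tile_path(zoom, tx, ty, max_zoom), down)

    levels = [(nx, ny) for _, _, nx, ny in reversed(dims)]  # ascending zoom
    layout = PyramidLayout(tile_size=tile_size, max_zoom=max_zoom, levels=levels)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(
            dict(
                tile_size=tile_size,
                max_zoom=max_zoom,
                mosaic_width=mosaic_store.width,
                mosaic_height=mosaic_store.height,
                levels=[list(l) for l in levels],
                path_template=layout.path_template,
            ),
            fh,
            indent=2,
        )
    (out_dir / "index.html").write_text(
        "<!doctype html><title>mosaic pyramid</title>\n"
        "<!-- Tile directory for any slippy-map viewer; path scheme: "
        f"{layout.path_template}, tile size {tile_size}, max zoom {max_zoom}. -->\n",
        encoding="utf-8",
    )
    return layout
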