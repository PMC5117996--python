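"""Domain types and overlap-graph construction for multi-beam SEM mosaics.

A multi-beam acquisition is a set of rectangular single-beam image tiles,
grouped into hexagonal multi-beam fields of view (mFOVs), each tile carrying
an approximate stage position from the microscope metadata.  The overlap
graph connects every pair of tiles whose frames, placed at those stage
positions, intersect; it is the structure on which pairwise alignment,
correction and global registration operate.

Coordinate convention: origin at the top-left, x to the right, y down,
0-based pixel indices.  A tile's ``stage_position`` is the global position of
its top-left corner, in pixels.  Rectangles are ``(x0, y0, x1, y1)`` with the
upper bounds exclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TileRecord",
    "AcquisitionMeta",
    "OverlapPair",
    "INTRA_1",
    "INTRA_2A",
    "INTRA_2B",
    "REASON_NONE",
    "REASON_LOW_R",
    "REASON_LONG_RESIDUAL",
    "REASON_SHIFT_EXCEEDS_OVERLAP",
    "REASON_NO_OVERLAP_RESULT",
    "build_overlap_graph",
    "classify_overlap_type",
    "rect_intersection",
    "rect_area",
]

# Overlap-type labels.  Intra-mFOV relations: lateral neighbour in the same
# row (INTRA_1) and the two diagonal-row neighbours (INTRA_2A: partner tile
# down-right, INTRA_2B: down-left).  Inter-mFOV pairs are binned by the
# direction of x_i - x_j into eight 45-degree sectors, INTER_0 .. INTER_7,
# with INTER_0 centred on +x.
INTRA_1 = "INTRA_1"
INTRA_2A = "INTRA_2A"
INTRA_2B = "INTRA_2B"

REASON_NONE = "NONE"
REASON_LOW_R = "LOW_R"
REASON_LONG_RESIDUAL = "LONG_RESIDUAL"
REASON_SHIFT_EXCEEDS_OVERLAP = "SHIFT_EXCEEDS_OVERLAP"
REASON_NO_OVERLAP_RESULT = "NO_OVERLAP_RESULT"

# Centered hexagonal numbers: valid tile counts for a hexagonal mFOV.
HEX_TILE_COUNTS = (1, 7, 19, 37, 61)


@dataclass
class TileRecord:
    """One single-beam image tile.

    ``image_source`` is either a 2D uint8 array held in memory or a path to
    an 8-bit grayscale image file (PNG/TIFF/BMP).
    """

    tile_id: str
    mfov_id: int
    beam_index: int
    stage_position: np.ndarray  # (x, y), pixels, global frame
    frame_size: tuple[int, int]  # (width, height), pixels
    image_source: np.ndarray | Path | None = None

    def __post_init__(self) -> None:
        self.stage_position = np.asarray(self.stage_position, dtype=float)
        w, h = self.frame_size
        if w <= 0 or h <= 0:
            raise ValueError(f"tile {self.tile_id}: frame_size must be positive, got {self.frame_size}")

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.mfov_id, self.beam_index)

    def frame_rect(self) -> np.ndarray:
        """Axis-aligned frame rectangle at the stage position."""
        x, y = self.stage_position
        w, h = self.frame_size
        return np.array([x, y, x + w, y + h], dtype=float)

    def image(self) -> np.ndarray:
        """Resolve the pixel data as a 2D uint8 array."""
        if self.image_source is None:
            raise ValueError(f"tile {self.tile_id} has no image source")
        if isinstance(self.image_source, np.ndarray):
            return self.image_source
        import imageio.v3 as iio

        arr = iio.imread(self.image_source)
        if arr.ndim == 3:  # collapse any color axis; tiles are grayscale
            arr = arr[..., 0]
        return np.ascontiguousarray(arr, dtype=np.uint8)


@dataclass
class AcquisitionMeta:
    """Acquisition-level constants carried alongside the tile list."""

    pixel_size_nm: float = 10.0
    stage_precision_um: float = 2.0
    tiles_per_mfov: int = 61
    layout: str = "hex"

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.layout == "hex" and self.tiles_per_mfov not in HEX_TILE_COUNTS:
            raise ValueError(
                f"tiles_per_mfov={self.tiles_per_mfov} is not a centered hexagonal "
                f"number {HEX_TILE_COUNTS}"
            )

    @property
    def stage_precision_px(self) -> float:
        return self.stage_precision_um * 1000.0 / self.pixel_size_nm


@dataclass
class OverlapPair:
    """An edge of the overlap graph.

    ``tile_i`` precedes ``tile_j`` under the lexicographic (mfov_id,
    beam_index) order, and ``p`` is always the optimal relative position
    x_i - x_j for that order.  ``r0`` is the initial residual
    (stage_i - stage_j) - p; ``r0_orig`` retains the pre-correction value
    for diagnostics.
    """

    tile_i: str
    tile_j: str
    overlap_type: str | None = None
    overlap_rect: np.ndarray | None = None  # (x0, y0, x1, y1)
    R: float | None = None
    p: np.ndarray | None = None
    r0: np.ndarray | None = None
    r0_orig: np.ndarray | None = None
    corrected: str = REASON_NONE

    def key(self) -> tuple[str, str]:
        return (self.tile_i, self.tile_j)

    def copy(self) -> "OverlapPair":
        return OverlapPair(
            tile_i=self.tile_i,
            tile_j=self.tile_j,
            overlap_type=self.overlap_type,
            overlap_rect=None if self.overlap_rect is None else self.overlap_rect.copy(),
            R=self.R,
            p=None if self.p is None else np.array(self.p, dtype=float),
            r0=None if self.r0 is None else np.array(self.r0, dtype=float),
            r0_orig=None if self.r0_orig is None else np.array(self.r0_orig, dtype=float),
            corrected=self.corrected,
        )


def rect_intersection(a: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    x0 = max(a[0], b[0])
    y0 = max(a[1], b[1])
    x1 = min(a[2], b[2])
    y1 = min(a[3], b[3])
    if x1 <= x0 or y1 <= y0:
        return None
    return np.array([x0, y0, x1, y1], dtype=float)


def rect_area(rect: np.ndarray) -> float:
    return float(max(0.0, rect[2] - rect[0]) * max(0.0, rect[3] - rect[1]))


def build_overlap_graph(
    tiles: Sequence[TileRecord], min_overlap_px: float = 256.0
) -> list[OverlapPair]:
    """Enumerate all unordered tile pairs whose frames intersect.

    Frames are axis-aligned rectangles placed at the stage positions; a pair
    is kept when the intersection area is at least ``min_overlap_px`` square
    pixels (default 16x16), excluding corner-touch slivers too small for
    phase correlation.  The result is duplicate-free, ordered by the
    canonical (mfov_id, beam_index) key, classified by overlap type, and
    invariant under permutation of the input.
    """
    if not tiles:
        return []
    frame_sizes = {t.frame_size for t in tiles}
    if len(frame_sizes) > 1:
        raise ValueError(f"tiles do not share a frame size: {sorted(frame_sizes)}")
    order = sorted(range(len(tiles)), key=lambda idx: tiles[idx].sort_key)
    ts = [tiles[idx] for idx in order]
    n = len(ts)
    w, h = ts[0].frame_size
    pos = np.array([t.stage_position for t in ts], dtype=float)  # (n, 2)
    x0, y0 = pos[:, 0], pos[:, 1]
    x1, y1 = x0 + w, y0 + h

    pairs: list[OverlapPair] = []
    by_id = {t.tile_id: t for t in ts}
    if len(by_id) != n:
        raise ValueError("duplicate tile_id in acquisition")
    # Row-chunked all-pairs intersection test: O(n^2) work, O(chunk*n) memory.
    chunk = max(1, int(2_000_000 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        iw = np.minimum(x1[start:stop, None], x1[None, :]) - np.maximum(
            x0[start:stop, None], x0[None, :]
        )
        ih = np.minimum(y1[start:stop, None], y1[None, :]) - np.maximum(
            y0[start:stop, None], y0[None, :]
        )
        area = np.where((iw > 0) & (ih > 0), iw * ih, 0.0)
        ii, jj = np.nonzero(area >= min_overlap_px)
        for a, b in zip(ii + start, jj):
            if a >= b:  # keep i < j in canonical order only
                continue
            ti, tj = ts[a], ts[b]
            rect = rect_intersection(ti.frame_rect(), tj.frame_rect())
            assert rect is not None
            pair = OverlapPair(tile_i=ti.tile_id, tile_j=tj.tile_id, overlap_rect=rect)
            pair.overlap_type = classify_overlap_type(pair, by_id)
            pairs.append(pair)
    pairs.sort(key=lambda pr: (by_id[pr.tile_i].sort_key, by_id[pr.tile_j].sort_key))
    return pairs


def classify_overlap_type(pair: OverlapPair, tiles: Mapping[str, TileRecord]) -> str:
    """Deterministic geometric label for an overlap pair.

    Intra-mFOV pairs: INTRA_1 when the displacement is predominantly
    horizontal (same-row lateral neighbour), otherwise one of the diagonal
    relations INTRA_2A / INTRA_2B split by the horizontal sign.  Inter-mFOV
    pairs: the direction of x_i - x_j quantised into eight 45-degree bins.
    """
    ti = tiles[pair.tile_i]
    tj = tiles[pair.tile_j]
    d = ti.stage_position - tj.stage_position
    dx, dy = float(d[0]), float(d[1])
    if ti.mfov_id == tj.mfov_id:
        if abs(dy) <= 0.5 * abs(dx):
            return INTRA_1
        # canonical order puts j in the later row, so d points upward;
        # the sign of dx separates the two diagonal relations
        return INTRA_2A if dx <= 0 else INTRA_2B
    theta = math.degrees(math.atan2(dy, dx))
    sector = int(round(theta / 45.0)) % 8
    return f"INTER_{sector}"
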