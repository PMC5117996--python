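"""Pairwise translation estimation by Fourier phase correlation.

For each overlapping tile pair the relative translation p = x_i - x_j that
best superimposes the shared content is estimated from the peak of the
inverse-transformed normalised cross-power spectrum, and the alignment
quality R is the Pearson correlation of the overlapping pixels at that
shift, clipped to [0, 1].

Shift convention: ``phase_correlate(a, b)`` returns the (dx, dy) by which
the content of ``b`` is displaced relative to ``a``, i.e.
``b[y, x] == a[y - dy, x - dx]`` for a pure cyclic translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .model import REASON_NO_OVERLAP_RESULT, REASON_NONE, OverlapPair, TileRecord

__all__ = ["AlignmentResult", "phase_correlate", "align_pair"]

_EPS = 1e-12


@dataclass
class AlignmentResult:
    shift: np.ndarray  # (dx, dy), integer pixels, displacement of b relative to a
    R: float
    n_peaks_tested: int
    degenerate: bool = False


def _overlap_slices(shape: tuple[int, int], dy: int, dx: int):
    """Index slices of the region of ``a`` and ``b`` that coincide when the
    content of ``b`` is ``a`` displaced by (dy, dx)."""
    h, w = shape
    ay0, ay1 = max(0, -dy), min(h, h - dy)
    ax0, ax1 = max(0, -dx), min(w, w - dx)
    by0, by1 = max(0, dy), min(h, h + dy)
    bx0, bx1 = max(0, dx), min(w, w + dx)
    return (slice(ay0, ay1), slice(ax0, ax1)), (slice(by0, by1), slice(bx0, bx1))


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u.astype(np.float64, copy=False)
    v = v.astype(np.float64, copy=False)
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u * u).sum() * (v * v).sum())
    if denom < _EPS:
        return 0.0
    return float((u * v).sum() / denom)


def phase_correlate(
    region_a: np.ndarray,
    region_b: np.ndarray,
    max_shift: int,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
    n_peaks: int = 4,
    min_valid: int = 64,
    subpixel: bool = False,
) -> AlignmentResult:
    """Estimate the integer translation between two equally shaped regions.

    The correlation surface is the inverse transform of the normalised
    cross-power spectrum.  The ``n_peaks`` strongest peaks within
    +-``max_shift`` are taken; each peak's four periodic interpretations are
    disambiguated by evaluating the Pearson correlation of the overlap
    pixels they imply (restricted to valid-mask pixels when masks are
    given), and the candidate with the highest correlation wins.  Ties are
    broken by smaller shift magnitude, then lexicographically.

    Degenerate (zero-variance) input yields R = 0 and shift (0, 0).
    ``subpixel`` is accepted for interface completeness; estimation is
    integer-valued (residuals are reported in whole pixels) and the flag
    currently has no effect.
    """
    a = np.asarray(region_a, dtype=np.float64)
    b = np.asarray(region_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"regions must share a shape, got {a.shape} vs {b.shape}")
    if min(a.shape) < 8:
        raise ValueError(f"regions too small for correlation: {a.shape}")
    if max_shift < 0:
        raise ValueError("max_shift must be non-negative")

    ma = np.ones(a.shape, dtype=bool) if mask_a is None else np.asarray(mask_a, dtype=bool)
    mb = np.ones(b.shape, dtype=bool) if mask_b is None else np.asarray(mask_b, dtype=bool)

    def _prep(img: np.ndarray, mask: np.ndarray) -> np.ndarray | None:
        vals = img[mask]
        if vals.size == 0 or vals.std() < _EPS:
            return None
        out = np.zeros_like(img)
        out[mask] = vals - vals.mean()
        return out

    a0 = _prep(a, ma)
    b0 = _prep(b, mb)
    if a0 is None or b0 is None:
        return AlignmentResult(np.zeros(2, dtype=int), 0.0, 0, degenerate=True)

    fa = scipy.fft.fft2(a0)
    fb = scipy.fft.fft2(b0)
    cross = fa * np.conj(fb)
    cross /= np.abs(cross) + _EPS
    surf = scipy.fft.ifft2(cross).real

    h, w = surf.shape
    # peak at index (py, px) corresponds to content displacement
    # (dy, dx) = (-py mod h, -px mod w); admit only wrapped shifts within range
    fy = np.fft.fftfreq(h, 1.0 / h).astype(int)  # 0..h/2, -h/2..-1
    fx = np.fft.fftfreq(w, 1.0 / w).astype(int)
    dy_of_idx = -fy
    dx_of_idx = -fx
    allowed = (np.abs(dy_of_idx)[:, None] <= max_shift + 1) & (
        np.abs(dx_of_idx)[None, :] <= max_shift + 1
    )
    masked = np.where(allowed, surf, -np.inf)

    candidates: list[tuple[int, int]] = []
    work = masked.copy()
    for _ in range(n_peaks):
        idx = int(np.argmax(work))
        py, px = divmod(idx, w)
        if not np.isfinite(work[py, px]):
            break
        # suppress a neighbourhood around the taken peak (cyclic)
        for oy in range(-2, 3):
            for ox in range(-2, 3):
                work[(py + oy) % h, (px + ox) % w] = -np.inf
        # four periodic interpretations of the peak
        base_dy = int(dy_of_idx[py])
        base_dx = int(dx_of_idx[px])
        for dy in {base_dy, base_dy - h if base_dy > 0 else base_dy + h}:
            for dx in {base_dx, base_dx - w if base_dx > 0 else base_dx + w}:
                if abs(dy) <= max_shift and abs(dx) <= max_shift and abs(dy) < h and abs(dx) < w:
                    candidates.append((dy, dx))

    if not candidates:
        candidates = [(0, 0)]
    candidates = sorted(set(candidates))

    best: tuple[float, float, int, int] | None = None  # (R, hypot, dx, dy)
    n_tested = 0
    for dy, dx in candidates:
        sl_a, sl_b = _overlap_slices((h, w), dy, dx)
        valid = ma[sl_a] & mb[sl_b]
        if valid.sum() < min_valid:
            continue
        r = _pearson(a[sl_a][valid], b[sl_b][valid])
        n_tested += 1
        cand = (r, float(np.hypot(dx, dy)), dx, dy)
        if best is None:
            best = cand
            continue
        if r > best[0] + 1e-9:
            best = cand
        elif abs(r - best[0]) <= 1e-9 and (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3]):
            best = cand
    if best is None:
        return AlignmentResult(np.zeros(2, dtype=int), 0.0, 0, degenerate=True)
    r, _, dx, dy = best
    return AlignmentResult(np.array([dx, dy], dtype=int), float(np.clip(r, 0.0, 1.0)), n_tested)


def _clip_rect_to_frame(rect: np.ndarray, tile: TileRecord) -> np.ndarray | None:
    """Integer intersection of a global rect with a tile's frame."""
    sx, sy = (int(round(v)) for v in tile.stage_position)
    fw, fh = tile.frame_size
    x0 = max(int(rect[0]), sx)
    y0 = max(int(rect[1]), sy)
    x1 = min(int(rect[2]), sx + fw)
    y1 = min(int(rect[3]), sy + fh)
    if x1 <= x0 or y1 <= y0:
        return None
    return np.array([x0, y0, x1, y1], dtype=int)


def _crop_toward(rect: np.ndarray, size: tuple[int, int], center: np.ndarray) -> np.ndarray:
    """Sub-rectangle of the given size positioned as close as possible to
    ``center`` while staying inside ``rect``."""
    w, h = size
    x0 = int(np.clip(round(center[0] - w / 2), rect[0], rect[2] - w))
    y0 = int(np.clip(round(center[1] - h / 2), rect[1], rect[3] - h))
    return np.array([x0, y0, x0 + w, y0 + h], dtype=int)


def _extract(tile: TileRecord, rect: np.ndarray) -> np.ndarray:
    """Pixel data of a global rect fully inside the tile frame."""
    sx, sy = (int(round(v)) for v in tile.stage_position)
    img = tile.image()
    return np.asarray(
        img[rect[1] - sy : rect[3] - sy, rect[0] - sx : rect[2] - sx], dtype=np.float64
    )


def align_pair(
    tile_i: TileRecord,
    tile_j: TileRecord,
    pair: OverlapPair,
    margin: int = 150,
    n_peaks: int = 4,
    min_valid: int = 256,
) -> OverlapPair:
    """Run phase correlation on the predicted overlap of a tile pair.

    The predicted overlap rectangle is expanded by ``margin`` pixels on each
    side (so that content displaced by up to the stage error remains inside
    the search window) and clipped to each tile's frame; equally sized
    fully-valid regions are then cropped from both windows toward the
    overlap centre and correlated, with the measured shift corrected for
    the difference of the two region origins.  On success the pair's ``p``
    (optimal x_i - x_j), ``R`` and initial residual ``r0`` are filled in;
    when too little area remains the pair is flagged ``NO_OVERLAP_RESULT``
    with R = 0.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if pair.overlap_rect is None:
        raise ValueError("pair has no overlap_rect; build the overlap graph first")
    rect = pair.overlap_rect.copy()
    rect[:2] = np.floor(rect[:2]) - margin
    rect[2:] = np.ceil(rect[2:]) + margin

    out = pair.copy()
    stage_diff = np.round(tile_i.stage_position) - np.round(tile_j.stage_position)

    def _fail() -> OverlapPair:
        out.R = 0.0
        out.p = stage_diff.astype(float)
        out.r0 = np.zeros(2)
        out.r0_orig = np.zeros(2)
        out.corrected = REASON_NO_OVERLAP_RESULT
        return out

    rect_a = _clip_rect_to_frame(rect, tile_i)
    rect_b = _clip_rect_to_frame(rect, tile_j)
    if rect_a is None or rect_b is None:
        return _fail()
    size = (
        int(min(rect_a[2] - rect_a[0], rect_b[2] - rect_b[0])),
        int(min(rect_a[3] - rect_a[1], rect_b[3] - rect_b[1])),
    )
    if min(size) < 8 or size[0] * size[1] < min_valid:
        return _fail()
    center = 0.5 * (pair.overlap_rect[:2] + pair.overlap_rect[2:])
    rect_a = _crop_toward(rect_a, size, center)
    rect_b = _crop_toward(rect_b, size, center)
    region_a = _extract(tile_i, rect_a)
    region_b = _extract(tile_j, rect_b)

    origin_diff = rect_b[:2] - rect_a[:2]  # (dx, dy), global frame
    res = phase_correlate(
        region_a,
        region_b,
        max_shift=int(max(margin, np.abs(origin_diff).max() + margin)),
        n_peaks=n_peaks,
        min_valid=min_valid,
    )
    if res.degenerate:
        return _fail()

    # Content displacement s of region_b relative to region_a, together
    # with the origin offset of the two source windows, gives the optimal
    # relative position:  p = (stage_i - stage_j) + s + (origin_b - origin_a).
    out.p = stage_diff + res.shift + origin_diff
    out.R = res.R
    out.r0 = stage_diff - out.p
    out.r0_orig = out.r0.copy()
    out.corrected = REASON_NONE
    return out
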