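"""Synthetic multi-beam SEM acquisitions with known ground truth.

Generates band-limited textured scenes (optionally overlaid with ring
motifs evoking osteonal lamellae), carves them into hexagonal 61-tile
mFOVs of overlapping tiles, perturbs the recorded stage coordinates with
integer-rounded Gaussian jitter emulating finite stage precision, and
optionally injects localised dark/blurred artifact regions of the kind
caused by topographic depressions shielding secondary electrons.  Every
pipeline stage is testable against the retained ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import write_metadata
from .model import HEX_TILE_COUNTS, AcquisitionMeta, TileRecord

__all__ = [
    "SceneSpec",
    "AcquisitionSpec",
    "ArtifactSpec",
    "SyntheticAcquisition",
    "generate_scene",
    "hex_layout",
    "generate_acquisition",
    "inject_artifacts",
    "required_scene_size",
]

ARTIFACT_DARK = "DARK"
ARTIFACT_BLUR = "BLUR"


@dataclass
class SceneSpec:
    """Ground-truth scene: size, texture and seed.

    ``texture``: "noise" for band-limited noise alone, "osteon" to overlay
    concentric ring motifs.  Same spec => bit-identical scene.
    """

    size: tuple[int, int]  # (width, height) px
    texture: str = "osteon"
    seed: int = 0
    smooth_sigma: float = 3.0  # autocorrelation length of the noise base, px

    def __post_init__(self) -> None:
        w, h = self.size
        if w <= 0 or h <= 0:
            raise ValueError("scene size must be positive")
        if self.texture not in ("noise", "osteon"):
            raise ValueError(f"unknown texture {self.texture!r}")


@dataclass
class ArtifactSpec:
    """A localised imaging artifact.

    ``region``: (x0, y0, x1, y1) in ground-truth global coordinates, or
    None together with ``tile_id`` to affect one whole tile.  DARK scales
    intensities by (1 - strength) and adds detector noise; BLUR convolves
    with a Gaussian of sigma proportional to strength.
    """

    kind: str
    strength: float
    region: tuple[float, float, float, float] | None = None
    tile_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (ARTIFACT_DARK, ARTIFACT_BLUR):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must be in [0, 1]")
        if (self.region is None) == (self.tile_id is None):
            raise ValueError("exactly one of region or tile_id must be given")


@dataclass
class AcquisitionSpec:
    """Geometry and noise of a synthetic acquisition.

    Defaults mirror the emulated instrument at reduced scale: hexagonal
    61-tile mFOVs, a quarter-scale 322x280 tile frame (the full 1288x1120
    frame is a configuration choice), 6% overlap within the instrument's
    2.4-55% range, and stage jitter at the scale of stage precision.
    """

    mfov_grid: tuple[int, int] = (1, 1)  # (rows, cols)
    tiles_per_mfov: int = 61
    tile_frame: tuple[int, int] = (322, 280)
    overlap_fraction: float = 0.06
    jitter_sigma: float = 15.0
    mfov_offset_sigma: float = 0.0  # optional common per-mFOV stage error
    artifacts: list[ArtifactSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.024 <= self.overlap_fraction <= 0.55):
            raise ValueError("overlap_fraction outside the instrument's 2.4-55% range")
        if self.jitter_sigma < 0 or self.mfov_offset_sigma < 0:
            raise ValueError("jitter sigma must be non-negative")
        if self.tiles_per_mfov not in HEX_TILE_COUNTS:
            raise ValueError(f"tiles_per_mfov must be one of {HEX_TILE_COUNTS}")


@dataclass
class SyntheticAcquisition:
    tiles: list[TileRecord]
    true_positions: dict[str, np.ndarray]
    stage_positions: dict[str, np.ndarray]
    meta: AcquisitionMeta
    scene: np.ndarray
    metadata_file: Path | None = None


def generate_scene(spec: SceneSpec) -> np.ndarray:
    """Deterministic uint8 scene with non-degenerate texture everywhere."""
    w, h = spec.size
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((h, w), dtype=np.float32)
    base = gaussian_filter(noise, spec.smooth_sigma, mode="reflect")
    base /= base.std() + 1e-9
    # broadband fine grain (shot-noise texture of SEM detection, part of the
    # scene so overlapping crops stay bit-identical); the smooth component
    # dominates the variance, keeping the autocorrelation length >= 4 px
    img = 128.0 + 34.0 * base + 8.0 * noise
    if spec.texture == "osteon":
        # concentric lamellar rings around scattered centres, rendered in a
        # local window (the Gaussian envelope is negligible beyond ~3.5 radii)
        n_rings = max(1, (w * h) // 400_000)
        for _ in range(n_rings):
            cx = rng.uniform(0, w)
            cy = rng.uniform(0, h)
            radius = rng.uniform(60, 220)
            period = rng.uniform(12, 30)
            ext = 3.5 * radius
            x0, x1 = max(0, int(cx - ext)), min(w, int(cx + ext) + 1)
            y0, y1 = max(0, int(cy - ext)), min(h, int(cy + ext) + 1)
            if x1 <= x0 or y1 <= y0:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
            rr = np.hypot(xx - cx, yy - cy)
            env = np.exp(-0.5 * (rr / radius) ** 2)
            img[y0:y1, x0:x1] += 18.0 * env * np.sin(2 * np.pi * rr / period)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _hex_rows(tiles_per_mfov: int) -> list[int]:
    side = {1: 1, 7: 2, 19: 3, 37: 4, 61: 5}[tiles_per_mfov]
    return list(range(side, 2 * side)) + list(range(2 * side - 2, side - 1, -1))


def hex_layout(
    tiles_per_mfov: int,
    tile_frame: tuple[int, int],
    overlap_fraction: float,
) -> np.ndarray:
    """In-mFOV tile offsets for a flat hexagonal beam arrangement.

    For 61 tiles the rows hold 5,6,7,8,9,8,7,6,5 tiles, each row centred,
    with horizontal pitch width*(1-overlap) and vertical pitch
    height*(1-overlap) so both lateral and diagonal neighbours overlap by
    at least the requested fraction.  Offsets are ordered row-major (beam
    index order) and returned relative to the layout's top-left corner.
    """
    if tiles_per_mfov not in HEX_TILE_COUNTS:
        raise ValueError(f"unsupported tiles_per_mfov {tiles_per_mfov}; use one of {HEX_TILE_COUNTS}")
    w, h = tile_frame
    pitch_x = w * (1.0 - overlap_fraction)
    pitch_y = h * (1.0 - overlap_fraction)
    rows = _hex_rows(tiles_per_mfov)
    offsets = []
    for r, count in enumerate(rows):
        y = r * pitch_y
        for cidx in range(count):
            x = (cidx - (count - 1) / 2.0) * pitch_x
            offsets.append((x, y))
    arr = np.array(offsets, dtype=float)
    arr[:, 0] -= arr[:, 0].min()
    return arr


def required_scene_size(spec: AcquisitionSpec, border: int = 64) -> tuple[int, int]:
    """Scene size (width, height) needed to carve the full acquisition."""
    offsets = hex_layout(spec.tiles_per_mfov, spec.tile_frame, spec.overlap_fraction)
    w, h = spec.tile_frame
    span_x = offsets[:, 0].max() + w
    span_y = offsets[:, 1].max() + h
    pitch_mx, pitch_my = _mfov_pitch(spec)
    rows, cols = spec.mfov_grid
    guard = border + int(4 * spec.jitter_sigma + 4 * spec.mfov_offset_sigma)
    stagger = 0.5 * w * (1.0 - spec.overlap_fraction) if rows > 1 else 0.0
    return (
        int(np.ceil((cols - 1) * pitch_mx + span_x + stagger)) + 2 * guard,
        int(np.ceil((rows - 1) * pitch_my + span_y)) + 2 * guard,
    )


def _mfov_pitch(spec: AcquisitionSpec) -> tuple[float, float]:
    """mFOV grid pitch chosen so edge tiles of adjacent mFOVs interlock."""
    offsets = hex_layout(spec.tiles_per_mfov, spec.tile_frame, spec.overlap_fraction)
    w, h = spec.tile_frame
    ov = spec.overlap_fraction
    span_x = offsets[:, 0].max()
    span_y = offsets[:, 1].max()
    pitch_mx = span_x + w * (1.0 - min(2.0 * ov, 0.5))
    pitch_my = span_y + h * (1.0 - ov)
    return pitch_mx, pitch_my


def generate_acquisition(
    scene: np.ndarray,
    spec: AcquisitionSpec,
    out_dir: str | Path | None = None,
) -> SyntheticAcquisition:
    """Carve an acquisition out of a scene.

    Tiles are crops at the (integer) true positions; the recorded stage
    positions are the true positions plus iid integer-rounded Gaussian
    jitter (plus an optional shared per-mFOV offset).  Artifacts in the
    spec are applied to the carved tiles.  With ``out_dir``, tile PNGs, the
    metadata file and ``ground_truth.csv`` are written there.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.tile_frame
    offsets = hex_layout(spec.tiles_per_mfov, spec.tile_frame, spec.overlap_fraction)
    pitch_mx, pitch_my = _mfov_pitch(spec)
    rows, cols = spec.mfov_grid
    guard = 64 + int(4 * spec.jitter_sigma + 4 * spec.mfov_offset_sigma)

    sh, sw = scene.shape
    tiles: list[TileRecord] = []
    true_positions: dict[str, np.ndarray] = {}
    stage_positions: dict[str, np.ndarray] = {}
    mfov_id = 0
    # odd mFOV rows are staggered by half a tile pitch so that adjacent
    # mFOVs interlock like the hexagonal tessellation of the instrument
    stagger = 0.5 * w * (1.0 - spec.overlap_fraction)
    for mr in range(rows):
        for mc in range(cols):
            origin = np.array(
                [guard + mc * pitch_mx + (mr % 2) * stagger, guard + mr * pitch_my]
            )
            mfov_off = (
                np.round(rng.normal(0.0, spec.mfov_offset_sigma, size=2))
                if spec.mfov_offset_sigma > 0
                else np.zeros(2)
            )
            for beam, off in enumerate(offsets):
                true = np.round(origin + off).astype(int)
                x, y = int(true[0]), int(true[1])
                if x < 0 or y < 0 or x + w > sw or y + h > sh:
                    raise ValueError(
                        f"layout exceeds scene bounds: tile mfov={mfov_id} beam={beam} "
                        f"at ({x},{y}) with frame {w}x{h} in scene {sw}x{sh}; "
                        f"need at least {required_scene_size(spec)}"
                    )
                jitter = np.round(rng.normal(0.0, spec.jitter_sigma, size=2))
                tid = f"t_{mfov_id:03d}_{beam:02d}"
                img = np.ascontiguousarray(scene[y : y + h, x : x + w])
                tiles.append(
                    TileRecord(
                        tile_id=tid,
                        mfov_id=mfov_id,
                        beam_index=beam,
                        stage_position=true.astype(float) + jitter + mfov_off,
                        frame_size=(w, h),
                        image_source=img,
                    )
                )
                true_positions[tid] = true.astype(float)
                stage_positions[tid] = tiles[-1].stage_position.copy()
            mfov_id += 1

    if spec.artifacts:
        tiles = inject_artifacts(tiles, spec.artifacts, seed=spec.seed + 1,
                                 positions=true_positions)

    meta = AcquisitionMeta(tiles_per_mfov=spec.tiles_per_mfov)
    metadata_file = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import imageio.v3 as iio

        files = {}
        for t in tiles:
            fname = f"{t.tile_id}.png"
            iio.imwrite(out_dir / fname, t.image())
            files[t.tile_id] = fname
        metadata_file = out_dir / "metadata.csv"
        write_metadata(tiles, meta, metadata_file, files)
        with open(out_dir / "ground_truth.csv", "w", encoding="utf-8") as fh:
            fh.write("tile_id,true_x,true_y\n")
            for tid in sorted(true_positions):
                tx, ty = true_positions[tid]
                fh.write(f"{tid},{tx:.1f},{ty:.1f}\n")

    return SyntheticAcquisition(
        tiles=tiles,
        true_positions=true_positions,
        stage_positions=stage_positions,
        meta=meta,
        scene=scene,
        metadata_file=metadata_file,
    )


def inject_artifacts(
    tiles: Sequence[TileRecord],
    artifact_spec: Sequence[ArtifactSpec],
    seed: int = 0,
    positions: dict[str, np.ndarray] | None = None,
    blur_sigma_scale: float = 30.0,
    dark_noise_sigma: float = 8.0,
) -> list[TileRecord]:
    """Apply dark/blur artifacts; geometry and tile order are unchanged.

    Regions are interpreted in the coordinates of ``positions`` (the true
    positions for synthetic data; defaults to the stage positions).  DARK
    multiplies in-region intensities by (1 - strength) and adds Gaussian
    detector noise of sigma ``dark_noise_sigma * strength``; BLUR convolves
    the region with a Gaussian of sigma ``blur_sigma_scale * strength``.
    Zero-strength artifacts leave tiles bit-identical.
    """
    rng = np.random.default_rng(seed)
    out: list[TileRecord] = []
    pos = positions or {t.tile_id: t.stage_position for t in tiles}
    for t in tiles:
        img = None  # lazily copied
        w, h = t.frame_size
        tx, ty = pos[t.tile_id]
        for art in artifact_spec:
            if art.strength == 0.0:
                continue
            if art.tile_id is not None:
                if art.tile_id != t.tile_id:
                    continue
                x0, y0, x1, y1 = 0, 0, w, h
            else:
                rx0, ry0, rx1, ry1 = art.region
                x0 = int(max(0, np.floor(rx0 - tx)))
                y0 = int(max(0, np.floor(ry0 - ty)))
                x1 = int(min(w, np.ceil(rx1 - tx)))
                y1 = int(min(h, np.ceil(ry1 - ty)))
                if x1 <= x0 or y1 <= y0:
                    continue
            if img is None:
                img = t.image().astype(np.float64)
            sub = img[y0:y1, x0:x1]
            if art.kind == ARTIFACT_DARK:
                sub *= 1.0 - art.strength
                sub += rng.normal(0.0, dark_noise_sigma * art.strength, size=sub.shape)
            else:  # BLUR
                sub[:] = gaussian_filter(sub, blur_sigma_scale * art.strength, mode="nearest")
            img[y0:y1, x0:x1] = sub
        if img is None:
            out.append(t)
        else:
            out.append(
                TileRecord(
                    tile_id=t.tile_id,
                    mfov_id=t.mfov_id,
                    beam_index=t.beam_index,
                    stage_position=t.stage_position.copy(),
                    frame_size=t.frame_size,
                    image_source=np.clip(np.round(img), 0, 255).astype(np.uint8),
                )
            )
    return out
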