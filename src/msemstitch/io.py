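"""Reading and writing acquisition metadata and stage tables.

Metadata format: UTF-8 delimited text with header
``tile_id,mfov_id,beam_index,x_px,y_px,file`` (or ``x_um,y_um`` for physical
coordinates, converted using the pixel size), preceded by optional comment
headers such as ``# pixel_size_nm=10``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AcquisitionMeta, OverlapPair, TileRecord

__all__ = [
    "read_acquisition",
    "write_metadata",
    "write_pair_table",
    "read_pair_table",
    "write_positions",
    "read_positions",
]

_META_KEYS = {
    "pixel_size_nm": float,
    "stage_precision_um": float,
    "tiles_per_mfov": int,
    "layout": str,
}


def _parse_comment_headers(path: Path) -> tuple[dict, int]:
    """Collect ``# key=value`` headers; return them and the row offset."""
    headers: dict = {}
    n_comments = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key in _META_KEYS:
                    headers[key] = _META_KEYS[key](val.strip())
    return headers, n_comments


def read_acquisition(
    tile_dir: str | Path, metadata_file: str | Path
) -> tuple[list[TileRecord], AcquisitionMeta]:
    """Load tile records and acquisition constants from a metadata file.

    Every row must reference an existing image file under ``tile_dir``;
    missing files, duplicate tile ids and non-numeric coordinates are hard
    errors.  Physical (micrometre) coordinates are converted to pixels with
    the declared pixel size.  Images are loaded lazily; the frame size is
    probed from the first tile.
    """
    tile_dir = Path(tile_dir)
    metadata_file = Path(metadata_file)
    headers, n_comments = _parse_comment_headers(metadata_file)
    meta = AcquisitionMeta(**headers)

    df = pd.read_csv(metadata_file, comment="#", dtype={"tile_id": str, "file": str})
    if df.empty:
        return [], meta

    physical = "x_um" in df.columns
    xcol, ycol = ("x_um", "y_um") if physical else ("x_px", "y_px")
    for col in ("tile_id", "mfov_id", "beam_index", xcol, ycol, "file"):
        if col not in df.columns:
            raise ValueError(f"metadata missing required column {col!r}")

    for col in (xcol, ycol):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"non-numeric or non-finite coordinate {col!r} in metadata row "
                f"{row + n_comments + 2} (tile {df['tile_id'].iloc[row]!r})"
            )
        df[col] = vals

    dup = df["tile_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate tile_id {df['tile_id'][dup].iloc[0]!r} in metadata")

    scale = 1000.0 / meta.pixel_size_nm if physical else 1.0  # um -> px
    tiles: list[TileRecord] = []
    frame_size: tuple[int, int] | None = None
    for rec in df.itertuples(index=False):
        img_path = tile_dir / rec.file
        if not img_path.is_file():
            raise FileNotFoundError(f"tile image {rec.file!r} not found for tile {rec.tile_id!r}")
        if frame_size is None:
            import imageio.v3 as iio

            probe = iio.imread(img_path)
            frame_size = (int(probe.shape[1]), int(probe.shape[0]))
        tiles.append(
            TileRecord(
                tile_id=str(rec.tile_id),
                mfov_id=int(rec.mfov_id),
                beam_index=int(rec.beam_index),
                stage_position=np.array(
                    [getattr(rec, xcol) * scale, getattr(rec, ycol) * scale], dtype=float
                ),
                frame_size=frame_size,
                image_source=img_path,
            )
        )
    return tiles, meta


def write_metadata(
    tiles: Sequence[TileRecord],
    meta: AcquisitionMeta,
    path: str | Path,
    files: Mapping[str, str],
) -> None:
    """Write the metadata table; ``files`` maps tile_id to image filename."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pixel_size_nm={meta.pixel_size_nm}\n")
        fh.write(f"# stage_precision_um={meta.stage_precision_um}\n")
        fh.write(f"# tiles_per_mfov={meta.tiles_per_mfov}\n")
        fh.write("tile_id,mfov_id,beam_index,x_px,y_px,file\n")
        for t in sorted(tiles, key=lambda t: t.sort_key):
            x, y = t.stage_position
            fh.write(f"{t.tile_id},{t.mfov_id},{t.beam_index},{x:.6g},{y:.6g},{files[t.tile_id]}\n")


def pairs_to_frame(pairs: Iterable[OverlapPair]) -> pd.DataFrame:
    rows = []
    for pr in pairs:
        p = pr.p if pr.p is not None else (np.nan, np.nan)
        r0 = pr.r0 if pr.r0 is not None else (np.nan, np.nan)
        rows.append(
            dict(
                tile_i=pr.tile_i,
                tile_j=pr.tile_j,
                type=pr.overlap_type,
                R=pr.R,
                p_x=p[0],
                p_y=p[1],
                r0_x=r0[0],
                r0_y=r0[1],
                corrected=pr.corrected,
            )
        )
    return pd.DataFrame(
        rows, columns=["tile_i", "tile_j", "type", "R", "p_x", "p_y", "r0_x", "r0_y", "corrected"]
    )


def write_pair_table(pairs: Iterable[OverlapPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tile_i": str, "tile_j": str})


def write_positions(positions: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tile_id,x_px,y_px\n")
        for tid in sorted(positions):
            x, y = positions[tid]
            fh.write(f"{tid},{x:.6f},{y:.6f}\n")


def read_positions(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, dtype={"tile_id": str})
    return {
        str(r.tile_id): np.array([r.x_px, r.y_px], dtype=float) for r in df.itertuples(index=False)
    }
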