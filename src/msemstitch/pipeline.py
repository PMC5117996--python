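"""End-to-end orchestration: read -> overlap graph -> align -> correct ->
register -> report -> composite -> pyramid, with config echo and logging."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .correction import CorrectionParams, correct_pairs, correction_report
from .model import AcquisitionMeta, OverlapPair, TileRecord, build_overlap_graph
from .pairwise import align_pair
from .registration import (
    MsdParams,
    default_anchor,
    integrate_msd,
    registration_report,
    residuals,
    solve_least_squares,
)
from .render import build_pyramid, composite_mosaic

__all__ = ["RunConfig", "run_stitch", "compare_solvers", "align_all"]

log = logging.getLogger(__name__)

SOLVERS = ("msd", "ls", "wls")


@dataclass
class RunConfig:
    """Parameters of a stitching run; defaults are the nominal instrument
    and model parameters (unit mass/stiffness, c=0.25, n=5, correction
    thresholds R=0.5 / 300 px / R>0.9)."""

    tile_dir: str | None = None
    metadata_file: str | None = None
    out_dir: str = "stitch_run"
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    msd: MsdParams = field(default_factory=MsdParams)
    margin: int = 150
    min_overlap_px: float = 256.0
    solver: str = "msd"
    render: bool = True
    chunk_size: int = 2048
    tile_size: int = 256
    background: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.solver not in SOLVERS:
            raise ValueError(f"solver must be one of {SOLVERS}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "correction" in raw and isinstance(raw["correction"], dict):
            raw["correction"] = CorrectionParams(**raw["correction"])
        if "msd" in raw and isinstance(raw["msd"], dict):
            raw["msd"] = MsdParams(**raw["msd"])
        return cls(**raw)


def align_all(
    tiles: Sequence[TileRecord],
    pairs: Sequence[OverlapPair],
    margin: int = 150,
) -> list[OverlapPair]:
    """Run pairwise phase correlation over the whole overlap graph."""
    by_id = {t.tile_id: t for t in tiles}
    out = []
    for pr in pairs:
        out.append(align_pair(by_id[pr.tile_i], by_id[pr.tile_j], pr, margin=margin))
    return out


def _register(tiles, pairs, config: RunConfig, solver: str):
    anchor = default_anchor(tiles)
    if solver == "msd":
        state = integrate_msd(tiles, pairs, config.msd, anchor_tile=anchor)
        return state.positions, state
    weighted = solver == "wls"
    return solve_least_squares(tiles, pairs, weighted=weighted, params=config.msd,
                               anchor_tile=anchor), None


def run_stitch(
    config: RunConfig,
    tiles: Sequence[TileRecord] | None = None,
    meta: AcquisitionMeta | None = None,
) -> dict:
    """Execute the full pipeline; all stage outputs land in the run directory.

    Identical config and inputs yield identical numeric outputs.  Returns a
    machine-readable summary (also written as ``summary.json``).
    """
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config_echo.yaml")

    def stage(name):
        log.info("stage %s", name)
        return time.time()

    if tiles is None:
        stage("read")
        if config.tile_dir is None or config.metadata_file is None:
            raise ValueError("run_stitch needs either tiles or tile_dir+metadata_file")
        tiles, meta = msio.read_acquisition(config.tile_dir, config.metadata_file)
    if not tiles:
        raise ValueError("stage read: acquisition contains no tiles")
    frame_size = tiles[0].frame_size
    stage_positions = {t.tile_id: t.stage_position.copy() for t in tiles}

    stage("overlap_graph")
    pairs = build_overlap_graph(tiles, min_overlap_px=config.min_overlap_px)
    log.info("overlap graph: %d tiles, %d pairs", len(tiles), len(pairs))

    stage("align")
    pairs = align_all(tiles, pairs, margin=config.margin)
    msio.write_pair_table(pairs, out_dir / "pairs_raw.csv")
    rs = [pr.R for pr in pairs if pr.R is not None]
    median_R = float(np.median(rs)) if rs else float("nan")

    stage("correct")
    corrected = correct_pairs(pairs, config.correction, frame_size=frame_size,
                              stage_positions=stage_positions)
    n_corrected = sum(1 for pr in corrected if pr.corrected != "NONE")
    correction_report(corrected).to_csv(out_dir / "correction_report.csv", index=False)
    msio.write_pair_table(corrected, out_dir / "pairs_corrected.csv")

    stage("register")
    positions, state = _register(tiles, corrected, config, config.solver)
    msio.write_positions(positions, out_dir / "positions.csv")
    if state is not None:
        with open(out_dir / "rms_trace.csv", "w", encoding="utf-8") as fh:
            fh.write("t,rms\n")
            for t, r in state.rms_trace:
                fh.write(f"{t},{r:.9g}\n")

    stage("report")
    report = registration_report(stage_positions, positions, corrected)
    report["pair_table"].to_csv(out_dir / "residuals.csv", index=False)

    mosaic_dims = None
    if config.render:
        stage("composite")
        store = composite_mosaic(tiles, positions, out_dir / "mosaic",
                                 chunk_size=config.chunk_size, background=config.background)
        mosaic_dims = (store.width, store.height)
        stage("pyramid")
        build_pyramid(store, out_dir / "pyramid", tile_size=config.tile_size,
                      background=config.background)

    summary = dict(
        n_tiles=len(tiles),
        n_pairs=len(pairs),
        n_corrected=n_corrected,
        median_R=median_R,
        solver=config.solver,
        rms_before=report["rms_before"],
        rms_after=report["rms_after"],
        mean_before=report["mean_before"],
        mean_after=report["mean_after"],
        reduction_pct=report["reduction_pct"],
        converged=None if state is None else state.converged,
        mosaic_dims=mosaic_dims,
        wall_time_s=time.time() - t_start,
    )
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    summary["positions"] = positions
    summary["pairs"] = corrected
    return summary


def compare_solvers(
    config: RunConfig,
    tiles: Sequence[TileRecord] | None = None,
    meta: AcquisitionMeta | None = None,
) -> pd.DataFrame:
    """Run unweighted LS, weighted LS and MSD on identical inputs.

    Reports per-solver residual RMS plus max/mean pairwise position
    differences between the solvers' solutions.
    """
    if tiles is None:
        if config.tile_dir is None or config.metadata_file is None:
            raise ValueError("compare_solvers needs either tiles or tile_dir+metadata_file")
        tiles, meta = msio.read_acquisition(config.tile_dir, config.metadata_file)
    frame_size = tiles[0].frame_size
    stage_positions = {t.tile_id: t.stage_position.copy() for t in tiles}
    pairs = build_overlap_graph(tiles, min_overlap_px=config.min_overlap_px)
    pairs = align_all(tiles, pairs, margin=config.margin)
    pairs = correct_pairs(pairs, config.correction, frame_size=frame_size,
                          stage_positions=stage_positions)

    solutions: dict[str, Mapping[str, np.ndarray]] = {}
    rows = []
    _, rms0 = residuals(stage_positions, pairs)
    for solver in SOLVERS:
        positions, _ = _register(tiles, pairs, config, solver)
        solutions[solver] = positions
        _, rms = residuals(positions, pairs)
        rows.append(dict(solver=solver, rms_before=rms0, rms_after=rms,
                         reduction_pct=100.0 * (1 - rms / rms0) if rms0 > 0 else 0.0))
    df = pd.DataFrame(rows)
    ids = sorted(stage_positions)
    for a in SOLVERS:
        for b in SOLVERS:
            if a >= b:
                continue
            diffs = np.array([solutions[a][t] - solutions[b][t] for t in ids])
            lens = np.linalg.norm(diffs, axis=1)
            df[f"max_diff_{a}_{b}"] = lens.max()
            df[f"mean_diff_{a}_{b}"] = lens.mean()
    return df
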