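"""Quality-based correction of unsatisfactory pairwise alignments.

Imaging artifacts (dark or blurred regions where secondary-electron
detection failed) produce spurious phase-correlation results.  A pairing is
unsatisfactory when it meets any of four criteria: low correlation (R <
0.5), a long initial residual (> 300 px), an alignment adjustment exceeding
the predicted overlap dimensions, or an implied relative position under
which the frames no longer overlap.  Such pairs have their parameters
replaced by R = 0.5 and p equal to the centroid of the high-quality
(R > 0.9) alignment vectors of the same overlap type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    REASON_LONG_RESIDUAL,
    REASON_LOW_R,
    REASON_NO_OVERLAP_RESULT,
    REASON_NONE,
    REASON_SHIFT_EXCEEDS_OVERLAP,
    OverlapPair,
    TileRecord,
)

__all__ = [
    "CorrectionParams",
    "is_unsatisfactory",
    "estimate_translation_table",
    "correct_pairs",
    "correction_report",
]

log = logging.getLogger(__name__)


@dataclass
class CorrectionParams:
    """Thresholds of the correction stage.

    r_min: pairs below this correlation are rejected and reset to it.
    r0_max: cap on the initial residual length, pixels.
    r_high: threshold defining the high-quality set used for centroids.
    """

    r_min: float = 0.5
    r0_max: float = 300.0
    r_high: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_min < self.r_high <= 1.0):
            raise ValueError(f"need 0 <= r_min < r_high <= 1, got {self.r_min}, {self.r_high}")
        if self.r0_max <= 0:
            raise ValueError("r0_max must be positive")


def is_unsatisfactory(
    pair: OverlapPair,
    params: CorrectionParams,
    frame_size: tuple[int, int] | None = None,
) -> tuple[bool, str]:
    """Apply the four rejection criteria in order; return the first hit.

    Criterion 3 compares the alignment adjustment relative to the stage
    prediction (the initial residual r0) component-wise against the
    predicted overlap width/height.  Criterion 4 checks that two frames at
    relative offset p still intersect (requires ``frame_size``).
    """
    if pair.R is None or pair.p is None or pair.r0 is None:
        raise ValueError(f"pair {pair.key()} has no alignment result")
    if pair.R < params.r_min:
        return True, REASON_LOW_R
    if float(np.hypot(*pair.r0)) > params.r0_max:
        return True, REASON_LONG_RESIDUAL
    if pair.overlap_rect is not None:
        ow = pair.overlap_rect[2] - pair.overlap_rect[0]
        oh = pair.overlap_rect[3] - pair.overlap_rect[1]
        if abs(pair.r0[0]) > ow or abs(pair.r0[1]) > oh:
            return True, REASON_SHIFT_EXCEEDS_OVERLAP
    if frame_size is not None:
        fw, fh = frame_size
        if abs(pair.p[0]) >= fw or abs(pair.p[1]) >= fh:
            return True, REASON_NO_OVERLAP_RESULT
    return False, REASON_NONE


def estimate_translation_table(
    pairs: Sequence[OverlapPair],
    params: CorrectionParams,
    frame_size: tuple[int, int] | None = None,
    stage_positions: Mapping[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-overlap-type centroid of high-quality alignment vectors.

    For each overlap type the component-wise mean of p over satisfactory
    pairs with R > r_high.  A type with no high-quality member falls back to
    the mean stage-predicted offset of its pairs (requires
    ``stage_positions``); the fallback is logged.
    """
    if not pairs:
        return {}
    table: dict[str, np.ndarray] = {}
    groups: dict[str, list[OverlapPair]] = {}
    for pr in pairs:
        groups.setdefault(pr.overlap_type or "UNKNOWN", []).append(pr)
    for otype, members in groups.items():
        good = [
            pr.p
            for pr in members
            if pr.R is not None
            and pr.R > params.r_high
            and not is_unsatisfactory(pr, params, frame_size)[0]
        ]
        if good:
            table[otype] = np.mean(np.asarray(good, dtype=float), axis=0)
        elif stage_positions is not None:
            offs = [
                stage_positions[pr.tile_i] - stage_positions[pr.tile_j] for pr in members
            ]
            table[otype] = np.mean(np.asarray(offs, dtype=float), axis=0)
            log.warning(
                "overlap type %s has no high-quality pair; falling back to the "
                "mean stage-predicted offset over %d pairs",
                otype,
                len(members),
            )
        else:
            log.warning(
                "overlap type %s has no high-quality pair and no stage positions "
                "for a fallback; type left without an estimate",
                otype,
            )
    return table


def correct_pairs(
    pairs: Sequence[OverlapPair],
    params: CorrectionParams,
    frame_size: tuple[int, int] | None = None,
    stage_positions: Mapping[str, np.ndarray] | None = None,
) -> list[OverlapPair]:
    """Replace the alignment parameters of every unsatisfactory pair.

    Rejected pairs get R := r_min and p := the per-type estimated
    translation; their residual r0 is recomputed from the stage positions
    while ``r0_orig`` keeps the pre-correction value.  Satisfactory pairs
    are returned unchanged (as copies).  The operation is idempotent.
    """
    table = estimate_translation_table(pairs, params, frame_size, stage_positions)
    out: list[OverlapPair] = []
    for pr in pairs:
        flag, reason = is_unsatisfactory(pr, params, frame_size)
        new = pr.copy()
        if flag:
            est = table.get(pr.overlap_type or "UNKNOWN")
            # The direction-binned label can misassign a pair whose jittered
            # stage offset sits near a bin boundary, and a centroid from the
            # wrong geometric relation is worse than no correction.  The
            # stage prediction is reliable to the stage precision, so choose
            # the centroid nearest to it among the types sharing the pair's
            # intra/inter character (mFOV membership is exact metadata; the
            # distinct relations within each character are far apart), and
            # keep the stage prediction itself when every centroid is
            # farther away than the residual cap.
            character = (pr.overlap_type or "UNKNOWN").split("_")[0]
            candidates = [ot for ot in sorted(table) if ot.split("_")[0] == character]
            if stage_positions is not None and candidates:
                stage_diff = stage_positions[pr.tile_i] - stage_positions[pr.tile_j]
                nearest = min(
                    candidates,
                    key=lambda ot: float(np.hypot(*(stage_diff - table[ot]))),
                )
                est = table[nearest]
                if float(np.hypot(*(stage_diff - est))) > params.r0_max:
                    log.warning(
                        "pair %s: nearest type centroid (%s) is %.0f px from the "
                        "stage prediction; using the stage-predicted offset",
                        pr.key(),
                        nearest,
                        float(np.hypot(*(stage_diff - est))),
                    )
                    est = stage_diff
                elif nearest != pr.overlap_type:
                    log.info(
                        "pair %s labelled %s corrected with the nearer %s centroid",
                        pr.key(),
                        pr.overlap_type,
                        nearest,
                    )
            new.R = params.r_min
            if est is not None:
                new.p = est.copy()
            if new.corrected == REASON_NONE:  # keep the original reason on re-runs
                new.corrected = reason
            if new.r0_orig is None:
                new.r0_orig = None if pr.r0 is None else np.array(pr.r0, dtype=float)
            if stage_positions is not None and new.p is not None:
                new.r0 = (
                    stage_positions[pr.tile_i] - stage_positions[pr.tile_j] - new.p
                )
        out.append(new)
    return out


def correction_report(pairs: Sequence[OverlapPair]) -> pd.DataFrame:
    """Tabulate corrected pairs with reason codes and replacement vectors."""
    rows = [
        dict(
            tile_i=pr.tile_i,
            tile_j=pr.tile_j,
            type=pr.overlap_type,
            reason=pr.corrected,
            R=pr.R,
            p_x=None if pr.p is None else pr.p[0],
            p_y=None if pr.p is None else pr.p[1],
            r0_orig_x=None if pr.r0_orig is None else pr.r0_orig[0],
            r0_orig_y=None if pr.r0_orig is None else pr.r0_orig[1],
        )
        for pr in pairs
        if pr.corrected != REASON_NONE
    ]
    return pd.DataFrame(
        rows,
        columns=["tile_i", "tile_j", "type", "reason", "R", "p_x", "p_y", "r0_orig_x", "r0_orig_y"],
    )
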