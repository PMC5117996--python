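"""Global registration of tile mosaics.

Each tile is a point mass; each overlapping pair is connected by a spring
whose rest configuration is the pairwise-optimal relative position p and
whose stiffness is k * R^n, so high-quality alignments dominate.  The damped
dynamics

    m x'' + c x' + F_k = 0,      F_k(i) = sum_j k_ij r_ij,
    r_ij = (x_i - x_j) - p_ij

relax the mosaic to the minimum of the weighted sum of squared residuals.
One tile (the centre tile of the first mFOV) is anchored to remove the
global translation degeneracy.  Integration uses an adaptive explicit
Runge-Kutta 4(5) scheme; the residual RMS is evaluated at fixed checkpoints
of simulated time and integration stops once its change falls below a
tolerance while the tiles are at rest (the RMS change alone is insensitive
to slowly drifting tiles whose springs are all weak).  The same minimum can be computed directly by a sparse linear
least-squares solve (weighted or unweighted), which serves as a reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .model import OverlapPair, TileRecord

__all__ = [
    "MsdParams",
    "RegistrationState",
    "spring_stiffness",
    "residuals",
    "msd_derivative",
    "integrate_msd",
    "solve_least_squares",
    "registration_report",
    "default_anchor",
]

log = logging.getLogger(__name__)


@dataclass
class MsdParams:
    """Mechanical and convergence parameters of the relaxation.

    Nominal mechanics: unit mass and spring constant, damping c = 0.25,
    stiffness exponent n = 5 (k_ij = k R^n).  ``conv_tol`` is the
    residual-RMS change per checkpoint below which the system is considered
    at rest; ``conv_checks`` consecutive checkpoint intervals must satisfy
    it, guarding against a coincidental near-zero change at an oscillation
    extremum of an underdamped mode.
    """

    m: float = 1.0
    k: float = 1.0
    c: float = 0.25
    n: float = 5.0
    conv_tol: float = 1e-6
    t_max: float = 1e4
    checkpoint_dt: float = 1.0
    conv_checks: int = 2
    vel_tol: float = 1e-4
    rtol: float = 1e-8
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if self.m <= 0 or self.k <= 0:
            raise ValueError("m and k must be positive")
        if self.c < 0 or self.n < 0:
            raise ValueError("c and n must be non-negative")
        if self.conv_tol <= 0:
            raise ValueError("conv_tol must be positive")


@dataclass
class RegistrationState:
    positions: dict[str, np.ndarray]
    velocities: dict[str, np.ndarray]
    anchor_tile: str
    rms_trace: list[tuple[float, float]]
    energy_trace: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = True


def spring_stiffness(R: float, params: MsdParams) -> float:
    """k_ij = k R^n; a power law of R favouring high-quality pairs."""
    if not (0.0 <= R <= 1.0):
        raise ValueError(f"R must be in [0, 1], got {R}")
    return params.k * R**params.n


# ---------------------------------------------------------------------------
# array plumbing


class _System:
    """Index-space view of a registration problem."""

    def __init__(
        self,
        ids: Sequence[str],
        positions: Mapping[str, np.ndarray],
        pairs: Sequence[OverlapPair],
        params: MsdParams,
    ):
        self.ids = list(ids)
        self.index = {tid: i for i, tid in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValueError("duplicate tile ids")
        self.x0 = np.array([positions[t] for t in self.ids], dtype=float)
        ii, jj, kk, pp = [], [], [], []
        for pr in pairs:
            if pr.tile_i not in self.index or pr.tile_j not in self.index:
                raise KeyError(f"pair {pr.key()} references an unknown tile")
            if pr.p is None or pr.R is None:
                raise ValueError(f"pair {pr.key()} has no alignment parameters")
            ii.append(self.index[pr.tile_i])
            jj.append(self.index[pr.tile_j])
            kk.append(spring_stiffness(float(pr.R), params))
            pp.append(np.asarray(pr.p, dtype=float))
        self.ii = np.asarray(ii, dtype=int)
        self.jj = np.asarray(jj, dtype=int)
        self.kk = np.asarray(kk, dtype=float)
        self.pp = np.asarray(pp, dtype=float).reshape(len(ii), 2)
        self.params = params

    def residual_vectors(self, pos: np.ndarray) -> np.ndarray:
        return pos[self.ii] - pos[self.jj] - self.pp

    def rms(self, pos: np.ndarray) -> float:
        if len(self.ii) == 0:
            return 0.0
        r = self.residual_vectors(pos)
        return float(np.sqrt(np.mean(np.sum(r * r, axis=1))))

    def forces(self, pos: np.ndarray) -> np.ndarray:
        F = np.zeros_like(pos)
        if len(self.ii):
            kr = self.kk[:, None] * self.residual_vectors(pos)
            np.add.at(F, self.ii, kr)
            np.add.at(F, self.jj, -kr)
        return F

    def energy(self, pos: np.ndarray, vel: np.ndarray) -> float:
        kinetic = 0.5 * self.params.m * float(np.sum(vel * vel))
        r = self.residual_vectors(pos)
        potential = 0.5 * float(np.sum(self.kk * np.sum(r * r, axis=1)))
        return kinetic + potential


def _positions_of(tiles) -> dict[str, np.ndarray]:
    if isinstance(tiles, Mapping):
        return {tid: np.asarray(p, dtype=float) for tid, p in tiles.items()}
    return {t.tile_id: np.asarray(t.stage_position, dtype=float) for t in tiles}


def default_anchor(tiles) -> str:
    """The centre-beam tile of the first mFOV: among tiles of the smallest
    mFOV id, the one closest to that mFOV's stage centroid."""
    if isinstance(tiles, Mapping):  # bare positions: first id in sorted order
        return sorted(tiles)[0]
    tiles = list(tiles)
    first = min(t.mfov_id for t in tiles)
    members = [t for t in tiles if t.mfov_id == first]
    centroid = np.mean([t.stage_position for t in members], axis=0)
    return min(members, key=lambda t: (np.linalg.norm(t.stage_position - centroid), t.beam_index)).tile_id


# ---------------------------------------------------------------------------
# public operations


def residuals(
    positions: Mapping[str, np.ndarray], pairs: Sequence[OverlapPair]
) -> tuple[np.ndarray, float]:
    """Per-pair residual vectors r_ij = (x_i - x_j) - p_ij and their RMS."""
    rs = []
    for pr in pairs:
        if pr.tile_i not in positions or pr.tile_j not in positions:
            raise KeyError(f"pair {pr.key()} references an unknown tile")
        rs.append(
            np.asarray(positions[pr.tile_i], dtype=float)
            - np.asarray(positions[pr.tile_j], dtype=float)
            - np.asarray(pr.p, dtype=float)
        )
    if not rs:
        return np.zeros((0, 2)), 0.0
    r = np.asarray(rs)
    return r, float(np.sqrt(np.mean(np.sum(r * r, axis=1))))


def msd_derivative(
    positions: Mapping[str, np.ndarray],
    velocities: Mapping[str, np.ndarray],
    pairs: Sequence[OverlapPair],
    params: MsdParams,
    anchor_tile: str,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Velocities and accelerations of all tiles; the anchor's are zero."""
    ids = sorted(positions)
    sysm = _System(ids, positions, pairs, params)
    pos = sysm.x0
    vel = np.array([velocities[t] for t in ids], dtype=float)
    acc = -(params.c * vel + sysm.forces(pos)) / params.m
    ai = sysm.index[anchor_tile]
    vel_out = vel.copy()
    vel_out[ai] = 0.0
    acc[ai] = 0.0
    return (
        {t: vel_out[i].copy() for i, t in enumerate(ids)},
        {t: acc[i].copy() for i, t in enumerate(ids)},
    )


def _components(n: int, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    if len(ii) == 0:
        return np.arange(n)
    adj = sp.coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    ncomp, labels = csgraph.connected_components(adj, directed=False)
    return labels


def integrate_msd(
    tiles,
    pairs: Sequence[OverlapPair],
    params: MsdParams | None = None,
    anchor_tile: str | None = None,
) -> RegistrationState:
    """Relax the mass-spring-damper system to equilibrium.

    ``tiles`` is a list of TileRecord (initial positions = stage positions)
    or a mapping tile_id -> initial position.  Each connected component of
    the positive-stiffness spring graph is registered with its own anchor
    (the requested anchor for its component, the member closest to the
    component centroid otherwise); isolated or all-R=0 tiles simply stay
    put.  Returns final positions, velocities and the RMS/energy traces.
    """
    params = params or MsdParams()
    positions = _positions_of(tiles)
    anchor = anchor_tile or default_anchor(tiles)
    ids = sorted(positions)
    sysm = _System(ids, positions, pairs, params)
    n = len(ids)

    live = sysm.kk > 0
    labels = _components(n, sysm.ii[live], sysm.jj[live])
    anchors = {labels[sysm.index[anchor]]: sysm.index[anchor]}
    for comp in np.unique(labels):
        if comp in anchors:
            continue
        members = np.nonzero(labels == comp)[0]
        centroid = sysm.x0[members].mean(axis=0)
        anchors[comp] = int(members[np.argmin(np.linalg.norm(sysm.x0[members] - centroid, axis=1))])
    if len(anchors) > 1:
        log.warning(
            "overlap graph has %d connected components; each registered with its own anchor",
            len(anchors),
        )
    anchor_rows = np.array(sorted(anchors.values()), dtype=int)

    pos = sysm.x0.copy()
    vel = np.zeros_like(pos)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        p = y[: 2 * n].reshape(n, 2)
        v = y[2 * n :].reshape(n, 2)
        a = -(params.c * v + sysm.forces(p)) / params.m
        v = v.copy()
        v[anchor_rows] = 0.0
        a[anchor_rows] = 0.0
        return np.concatenate([v.ravel(), a.ravel()])

    t = 0.0
    y = np.concatenate([pos.ravel(), vel.ravel()])
    rms_prev = sysm.rms(pos)
    rms_trace = [(0.0, rms_prev)]
    energy_trace = [(0.0, sysm.energy(pos, vel))]
    converged = False
    ok_streak = 0
    while t < params.t_max and not converged:
        t_next = min(t + params.checkpoint_dt, params.t_max)
        sol = solve_ivp(
            rhs, (t, t_next), y, method="RK45", rtol=params.rtol, atol=params.atol
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"integration failed at t={t}: {sol.message}")
        y = sol.y[:, -1]
        t = t_next
        pos = y[: 2 * n].reshape(n, 2)
        vel = y[2 * n :].reshape(n, 2)
        rms_now = sysm.rms(pos)
        rms_trace.append((t, rms_now))
        energy_trace.append((t, sysm.energy(pos, vel)))
        vel_rms = float(np.sqrt(np.mean(np.sum(vel * vel, axis=1))))
        if abs(rms_now - rms_prev) < params.conv_tol and vel_rms < params.vel_tol:
            ok_streak += 1
            if ok_streak >= params.conv_checks:
                converged = True
        else:
            ok_streak = 0
        rms_prev = rms_now
    if not converged:
        log.warning("registration did not converge within t_max=%g", params.t_max)

    return RegistrationState(
        positions={tid: pos[i].copy() for i, tid in enumerate(ids)},
        velocities={tid: vel[i].copy() for i, tid in enumerate(ids)},
        anchor_tile=anchor,
        rms_trace=rms_trace,
        energy_trace=energy_trace,
        converged=converged,
    )


def solve_least_squares(
    tiles,
    pairs: Sequence[OverlapPair],
    weighted: bool = True,
    params: MsdParams | None = None,
    anchor_tile: str | None = None,
) -> dict[str, np.ndarray]:
    """Minimise sum_ij w_ij ||(x_i - x_j) - p_ij||^2 with the anchor fixed.

    Weights are R^n (weighted) or 1 (unweighted).  The objective is
    quadratic, so the sparse normal equations are solved directly; x and y
    decouple and share one factorisation.  A connected component of the
    positive-weight graph that does not contain the anchor makes the system
    singular and is reported as a hard error.
    """
    params = params or MsdParams()
    positions = _positions_of(tiles)
    anchor = anchor_tile or default_anchor(tiles)
    ids = sorted(positions)
    index = {tid: i for i, tid in enumerate(ids)}
    n = len(ids)

    ii, jj, ww, pp = [], [], [], []
    for pr in pairs:
        if pr.tile_i not in index or pr.tile_j not in index:
            raise KeyError(f"pair {pr.key()} references an unknown tile")
        w = float(pr.R) ** params.n if weighted else 1.0
        if w <= 0:
            continue
        ii.append(index[pr.tile_i])
        jj.append(index[pr.tile_j])
        ww.append(w)
        pp.append(np.asarray(pr.p, dtype=float))
    ii = np.asarray(ii, dtype=int)
    jj = np.asarray(jj, dtype=int)
    ww = np.asarray(ww, dtype=float)
    pp = np.asarray(pp, dtype=float).reshape(len(ww), 2)

    labels = _components(n, ii, jj)
    bad = np.unique(labels[labels != labels[index[anchor]]])
    if len(bad):
        members = [ids[i] for i in np.nonzero(labels == bad[0])[0]][:5]
        raise ValueError(
            f"positive-weight overlap graph is disconnected from the anchor: "
            f"component containing {members} has no fixed tile (singular system)"
        )

    free_of_comp = labels == labels[index[anchor]]
    free = np.nonzero(free_of_comp)[0]
    free = free[free != index[anchor]]
    col = -np.ones(n, dtype=int)
    col[free] = np.arange(len(free))

    rows, cols, vals = [], [], []
    b = np.zeros((len(free), 2))
    x0 = np.array([positions[t] for t in ids], dtype=float)
    for a, bb, w, p in zip(ii, jj, ww, pp):
        ca, cb = col[a], col[bb]
        if ca >= 0:
            rows.append(ca)
            cols.append(ca)
            vals.append(w)
            b[ca] += w * p
        if cb >= 0:
            rows.append(cb)
            cols.append(cb)
            vals.append(w)
            b[cb] -= w * p
        if ca >= 0 and cb >= 0:
            rows.extend([ca, cb])
            cols.extend([cb, ca])
            vals.extend([-w, -w])
        elif ca >= 0:  # partner is the anchor
            b[ca] += w * x0[bb]
        elif cb >= 0:
            b[cb] += w * x0[a]

    out = {tid: x0[i].copy() for i, tid in enumerate(ids)}  # anchored/isolated stay put
    if len(free):
        L = sp.csc_matrix((vals, (rows, cols)), shape=(len(free), len(free)))
        solve = spla.factorized(L)
        sol_x = solve(b[:, 0])
        sol_y = solve(b[:, 1])
        for i, f in enumerate(free):
            out[ids[f]] = np.array([sol_x[i], sol_y[i]])
    return out


def registration_report(
    before_positions: Mapping[str, np.ndarray],
    after_positions: Mapping[str, np.ndarray],
    pairs: Sequence[OverlapPair],
) -> dict:
    """Residual statistics before/after registration.

    Returns RMS and mean residual length before and after, the percentage
    RMS reduction, a log-binned histogram of residual lengths, and a
    per-pair table (with overlap midpoints) for spatial mapping.
    """
    r_before, rms_before = residuals(before_positions, pairs)
    r_after, rms_after = residuals(after_positions, pairs)
    len_before = np.linalg.norm(r_before, axis=1) if len(r_before) else np.zeros(0)
    len_after = np.linalg.norm(r_after, axis=1) if len(r_after) else np.zeros(0)
    if rms_before > 0:
        reduction = 100.0 * (1.0 - rms_after / rms_before)
    else:
        reduction = 0.0

    top = max(float(len_before.max(initial=1.0)), float(len_after.max(initial=1.0)), 1.0)
    bins = np.logspace(-1, np.log10(top * 1.001), 25)
    hist_before, _ = np.histogram(len_before, bins=bins)
    hist_after, _ = np.histogram(len_after, bins=bins)

    rows = []
    for pr, lb, la in zip(pairs, len_before, len_after):
        mid = 0.5 * (
            np.asarray(before_positions[pr.tile_i]) + np.asarray(before_positions[pr.tile_j])
        )
        rows.append(
            dict(
                tile_i=pr.tile_i,
                tile_j=pr.tile_j,
                type=pr.overlap_type,
                R=pr.R,
                corrected=pr.corrected,
                mid_x=mid[0],
                mid_y=mid[1],
                r_before=lb,
                r_after=la,
            )
        )
    return dict(
        rms_before=rms_before,
        rms_after=rms_after,
        mean_before=float(len_before.mean()) if len(len_before) else 0.0,
        mean_after=float(len_after.mean()) if len(len_after) else 0.0,
        reduction_pct=float(reduction),
        hist_bins=bins,
        hist_before=hist_before,
        hist_after=hist_after,
        pair_table=pd.DataFrame(rows),
    )
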