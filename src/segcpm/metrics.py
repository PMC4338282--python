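"""Tissue- and cell-level measurements.

Shape: the tissue's principal axes come from the covariance (gyration)
tensor of all non-medium site coordinates; axis lengths are the ranges of
site projections onto the two principal directions (plus one site width), and
the principal angle is measured against the field y-axis.

Motion: centroid tracks sampled every 1000 MCS yield per-cell displacement
vectors (between MCS 5000, after inflation, and the end of the run), mean
cell speeds, and the coherence of neighbouring displacement directions.
Displacement vectors can be corrected for whole-tissue rotation via the
unwrapped principal-angle time series.

Pattern integrity: stray-cell counts and boundary-row mixing quantify how
well cells stay with their designated segment; same-type contact graphs
detect merging of segments; a rank correlation between protein concentration
and axial position quantifies sorting of gradient tissues.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import ContractViolation, UndefinedMeasureError
from .state import WALL, SimState

__all__ = [
    "TissueAxes", "tissue_axes", "tissue_centroid", "displacement_vectors",
    "rotation_correct", "neighbour_angle_coherence", "mean_cell_speed",
    "cell_contact_pairs", "segment_integrity", "detect_segment_merging",
    "equilibrium_contact_length", "predicted_axis_lengths", "sorting_index",
    "unwrap_principal_angle",
]


class TissueAxes(NamedTuple):
    long_axis: float
    short_axis: float
    angle: float  # of the long axis, measured from the field y-axis


def _tissue_coords(state_or_sites) -> tuple[np.ndarray, np.ndarray]:
    sites = state_or_sites.sites if isinstance(state_or_sites, SimState) \
        else np.asarray(state_or_sites)
    ys, xs = np.nonzero(sites > 0)
    if xs.size == 0:
        raise UndefinedMeasureError("empty tissue has no shape")
    return xs.astype(np.float64), ys.astype(np.float64)


def tissue_centroid(state_or_sites) -> tuple[float, float]:
    """(x, y) mean position of all non-medium sites."""
    xs, ys = _tissue_coords(state_or_sites)
    return float(xs.mean()), float(ys.mean())


def tissue_axes(state_or_sites) -> TissueAxes:
    """Principal axis lengths and orientation of the tissue.

    The dominant eigenvector of the site-coordinate covariance matrix gives
    the long-axis direction; lengths are peak-to-peak projections plus one
    site width, so an axis-aligned solid ``60 x 50`` rectangle measures
    exactly 60 by 50.  The angle of the long axis is reported against the
    field y-axis, in ``(-pi/2, pi/2]``.
    """
    xs, ys = _tissue_coords(state_or_sites)
    coords = np.stack([xs, ys], axis=1)
    cov = np.cov(coords.T) if coords.shape[0] > 1 else np.zeros((2, 2))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    minor = np.array([-major[1], major[0]])
    long_axis = float(np.ptp(coords @ major)) + 1.0
    short_axis = float(np.ptp(coords @ minor)) + 1.0
    if short_axis > long_axis:
        long_axis, short_axis = short_axis, long_axis
        major = minor
    # angle with the y-axis, folded into (-pi/2, pi/2]
    angle = math.atan2(major[0], major[1])
    if angle > math.pi / 2:
        angle -= math.pi
    elif angle <= -math.pi / 2:
        angle += math.pi
    return TissueAxes(long_axis, short_axis, angle)


# ---------------------------------------------------------------------------
# track-based measures

def _positions_at(tracks: pd.DataFrame, t: int) -> pd.DataFrame:
    snap = tracks[tracks.mcs == t]
    if snap.empty:
        raise ContractViolation(f"tracks hold no sample at MCS {t}")
    return snap.set_index("sigma")[["x", "y"]]


def displacement_vectors(tracks: pd.DataFrame, t_start: int = 5000,
                         t_end: int | None = None) -> pd.DataFrame:
    """Per-cell displacement between two sampled times.

    Returns a frame indexed by sigma with the start position (``x0``, ``y0``)
    and the vector (``dx``, ``dy``); cells retired before ``t_end`` are
    excluded and counted in ``.attrs['excluded']``.
    """
    if t_end is None:
        t_end = int(tracks.mcs.max())
    start = _positions_at(tracks, t_start)
    end = _positions_at(tracks, t_end)
    common = start.index.intersection(end.index)
    out = pd.DataFrame({
        "x0": start.loc[common, "x"], "y0": start.loc[common, "y"],
        "dx": end.loc[common, "x"] - start.loc[common, "x"],
        "dy": end.loc[common, "y"] - start.loc[common, "y"],
    })
    out.attrs["excluded"] = int(len(start.index.difference(end.index)))
    out.attrs["t_start"], out.attrs["t_end"] = int(t_start), int(t_end)
    return out


def unwrap_principal_angle(angles: np.ndarray) -> np.ndarray:
    """Unwrap a principal-angle time series (period pi, eigenvector sign
    fixed by continuity) into a continuous rotation signal."""
    return np.unwrap(2.0 * np.asarray(angles, dtype=np.float64)) / 2.0


def rotation_correct(vectors: pd.DataFrame,
                     shapes: pd.DataFrame) -> pd.DataFrame:
    """Correct displacement vectors for net whole-tissue rotation.

    The net change of the (unwrapped) principal angle between the vector
    interval's endpoints is rotated out: each end point is rotated by the
    negative net angle about the final tissue centroid, so a pure rigid
    rotation yields zero corrected vectors.
    """
    t0 = vectors.attrs.get("t_start")
    t1 = vectors.attrs.get("t_end")
    window = shapes[(shapes.mcs >= t0) & (shapes.mcs <= t1)]
    if window.empty or window.mcs.iloc[0] > t0 or window.mcs.iloc[-1] < t1:
        raise ContractViolation("shape series does not cover the vector interval")
    theta = unwrap_principal_angle(window.angle.to_numpy())
    dtheta = float(theta[-1] - theta[0])
    cx = float(window.cx.iloc[-1])
    cy = float(window.cy.iloc[-1])
    cos_t, sin_t = math.cos(-dtheta), math.sin(-dtheta)
    ex = vectors.x0 + vectors.dx - cx
    ey = vectors.y0 + vectors.dy - cy
    ex_r = cos_t * ex - sin_t * ey + cx
    ey_r = sin_t * ex + cos_t * ey + cy
    out = vectors.copy()
    out["dx"] = ex_r - vectors.x0
    out["dy"] = ey_r - vectors.y0
    out.attrs = dict(vectors.attrs)
    out.attrs["net_rotation"] = dtheta
    return out


def neighbour_angle_coherence(vectors: pd.DataFrame,
                              radius: float = 30.0) -> np.ndarray:
    """Mean absolute angle (radians, in [0, pi]) between each displacement
    vector and every vector starting within ``radius`` sites of its start
    point.  Vectors without neighbours (or with zero length) get NaN.
    Parallel fields score 0; isotropic random fields score ~pi/2.
    """
    if len(vectors) < 2:
        raise ContractViolation("need at least two displacement vectors")
    starts = vectors[["x0", "y0"]].to_numpy()
    vecs = vectors[["dx", "dy"]].to_numpy()
    norms = np.linalg.norm(vecs, axis=1)
    tree = cKDTree(starts)
    out = np.full(len(vectors), np.nan)
    for i, neigh in enumerate(tree.query_ball_point(starts, r=radius)):
        if norms[i] == 0.0:
            continue
        angles = []
        for j in neigh:
            if j == i or norms[j] == 0.0:
                continue
            cosang = np.dot(vecs[i], vecs[j]) / (norms[i] * norms[j])
            angles.append(math.acos(min(1.0, max(-1.0, cosang))))
        if angles:
            out[i] = float(np.mean(angles))
    return out


def mean_cell_speed(tracks: pd.DataFrame, t_start: int = 5000,
                    t_end: int | None = None) -> float:
    """Mean cell displacement speed in sites/MCS.

    Per cell, the mean over consecutive sampling intervals of
    ``|delta centroid| / delta t`` from ``t_start`` on; then the mean over
    cells — an average both over the variable speed of a cell and between
    cells.
    """
    sel = tracks[tracks.mcs >= t_start]
    if t_end is not None:
        sel = sel[sel.mcs <= t_end]
    if sel.mcs.nunique() < 2:
        raise ContractViolation("need at least two samples past t_start")
    sel = sel.sort_values(["sigma", "mcs"])
    g = sel.groupby("sigma")
    dx = g.x.diff()
    dy = g.y.diff()
    dt = g.mcs.diff()
    speed = np.hypot(dx, dy) / dt
    per_cell = speed.groupby(sel.sigma).mean().dropna()
    return float(per_cell.mean())


# ---------------------------------------------------------------------------
# segment pattern integrity

def cell_contact_pairs(state: SimState) -> np.ndarray:
    """Unordered pairs (sigma_a < sigma_b) of distinct cells sharing at least
    one Moore-8 contact, extracted from the lattice."""
    sites = state.sites
    pairs = []
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        a = sites[max(0, -dy):sites.shape[0] - max(0, dy),
                  max(0, -dx):sites.shape[1] - max(0, dx)]
        b = sites[max(0, dy):sites.shape[0] + min(0, dy) or None,
                  max(0, dx):sites.shape[1] + min(0, dx) or None]
        mask = (a > 0) & (b > 0) & (a != b)
        if mask.any():
            pairs.append(np.stack([np.minimum(a[mask], b[mask]),
                                   np.maximum(a[mask], b[mask])], axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.unique(np.concatenate(pairs, axis=0), axis=0).astype(np.int64)


def _require_segmented(state: SimState) -> None:
    if not np.any(state.segment[state.alive()] >= 0):
        raise UndefinedMeasureError("tissue carries no segment labels")


def segment_integrity(state: SimState) -> tuple[float, int]:
    """(mixing fraction, stray count) of a segmented tissue.

    A *stray* is a live cell with no Moore-adjacent cell of its own segment
    label.  The mixing fraction is the fraction of boundary-row cells (cells
    seeded in a row adjacent to another segment) that touch a same-type cell
    of a different segment.
    """
    _require_segmented(state)
    pairs = cell_contact_pairs(state)
    seg = state.segment
    ct = state.ctype
    alive_idx = np.nonzero(state.alive())[0]
    has_own = {int(s): False for s in alive_idx}
    mixed = {int(s): False for s in alive_idx}
    for a, b in pairs:
        a, b = int(a), int(b)
        if seg[a] == seg[b]:
            has_own[a] = True
            has_own[b] = True
        elif ct[a] == ct[b]:
            mixed[a] = True
            mixed[b] = True
    strays = sum(1 for s in alive_idx if not has_own[int(s)])
    brow = [int(s) for s in alive_idx if state.boundary_row[s]]
    mixing = (sum(1 for s in brow if mixed[s]) / len(brow)) if brow else 0.0
    return float(mixing), int(strays)


def detect_segment_merging(state: SimState) -> tuple[bool, list[tuple[int, int]]]:
    """Detect same-type segments that have fused.

    Builds the cell adjacency graph restricted to same-type contacts and
    reports every pair of distinct segment labels found inside one connected
    component.
    """
    _require_segmented(state)
    alive_idx = np.nonzero(state.alive())[0]
    index = {int(s): i for i, s in enumerate(alive_idx)}
    pairs = cell_contact_pairs(state)
    rows, cols = [], []
    for a, b in pairs:
        if state.ctype[a] == state.ctype[b]:
            rows.append(index[int(a)])
            cols.append(index[int(b)])
    n = len(alive_idx)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    merged: set[tuple[int, int]] = set()
    for comp in np.unique(labels):
        segs = np.unique(state.segment[alive_idx[labels == comp]])
        segs = segs[segs >= 0]
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                merged.add((int(segs[i]), int(segs[j])))
    return bool(merged), sorted(merged)


# ---------------------------------------------------------------------------
# analytic equilibrium shape

def equilibrium_contact_length(n_segments: int, segment_area: float,
                               gamma_rg: float, gamma_cm: float) -> float:
    """Equilibrium intersegment contact length of a stack of ``n`` segments.

    Approximating each segment as an ``L x (A_s / L)`` rectangle, the total
    boundary energy is ``E(L) = (n-1) gamma_rg L + gamma_cm (2L + 2n A_s/L)``
    and its minimiser is

        L* = sqrt(2 gamma_cm n A_s / ((n-1) gamma_rg + 2 gamma_cm)).

    With ``gamma_rg = 0`` this reduces to the square tissue
    ``L* = sqrt(n A_s)``; large ``gamma_rg`` drives ``L*`` toward zero.
    """
    denom = (n_segments - 1) * gamma_rg + 2.0 * gamma_cm
    if denom <= 0 or gamma_cm <= 0 or segment_area <= 0 or n_segments < 1:
        raise UndefinedMeasureError(
            "equilibrium undefined: need positive tensions and areas")
    return math.sqrt(2.0 * gamma_cm * n_segments * segment_area / denom)


def predicted_axis_lengths(n_segments: int, segment_area: float,
                           gamma_rg: float, gamma_cm: float
                           ) -> tuple[float, float]:
    """(long, short) tissue axis lengths predicted by the rectangle
    approximation: width L*, height n A_s / L*."""
    L = equilibrium_contact_length(n_segments, segment_area, gamma_rg, gamma_cm)
    height = n_segments * segment_area / L
    return (max(height, L), min(height, L))


# ---------------------------------------------------------------------------
# gradient-tissue sorting

def sorting_index(state: SimState) -> float:
    """Absolute rank correlation between protein-B concentration and centroid
    position along the tissue's principal axis: 1 for a perfectly sorted
    gradient tissue, ~0 for a mixed one."""
    alive = state.alive()
    conc = state.conc_b[alive]
    if conc.size < 3 or np.any(np.isnan(conc)):
        raise UndefinedMeasureError("sorting index needs >= 3 gradient cells")
    if np.ptp(conc) == 0.0:
        raise UndefinedMeasureError("sorting index undefined: uniform B")
    axes = tissue_axes(state)
    direction = np.array([math.sin(axes.angle), math.cos(axes.angle)])
    cents = state.centroids()[alive]
    proj = cents @ direction
    rho, _ = stats.spearmanr(conc, proj)
    if np.isnan(rho):
        raise UndefinedMeasureError("sorting index undefined on degenerate tissue")
    return float(abs(rho))
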