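"""Discretized membrane curvature from reference points and reference normals.

The estimator meshes the membrane laterally (30 x 30 by default), builds one
reference point per cell as the smoothed mean position of lower-leaflet
phosphate beads within a cutoff radius, and one reference normal per cell as
the unit vector from the local mean tail-carbon position toward the local
mean lower-leaflet phosphate position (pointing outward through the lower
leaflet; (0, 0, -1) for a flat patch).  Adjacent cells i and i+1 along a grid
axis give a curvature angle theta_i between their normals and a reference
distance D_i between their reference points; the local radius of curvature is
R_i = D_i / tan(theta_i) and the curvature C_i = 1/R_i.  Doing this along
both grid axes yields the two principal-direction curvatures C_x and C_y and
the mean curvature C_m = (C_x + C_y) / 2.

Sign convention: positive where the surface bulges toward the upper
(extracellular) side; a bump toward +z has C_m > 0 at its apex.

Closed geometries (cylinders) are analyzed in an unwrapped chart whose axes
align with the azimuthal and axial directions; the chart is estimated from
the data (axis = lower-leaflet centroid, unwrap radius = mean axial
distance), so the grid construction's height-field assumption holds locally.
Distances D_i are 3D Euclidean distances between reference points, which
converge to the true chord on curved surfaces where a lateral projection
would bias 1/R upward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .frames import LOWER, PHOSPHATE, TAIL_CARBON, MembraneFrame
from .pores import GridField, bin_beads

THETA_MIN = 1e-4  # rad; below this the surface is treated as flat (C = 0)
THETA_MAX = 1.0  # rad; larger bends between adjacent cells are unresolvable
Z_OUTLIER = 1.5  # nm; lipids further than this from the local surface are
#                  "out of regular conformation" and excluded


@dataclass
class Chart:
    """Mapping from 3D bead positions to 2D analysis coordinates (u, v)."""

    kind: str  # "planar" | "cylindrical"
    Lu: float
    Lv: float
    periodic_u: bool
    periodic_v: bool
    axis_point: np.ndarray | None = None  # (x0, z0) for cylindrical charts
    radius: float | None = None  # unwrap radius for cylindrical charts

    def to_chart(self, positions: np.ndarray) -> np.ndarray:
        p = np.asarray(positions, dtype=float)
        if self.kind == "planar":
            return p[:, :2].copy()
        dx = p[:, 0] - self.axis_point[0]
        dz = p[:, 2] - self.axis_point[1]
        phi = np.mod(np.arctan2(dz, dx), 2.0 * math.pi)
        return np.column_stack([self.radius * phi, p[:, 1]])

    def delta(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Chart displacement a - b with periodic minimum image where applicable."""
        d = a - b
        if self.periodic_u:
            d[..., 0] -= self.Lu * np.round(d[..., 0] / self.Lu)
        if self.periodic_v:
            d[..., 1] -= self.Lv * np.round(d[..., 1] / self.Lv)
        return d


def planar_chart(frame: MembraneFrame) -> Chart:
    return Chart(
        kind="planar",
        Lu=float(frame.box[0]),
        Lv=float(frame.box[1]),
        periodic_u=True,
        periodic_v=True,
    )


def cylindrical_chart(frame: MembraneFrame) -> Chart:
    """Unwrapped azimuthal x axial chart, estimated from the lower leaflet.

    The cylinder axis is taken along y; its (x, z) location is the centroid of
    the lower-leaflet phosphates and the unwrap radius their mean distance
    from that axis.
    """
    low = frame.phosphates(LOWER)
    if len(low) == 0:
        raise ValueError("no lower-leaflet phosphates to estimate the chart from")
    axis = np.array([low[:, 0].mean(), low[:, 2].mean()])
    r = float(
        np.mean(np.hypot(low[:, 0] - axis[0], low[:, 2] - axis[1]))
    )
    return Chart(
        kind="cylindrical",
        Lu=2.0 * math.pi * r,
        Lv=float(frame.box[1]),
        periodic_u=True,
        periodic_v=True,
        axis_point=axis,
        radius=r,
    )


def chart_for_frame(frame: MembraneFrame) -> Chart:
    if frame.meta.get("geometry") == "cylinder":
        return cylindrical_chart(frame)
    return planar_chart(frame)


@dataclass
class CurvatureField:
    """Per-cell reference points, normals, and curvature components."""

    n_u: int
    n_v: int
    cell_size: tuple[float, float]
    chart: Chart
    ref_points: np.ndarray  # (n_u, n_v, 3)
    ref_normals: np.ndarray  # (n_u, n_v, 3), unit where valid
    valid: np.ndarray  # (n_u, n_v) bool
    C_x: np.ndarray = field(default=None)
    C_y: np.ndarray = field(default=None)
    C_m: np.ndarray = field(default=None)

    def cell_centers(self) -> np.ndarray:
        cu, cv = self.cell_size
        u = cu * (np.arange(self.n_u) + 0.5)
        v = cv * (np.arange(self.n_v) + 0.5)
        U, V = np.meshgrid(u, v, indexing="ij")
        return np.stack([U, V], axis=-1)


def _local_means(
    points: np.ndarray,
    q: np.ndarray,
    centers: np.ndarray,
    chart: Chart,
    radius: float,
    heights: np.ndarray | None = None,
    extra: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Mean 3D position of points within chart-distance ``radius`` of each center.

    With ``heights`` given, points deviating more than Z_OUTLIER from the
    provisional per-cell mean height are excluded in a second pass.  ``extra``
    is an optional per-point payload (e.g. the owning lipid's tail-carbon
    mean) averaged with the identical inclusion mask.
    Returns (means (n_cells, 3), counts (n_cells,), extra_means or None).
    """
    n_cells = len(centers)
    means = np.zeros((n_cells, 3))
    counts = np.zeros(n_cells, dtype=int)
    extra_means = None if extra is None else np.zeros((n_cells, 3))
    chunk = max(1, int(2e7 // max(1, len(points))))
    for s in range(0, n_cells, chunk):
        c = centers[s : s + chunk]
        d = chart.delta(q[None, :, :], c[:, None, :])
        within = (d[..., 0] ** 2 + d[..., 1] ** 2) <= radius**2
        cnt = within.sum(axis=1)
        if heights is not None:
            mh = within @ heights / np.maximum(cnt, 1)
            within = within & (
                np.abs(heights[None, :] - mh[:, None]) <= Z_OUTLIER
            )
            cnt = within.sum(axis=1)
        denom = np.maximum(cnt, 1)[:, None]
        means[s : s + chunk] = within @ points / denom
        counts[s : s + chunk] = cnt
        if extra is not None:
            extra_means[s : s + chunk] = within @ extra / denom
    return means, counts, extra_means


def _heights(positions: np.ndarray, chart: Chart) -> np.ndarray:
    """Out-of-surface coordinate: z for planar charts, axial distance otherwise."""
    if chart.kind == "planar":
        return positions[:, 2].copy()
    return np.hypot(
        positions[:, 0] - chart.axis_point[0],
        positions[:, 2] - chart.axis_point[1],
    )


def _pore_excluded(
    frame: MembraneFrame, sel: np.ndarray, pore: GridField | None
) -> np.ndarray:
    """Mask (over sel's True entries) of beads binned into pore-mask cells."""
    idx = np.nonzero(sel)[0]
    if pore is None or pore.values.dtype != bool:
        return np.zeros(len(idx), dtype=bool)
    i, j = bin_beads(frame.positions[idx, :2], frame.box, pore.n_x)
    return pore.values[i, j]


def reference_points(
    frame: MembraneFrame,
    chart: Chart,
    n: int | tuple[int, int] = 30,
    smoothing_radius: float = 3.0,
    pore: GridField | None = None,
) -> CurvatureField:
    """Per-cell reference points: smoothed lower-leaflet phosphate positions.

    Cells with no phosphate neighbor within ``smoothing_radius`` — and cells
    whose center lies inside the pore mask, when one is given — are flagged
    invalid.  Lipids binned into pore cells or deviating more than 1.5 nm
    from the local reference surface are excluded from the averages.
    """
    if smoothing_radius <= 0:
        raise ValueError("smoothing_radius must be positive")
    n_u, n_v = (n, n) if isinstance(n, int) else n
    sel = (frame.roles == PHOSPHATE) & (frame.leaflets == LOWER)
    if not np.any(sel):
        raise ValueError("no lower-leaflet phosphates in frame")
    excl = _pore_excluded(frame, sel, pore)
    pts = frame.positions[sel][~excl]
    q = chart.to_chart(pts)
    fld = CurvatureField(
        n_u=n_u,
        n_v=n_v,
        cell_size=(chart.Lu / n_u, chart.Lv / n_v),
        chart=chart,
        ref_points=np.zeros((n_u, n_v, 3)),
        ref_normals=np.zeros((n_u, n_v, 3)),
        valid=np.zeros((n_u, n_v), dtype=bool),
    )
    centers = fld.cell_centers().reshape(-1, 2)
    means, counts, _ = _local_means(
        pts, q, centers, chart, smoothing_radius, heights=_heights(pts, chart)
    )
    fld.ref_points = means.reshape(n_u, n_v, 3)
    fld.valid = (counts > 0).reshape(n_u, n_v)
    if pore is not None and pore.values.dtype == bool:
        ci, cj = bin_beads(
            _chart_centers_to_xy(fld, frame), frame.box, pore.n_x
        )
        fld.valid &= ~pore.values[ci, cj].reshape(n_u, n_v)
    return fld


def _chart_centers_to_xy(fld: CurvatureField, frame: MembraneFrame) -> np.ndarray:
    """Lateral (x, y) of cell centers, for pore-mask lookup (planar charts)."""
    centers = fld.cell_centers().reshape(-1, 2)
    if fld.chart.kind == "planar":
        return centers
    # Cylindrical chart: use the reference points' own lateral positions.
    return fld.ref_points.reshape(-1, 3)[:, :2]


def reference_normals(
    frame: MembraneFrame,
    fld: CurvatureField,
    smoothing_radius: float = 3.0,
    pore: GridField | None = None,
) -> CurvatureField:
    """Unit normals from local mean tail position toward local mean phosphate.

    Selection is per lipid: the cell's normal averages the phosphate and the
    tail carbons of the same bottom-leaflet lipids (keyed by the head bead's
    chart position) that define the reference point.  Selecting tail beads by
    their own lateral position instead would be blind to tilt -- on any
    uniformly tilted patch, the disc means of the head and tail layers sit
    vertically above one another -- so the lipid is the unit of selection and
    of exclusion.  The normal points outward from the bilayer midplane
    through the lower leaflet ((0, 0, -1) on a flat patch).  Cells whose
    tail and phosphate means coincide are flagged invalid rather than
    raising.
    """
    chart = fld.chart
    sel = (frame.roles == PHOSPHATE) & (frame.leaflets == LOWER)
    if not np.any(sel):
        raise ValueError("no lower-leaflet phosphates in frame")
    excl = _pore_excluded(frame, sel, pore)
    head_idx = np.nonzero(sel)[0][~excl]
    heads = frame.positions[head_idx]

    tail_sel = (frame.roles == TAIL_CARBON) & (frame.leaflets == LOWER)
    if not np.any(tail_sel):
        raise ValueError("no lower-leaflet tail-carbon beads in frame")
    lipid_tail = np.full((len(head_idx), 3), np.nan)
    if np.all(frame.residue_ids[head_idx] >= 0):
        t_res = frame.residue_ids[tail_sel]
        t_pos = frame.positions[tail_sel]
        order = np.argsort(t_res, kind="stable")
        t_res, t_pos = t_res[order], t_pos[order]
        uniq, start, cnt = np.unique(t_res, return_index=True, return_counts=True)
        sums = np.add.reduceat(t_pos, start, axis=0)
        tmean = {int(r): sums[k] / cnt[k] for k, r in enumerate(uniq)}
        for k, hi in enumerate(head_idx):
            tm = tmean.get(int(frame.residue_ids[hi]))
            if tm is not None:
                lipid_tail[k] = tm
    else:  # residue identity unavailable: nearest tail triplet heuristic
        from scipy.spatial import cKDTree

        t_pos = frame.positions[tail_sel]
        tree = cKDTree(t_pos)
        _, idx = tree.query(heads, k=min(3, len(t_pos)))
        lipid_tail = t_pos[np.atleast_2d(idx)].mean(axis=1)

    ok_lipid = np.all(np.isfinite(lipid_tail), axis=1)
    heads, lipid_tail = heads[ok_lipid], lipid_tail[ok_lipid]
    q = chart.to_chart(heads)
    centers = fld.cell_centers().reshape(-1, 2)
    head_means, counts, tail_means = _local_means(
        heads,
        q,
        centers,
        chart,
        smoothing_radius,
        heights=_heights(heads, chart),
        extra=lipid_tail,
    )
    vec = head_means - tail_means
    norm = np.linalg.norm(vec, axis=1)
    ok = fld.valid.reshape(-1) & (counts > 0) & (norm > 1e-9)
    normals = np.zeros_like(vec)
    normals[ok] = vec[ok] / norm[ok, None]
    fld.ref_normals = normals.reshape(fld.n_u, fld.n_v, 3)
    fld.valid = ok.reshape(fld.n_u, fld.n_v)
    return fld


def _axis_curvature(fld: CurvatureField, axis: int) -> np.ndarray:
    """Curvature along one grid axis via R = D / tan(theta) on neighbor pairs.

    Central differences over (i-1, i+1) with periodic wrap where the chart is
    periodic; one-sided at open edges.  theta below THETA_MIN gives C = 0;
    invalid neighbors give NaN.
    """
    P = fld.ref_points
    N = fld.ref_normals
    V = fld.valid
    periodic = fld.chart.periodic_u if axis == 0 else fld.chart.periodic_v
    n_ax = fld.n_u if axis == 0 else fld.n_v

    def shifted(arr: np.ndarray, k: int) -> np.ndarray:
        return np.roll(arr, -k, axis=axis)

    C = np.full(V.shape, np.nan)
    # Candidate neighbor pairs in preference order: central, then one-sided.
    for da, db in ((-1, +1), (0, +1), (-1, 0)):
        Pa, Pb = shifted(P, da), shifted(P, db)
        Na, Nb = shifted(N, da), shifted(N, db)
        Va, Vb = shifted(V, da), shifted(V, db)
        pair_ok = V & Va & Vb
        if not periodic:
            idx = np.arange(n_ax)
            in_range = (idx + da >= 0) & (idx + db < n_ax)
            shape_mask = in_range[:, None] if axis == 0 else in_range[None, :]
            pair_ok = pair_ok & shape_mask
        todo = pair_ok & np.isnan(C)
        if not np.any(todo):
            continue
        d = Pb - Pa
        D = np.linalg.norm(d, axis=-1)
        cos_t = np.clip(np.sum(Na * Nb, axis=-1), -1.0, 1.0)
        theta = np.arccos(cos_t)
        t_hat = d / np.maximum(D, 1e-12)[..., None]
        sign = -np.sign(np.sum((Nb - Na) * t_hat, axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            mag = np.tan(theta) / D
            val = np.where(theta < THETA_MIN, 0.0, sign * mag)
            val = np.where((theta > THETA_MAX) | (D <= 1e-9), np.nan, val)
        C[todo] = val[todo]
    return C


def principal_curvatures(fld: CurvatureField) -> CurvatureField:
    """Fill C_x, C_y (per grid axis) and C_m = (C_x + C_y)/2 on the field.

    Cells lacking a usable neighbor pair along either axis are invalidated.
    """
    fld.C_x = _axis_curvature(fld, 0)
    fld.C_y = _axis_curvature(fld, 1)
    fld.C_m = (fld.C_x + fld.C_y) / 2.0
    fld.valid = fld.valid & np.isfinite(fld.C_m)
    return fld


def curvature_field(
    frame: MembraneFrame,
    n: int | tuple[int, int] = 30,
    smoothing_radius: float = 3.0,
    chart: Chart | str = "auto",
    pore: GridField | None = None,
) -> CurvatureField:
    """Full pipeline: chart -> reference points -> normals -> curvatures."""
    if chart == "auto":
        chart = chart_for_frame(frame)
    elif chart == "planar":
        chart = planar_chart(frame)
    elif chart == "cylindrical":
        chart = cylindrical_chart(frame)
    fld = reference_points(frame, chart, n, smoothing_radius, pore)
    fld = reference_normals(frame, fld, smoothing_radius, pore)
    return principal_curvatures(fld)


def vertex_curvature(
    fld: CurvatureField,
    np_position: np.ndarray,
    np_radius: float,
    search_factor: float = 1.5,
) -> tuple[tuple[int, int], float]:
    """The vertex cell: maximal C_m within a search disc under the nanoparticle.

    Returns ((i, j), C_m).  Ties are broken by smaller lateral distance to the
    NP axis, then by cell index order.  Raises if no valid cell lies within
    the search disc of radius ``search_factor * np_radius``.
    """
    if fld.C_m is None:
        raise ValueError("curvature field not computed; call principal_curvatures")
    p = np.asarray(np_position, dtype=float).reshape(3)
    q = fld.chart.to_chart(p[None, :])[0]
    centers = fld.cell_centers().reshape(-1, 2)
    d = np.linalg.norm(fld.chart.delta(centers, q[None, :]), axis=1)
    ok = fld.valid.reshape(-1) & (d <= search_factor * np_radius)
    if not np.any(ok):
        raise ValueError("no valid curvature cell within the search disc")
    cm = fld.C_m.reshape(-1)
    idx = np.nonzero(ok)[0]
    # Lexicographic: max C_m, then min distance, then min index.
    order = sorted(idx, key=lambda k: (-cm[k], d[k], k))
    best = order[0]
    return (best // fld.n_v, best % fld.n_v), float(cm[best])


__all__ = [
    "Chart",
    "CurvatureField",
    "planar_chart",
    "cylindrical_chart",
    "chart_for_frame",
    "reference_points",
    "reference_normals",
    "principal_curvatures",
    "curvature_field",
    "vertex_curvature",
    "THETA_MIN",
    "THETA_MAX",
]
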