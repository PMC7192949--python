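"""Four-way classification of nanoparticle translocation outcomes and kinetics.

Each NP-membrane trajectory ends in one of four configurations:

* ``outer_wrap`` — the particle rests on the extracellular face, partially
  wrapped by the membrane, and never crosses;
* ``free_translocate`` — the particle crosses through a transient pore and
  roams freely in the cytosolic region without further membrane contact;
* ``inner_attach`` — the particle mostly crosses but stays tethered to the
  inner leaflet by a small buried fraction;
* ``embedment`` — the particle halts inside the bilayer, exposed to both
  sides like a transmembrane protein.

The decision is made on terminal-window medians of three per-frame geometric
descriptors: the z offset of the NP center from the local bilayer midplane,
the fraction of ligand-terminal beads in contact with lipids, and the
fraction of directions around the NP covered by nearby lipid head groups.
Thresholds are expressed in units of the membrane half-thickness and contact
fraction, so they transfer across membrane models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .frames import (
    LIGAND,
    LOWER,
    NO_LEAFLET,
    NP_CORE,
    UPPER,
    MembraneFrame,
    Trajectory,
    lateral_delta,
)
from .pores import PoreSeries
from .syngen import TranslocationClass


@dataclass
class ClassifierParams:
    """Tunable thresholds of the classifier (lengths nm, times frames)."""

    thickness: float = 4.0  # phosphate-to-phosphate bilayer thickness
    c_attach: float = 0.05  # contact fraction separating inner_attach from free
    contact_cutoff: float = 0.6  # nm, about one CG bead diameter
    wrap_extra: float = 1.0  # nm beyond the NP radius for wrap coverage
    local_radius_factor: float = 1.5  # local-midplane disc, units of NP radius
    terminal_fraction: float = 0.1  # tail of the trajectory used for the verdict
    arrest_eps: float = 0.05  # nm, motion below this over the window = arrest
    arrest_window: int = 25  # frames (10 ns at 0.4 ns/frame)
    n_directions: int = 256  # uniform sphere sampling for wrap_fraction


@dataclass
class TranslocationResult:
    """Per-trajectory verdict plus kinetic summary."""

    label: TranslocationClass
    nucleation_time: float | None
    duration: float | None
    max_pore_area: float
    final_z_offset: float
    final_contact_fraction: float
    wrap_fraction: float
    no_entry: bool = False  # outer_wrap that never even contacted the membrane


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def np_center(frame: MembraneFrame) -> np.ndarray:
    core = frame.positions[frame.roles == NP_CORE]
    if len(core) == 0:
        raise ValueError("frame contains no np_core beads")
    return core.mean(axis=0)


def _local_midplane(
    frame: MembraneFrame, center: np.ndarray, radius: float
) -> float:
    """Mean of the two leaflets' local phosphate surfaces under the NP.

    The sampling disc is widened (doubling) until both leaflets contribute,
    falling back to the global leaflet means — the disc can be empty while a
    pore is open directly beneath the particle.
    """
    z_leaf = {}
    for leaflet in (UPPER, LOWER):
        pts = frame.phosphates(leaflet)
        if len(pts) == 0:
            raise ValueError("frame lacks phosphates in one leaflet")
        d = np.linalg.norm(lateral_delta(pts, center, frame.box), axis=1)
        r = radius
        sel = d <= r
        while not np.any(sel) and r < max(frame.box[:2]):
            r *= 2.0
            sel = d <= r
        z_leaf[leaflet] = float(pts[sel, 2].mean()) if np.any(sel) else float(
            pts[:, 2].mean()
        )
    return 0.5 * (z_leaf[UPPER] + z_leaf[LOWER])


def frame_geometry(
    frame: MembraneFrame,
    params: ClassifierParams,
    directions: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(z_offset, contact_fraction, wrap_fraction) for one frame.

    z_offset: NP core centroid z minus the local bilayer midplane.
    contact_fraction: fraction of ligand-terminal beads within
    ``contact_cutoff`` of any lipid bead.
    wrap_fraction: fraction of uniformly sampled directions around the NP
    centroid whose angularly nearest lipid head lies within NP radius +
    ``wrap_extra``.
    """
    center = np_center(frame)
    lig = frame.positions[frame.roles == LIGAND]
    if len(lig) == 0:
        raise ValueError("frame contains no ligand beads")
    np_radius = float(np.linalg.norm(lig - center, axis=1).max())
    z_off = center[2] - _local_midplane(
        frame, center, params.local_radius_factor * np_radius
    )

    lipid = frame.positions[frame.leaflets != NO_LEAFLET]
    tree = cKDTree(lipid)
    near = tree.query_ball_point(lig, params.contact_cutoff, return_length=True)
    contact = float(np.count_nonzero(near) / len(lig))

    if directions is None:
        directions = _fibonacci_sphere(params.n_directions)
    heads = frame.phosphates()
    rel = heads - center
    dist = np.linalg.norm(rel, axis=1)
    keep = dist > 1e-9
    rel, dist = rel[keep], dist[keep]
    unit = rel / dist[:, None]
    # Assign each direction to its angularly nearest head; covered if that
    # head sits within the wrap shell.
    cos = directions @ unit.T
    nearest = np.argmax(cos, axis=1)
    covered = dist[nearest] <= np_radius + params.wrap_extra
    wrap = float(np.mean(covered))
    return float(z_off), contact, wrap


def np_geometry_series(
    traj: Trajectory, params: ClassifierParams | None = None
) -> np.ndarray:
    """Per-frame (z_offset, contact_fraction, wrap_fraction), shape (n, 3)."""
    params = params or ClassifierParams()
    dirs = _fibonacci_sphere(params.n_directions)
    return np.array(
        [frame_geometry(f, params, dirs) for f in traj.frames]
    )


def classify(
    traj: Trajectory,
    params: ClassifierParams | None = None,
    geometry: np.ndarray | None = None,
    pore: PoreSeries | None = None,
) -> TranslocationResult:
    """Assign one of the four translocation outcomes to a trajectory.

    Terminal-window (final ``terminal_fraction`` of frames) medians decide:
    z_offset above +half-thickness is outer_wrap; |z_offset| within the
    half-thickness is embedment (boundary assigned inward); below, the
    contact fraction separates inner_attach (>= c_attach) from
    free_translocate.  A trajectory that never contacts the membrane is
    outer_wrap with ``no_entry`` set, preserving the four-way taxonomy.
    """
    params = params or ClassifierParams()
    if traj.n_frames < 50:
        raise ValueError("classification needs at least 50 frames")
    geo = np_geometry_series(traj, params) if geometry is None else geometry
    n_term = max(1, int(round(params.terminal_fraction * traj.n_frames)))
    term = geo[-n_term:]
    z_off = float(np.median(term[:, 0]))
    contact = float(np.median(term[:, 1]))
    wrap = float(np.median(term[:, 2]))
    half = params.thickness / 2.0
    if z_off > half:
        label = TranslocationClass.OUTER_WRAP
    elif abs(z_off) <= half:
        label = TranslocationClass.EMBEDMENT
    elif contact >= params.c_attach:
        label = TranslocationClass.INNER_ATTACH
    else:
        label = TranslocationClass.FREE_TRANSLOCATE
    no_entry = label is TranslocationClass.OUTER_WRAP and float(
        geo[:, 1].max()
    ) == 0.0

    nucleation = pore.nucleation_time if pore is not None else None
    max_area = float(np.max(pore.area)) if pore is not None else 0.0
    duration = None
    if pore is not None:
        nucleation, duration = kinetics(traj, pore, label, params, geometry=geo)
    return TranslocationResult(
        label=label,
        nucleation_time=nucleation,
        duration=duration,
        max_pore_area=max_area,
        final_z_offset=z_off,
        final_contact_fraction=contact,
        wrap_fraction=wrap,
        no_entry=no_entry,
    )


def kinetics(
    traj: Trajectory,
    pore: PoreSeries,
    label: TranslocationClass,
    params: ClassifierParams | None = None,
    geometry: np.ndarray | None = None,
) -> tuple[float | None, float | None]:
    """(nucleation_time, duration) for a classified trajectory.

    Duration runs from membrane entry (first frame with z_offset below
    +half-thickness) to exit (z_offset below -half-thickness) for
    free_translocate, or to motion arrest (z_offset range below
    ``arrest_eps`` over ``arrest_window`` frames) for inner_attach and
    embedment; outer_wrap has no duration.
    """
    params = params or ClassifierParams()
    label = TranslocationClass(label)
    if label is TranslocationClass.OUTER_WRAP:
        return pore.nucleation_time, None
    geo = np_geometry_series(traj, params) if geometry is None else geometry
    z = geo[:, 0]
    half = params.thickness / 2.0
    inside = z < half
    if not inside.any():
        return pore.nucleation_time, None
    f_entry = int(np.argmax(inside))
    end: int | None = None
    if label is TranslocationClass.FREE_TRANSLOCATE:
        out = z < -half
        out[:f_entry] = False
        end = int(np.argmax(out)) if out.any() else None
    else:
        w = params.arrest_window
        for a in range(f_entry, len(z) - w + 1):
            win = z[a : a + w]
            if win.max() - win.min() < params.arrest_eps:
                end = a
                break
    if end is None:
        return pore.nucleation_time, None
    duration = float(traj.times[end] - traj.times[f_entry])
    return pore.nucleation_time, duration


__all__ = [
    "ClassifierParams",
    "TranslocationResult",
    "np_geometry_series",
    "frame_geometry",
    "classify",
    "kinetics",
    "np_center",
]
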