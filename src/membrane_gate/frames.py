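"""Core in-memory containers for bead-resolution membrane snapshots.

All coordinates are in nm, all times in ns.  A :class:`MembraneFrame` holds a
single snapshot of typed beads; a :class:`Trajectory` is an ordered sequence of
frames with strictly increasing times.  Bead typing follows the coarse-grained
roles the analyses care about: the phosphate head-group bead marks the membrane
surface, tail-carbon beads mark the hydrophobic interior, ligand and core beads
belong to a monolayer-protected nanoparticle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

# Bead roles (stored as small ints for compactness).
PHOSPHATE = 0
TAIL_CARBON = 1
LIGAND = 2
NP_CORE = 3
OTHER = 4

ROLE_NAMES = {
    PHOSPHATE: "phosphate",
    TAIL_CARBON: "tail_carbon",
    LIGAND: "ligand",
    NP_CORE: "np_core",
    OTHER: "other",
}
ROLE_CODES = {v: k for k, v in ROLE_NAMES.items()}

# Leaflet labels: +1 upper (extracellular-facing), -1 lower (cytosolic-facing),
# 0 for beads that belong to neither leaflet (nanoparticle, solvent).
UPPER = 1
LOWER = -1
NO_LEAFLET = 0


@dataclass
class MembraneFrame:
    """One snapshot: typed bead coordinates, leaflet labels, box dimensions.

    Parameters
    ----------
    positions : (N, 3) float array, nm
    roles : (N,) int array of bead roles (PHOSPHATE, TAIL_CARBON, ...)
    leaflets : (N,) int array (+1 upper, -1 lower, 0 none)
    residue_ids : (N,) int array; beads of one lipid share a residue id
    box : (3,) float array, nm, orthorhombic box with origin at (0, 0, 0)
    meta : free-form metadata (geometry of origin, chart hints, ground truth)
    """

    positions: np.ndarray
    roles: np.ndarray
    leaflets: np.ndarray
    residue_ids: np.ndarray
    box: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.roles = np.asarray(self.roles, dtype=np.int8).reshape(n)
        self.leaflets = np.asarray(self.leaflets, dtype=np.int8).reshape(n)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64).reshape(n)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead position")
        if np.any(self.box <= 0):
            raise ValueError(f"non-positive box edge: {self.box}")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def select(self, mask: np.ndarray) -> "MembraneFrame":
        """Return a new frame keeping only beads where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return MembraneFrame(
            positions=self.positions[mask].copy(),
            roles=self.roles[mask].copy(),
            leaflets=self.leaflets[mask].copy(),
            residue_ids=self.residue_ids[mask].copy(),
            box=self.box.copy(),
            meta=dict(self.meta),
        )

    def phosphates(self, leaflet: int | None = None) -> np.ndarray:
        """Positions of phosphate beads, optionally restricted to one leaflet."""
        m = self.roles == PHOSPHATE
        if leaflet is not None:
            m &= self.leaflets == leaflet
        return self.positions[m]

    def copy(self) -> "MembraneFrame":
        return self.select(np.ones(self.n_beads, dtype=bool))


@dataclass
class Trajectory:
    """Ordered frames with strictly increasing times (ns).

    Bead counts may decrease between frames when lipids are removed by pore
    punching; the box topology is shared.
    """

    frames: list[MembraneFrame]
    times: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_interval(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[1] - self.times[0])


def lateral_delta(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image lateral (x, y) displacement a - b under periodic wrapping."""
    d = np.asarray(a)[..., :2] - np.asarray(b)[..., :2]
    L = np.asarray(box)[:2]
    return d - L * np.round(d / L)


def assign_leaflets(frame: MembraneFrame) -> MembraneFrame:
    """Label lipid beads upper/lower by their lipid's phosphate z vs the median.

    Suitable for flat or gently deformed patches read from files that carry no
    leaflet information (GRO, XYZ written by other tools).
    """
    out = frame.copy()
    phos = frame.roles == PHOSPHATE
    if not np.any(phos):
        return out
    mid = float(np.median(frame.positions[phos, 2]))
    lipid_roles = (frame.roles == PHOSPHATE) | (frame.roles == TAIL_CARBON)
    # Map residue -> its phosphate z.
    phos_res = frame.residue_ids[phos]
    phos_z = frame.positions[phos, 2]
    z_of = dict(zip(phos_res.tolist(), phos_z.tolist()))
    lab = np.zeros(frame.n_beads, dtype=np.int8)
    for i in np.nonzero(lipid_roles)[0]:
        z = z_of.get(int(frame.residue_ids[i]))
        if z is not None:
            lab[i] = UPPER if z >= mid else LOWER
    out.leaflets = lab
    return out


__all__ = [
    "MembraneFrame",
    "Trajectory",
    "PHOSPHATE",
    "TAIL_CARBON",
    "LIGAND",
    "NP_CORE",
    "OTHER",
    "UPPER",
    "LOWER",
    "NO_LEAFLET",
    "ROLE_NAMES",
    "ROLE_CODES",
    "lateral_delta",
    "assign_leaflets",
]
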