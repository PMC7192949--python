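"""Synthetic bead-resolution membranes, NP trajectories, and umbrella samples.

Everything here carries analytically known ground truth so the analysis
modules can be validated without molecular-dynamics output.  The emulated
system is a coarse-grained DPPC-like bilayer: each lipid is one phosphate
head bead plus three tail-carbon beads at 0.5 nm spacing along the local
inward normal.  Geometries: flat patches, Gaussian bumps/dimples, full
cylinders (axis along y), and spherical caps.  For curved geometries the
nominal radius is the radius of the lower-leaflet phosphate surface, i.e.
the surface whose curvature the estimator measures, so the ground-truth
curvature is exactly 1/R.

Nanoparticle trajectories are scripted: a monolayer-protected NP (core bead
plus a shell of ligand-terminal beads) follows a piecewise-linear z path
specific to each of the four translocation outcomes, with a transient pore
(lipids removed, later restored) inserted at the scripted nucleation time
for the pore-forming outcomes.  Umbrella datasets are drawn from the exact
Boltzmann density of a prescribed truth PMF plus harmonic bias by
inverse-CDF sampling.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any

import numpy as np

from .energetics import PMFProfile, UmbrellaDataset, Window, KB
from .frames import (
    LIGAND,
    LOWER,
    NO_LEAFLET,
    NP_CORE,
    OTHER,
    PHOSPHATE,
    TAIL_CARBON,
    UPPER,
    MembraneFrame,
    Trajectory,
    lateral_delta,
)

TAIL_OFFSETS = np.array([0.5, 1.0, 1.5])  # nm along the inward normal
DEFAULT_THICKNESS = 4.0  # nm, phosphate-to-phosphate
DEFAULT_NOISE_SD = 0.1  # nm, isotropic thermal roughness


class Geometry(str, Enum):
    FLAT = "flat"
    BUMP = "bump"
    CYLINDER = "cylinder"
    SPHERE = "sphere"


class TranslocationClass(str, Enum):
    OUTER_WRAP = "outer_wrap"
    FREE_TRANSLOCATE = "free_translocate"
    INNER_ATTACH = "inner_attach"
    EMBEDMENT = "embedment"


class ChargeScheme(str, Enum):
    CONST = "Const"
    HALF = "Half"
    D025 = "0.25D"
    D05 = "0.5D"
    D086 = "0.86D"
    D2 = "D2"


class LigandChemistry(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    HYDROPHILIC = "hydrophilic"


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic membrane."""

    geometry: Geometry = Geometry.FLAT
    lateral_extent: float = 12.0  # nm (axial length for cylinders)
    lipid_spacing: float = 0.8  # nm between head beads on the surface lattice
    bilayer_thickness: float = DEFAULT_THICKNESS
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    geometry_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lateral_extent <= 0:
            raise ValueError("lateral_extent must be positive")
        if self.lipid_spacing <= 0:
            raise ValueError("lipid_spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        g = Geometry(self.geometry)
        object.__setattr__(self, "geometry", g)
        if g in (Geometry.CYLINDER, Geometry.SPHERE):
            r = self.geometry_params.get("radius")
            if r is None:
                raise ValueError(f"{g.value} geometry needs geometry_params['radius']")
            if r < self.bilayer_thickness / 2:
                raise ValueError(
                    f"radius {r} nm smaller than half the bilayer thickness"
                )


# Reference ionization: a 2-nm core carries 99 e at full coating.
REFERENCE_CHARGE = 99
REFERENCE_DIAMETER = 2.0
DEFAULT_CORE_DIAMETERS = (4.0, 6.0, 8.0)  # nm, non-reference sizes of the grid


@dataclass(frozen=True)
class NPDesign:
    """One nanoparticle design point: core size, charge scaling, chemistry."""

    core_diameter: float
    charge_scheme: ChargeScheme
    ligand_chemistry: LigandChemistry
    ionized_count: int

    def __post_init__(self) -> None:
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be positive")
        if self.ionized_count < 0:
            raise ValueError("ionized_count must be non-negative")
        object.__setattr__(self, "charge_scheme", ChargeScheme(self.charge_scheme))
        object.__setattr__(
            self, "ligand_chemistry", LigandChemistry(self.ligand_chemistry)
        )


def _scheme_charge(scheme: ChargeScheme, diameter: float) -> int:
    """Ionized-terminal count under a charge-size scaling scheme.

    Anchored to the 2-nm / 99 e reference; the D-proportional schemes scale
    linearly in diameter with the named prefactor, D2 quadratically.
    """
    ratio = diameter / REFERENCE_DIAMETER
    factors = {
        ChargeScheme.CONST: 1.0,
        ChargeScheme.HALF: 0.5,
        ChargeScheme.D025: 0.25 * ratio,
        ChargeScheme.D05: 0.5 * ratio,
        ChargeScheme.D086: 0.86 * ratio,
        ChargeScheme.D2: ratio**2,
    }
    return int(round(REFERENCE_CHARGE * factors[ChargeScheme(scheme)]))


def enumerate_design_grid(
    core_diameters: tuple[float, ...] = DEFAULT_CORE_DIAMETERS,
) -> list[NPDesign]:
    """The full default study grid: 6 charge schemes x 3 core sizes x 2 chemistries."""
    grid = []
    for scheme in ChargeScheme:
        for d in core_diameters:
            for chem in LigandChemistry:
                grid.append(
                    NPDesign(
                        core_diameter=d,
                        charge_scheme=scheme,
                        ligand_chemistry=chem,
                        ionized_count=_scheme_charge(scheme, d),
                    )
                )
    return grid


@dataclass
class TrajectoryLabel:
    """Ground-truth annotation of one scripted NP trajectory."""

    true_class: TranslocationClass
    true_nucleation_time: float | None = None  # ns
    true_duration: float | None = None  # ns
    true_pore_radius: float | None = None  # nm

    def __post_init__(self) -> None:
        self.true_class = TranslocationClass(self.true_class)
        if self.true_class is TranslocationClass.OUTER_WRAP:
            if any(
                v is not None
                for v in (
                    self.true_nucleation_time,
                    self.true_duration,
                    self.true_pore_radius,
                )
            ):
                raise ValueError("outer_wrap trajectories carry no pore ground truth")


# ---------------------------------------------------------------------------
# Surface lattices
# ---------------------------------------------------------------------------


def _flat_lattice(extent: float, spacing: float) -> np.ndarray:
    n = int(math.floor(extent / spacing))
    if n < 1:
        raise ValueError(
            f"lipid_spacing {spacing} nm exceeds lateral_extent {extent} nm: "
            "membrane would be empty"
        )
    off = (extent - n * spacing) / 2.0 + spacing / 2.0
    u = off + spacing * np.arange(n)
    X, Y = np.meshgrid(u, u, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel()])


def _fibonacci_cap(n: int, cos_min: float) -> np.ndarray:
    """n near-uniform unit vectors on the spherical cap z/|r| >= cos_min."""
    i = np.arange(n) + 0.5
    z = 1.0 - (1.0 - cos_min) * i / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _leaflet_surface(
    spec: SynthSpec, leaflet: int
) -> tuple[np.ndarray, np.ndarray, dict[str, Any]]:
    """Head positions and unit up-normals for one leaflet of the geometry.

    "Up" points from the lower leaflet toward the upper leaflet (outward for
    closed geometries); tails are placed at head + d*up for the lower leaflet
    and head - d*up for the upper.
    """
    t = spec.bilayer_thickness
    ext = spec.lateral_extent
    sp = spec.lipid_spacing
    gp = spec.geometry_params
    geom = Geometry(spec.geometry)

    if geom in (Geometry.FLAT, Geometry.BUMP):
        amp = float(gp.get("amplitude", 2.0)) if geom is Geometry.BUMP else 0.0
        width = float(gp.get("width", 4.0))
        box_z = float(gp.get("box_z", t + 12.0 + 2 * abs(amp)))
        z_mid = box_z / 2.0
        xy = _flat_lattice(ext, sp)
        r2 = np.sum((xy - ext / 2.0) ** 2, axis=1)
        h = amp * np.exp(-r2 / (2.0 * width**2)) if amp != 0.0 else np.zeros(len(xy))
        z = z_mid + (t / 2.0 if leaflet == UPPER else -t / 2.0) + h
        heads = np.column_stack([xy, z])
        if amp != 0.0:
            dx = -(xy[:, 0] - ext / 2.0) / width**2 * h
            dy = -(xy[:, 1] - ext / 2.0) / width**2 * h
            up = np.column_stack([-dx, -dy, np.ones(len(xy))])
            up /= np.linalg.norm(up, axis=1, keepdims=True)
        else:
            up = np.tile([0.0, 0.0, 1.0], (len(xy), 1))
        meta = {
            "geometry": geom.value,
            "z_mid": z_mid,
            "box": np.array([ext, ext, box_z]),
            "bump_amplitude": amp,
            "bump_width": width,
        }
        return heads, up, meta

    if geom is Geometry.CYLINDER:
        R_low = float(gp["radius"])
        R = R_low if leaflet == LOWER else R_low + t
        pad = 2.0
        box_xz = 2.0 * (R_low + t + pad)
        cx = cz = box_xz / 2.0
        n_phi = max(3, int(math.floor(2.0 * math.pi * R / sp)))
        n_y = int(math.floor(ext / sp))
        if n_y < 1:
            raise ValueError("lipid_spacing exceeds the cylinder length")
        phi = 2.0 * math.pi * np.arange(n_phi) / n_phi
        y = (ext - n_y * sp) / 2.0 + sp * (np.arange(n_y) + 0.5)
        PHI, Y = np.meshgrid(phi, y, indexing="ij")
        radial = np.column_stack(
            [np.cos(PHI.ravel()), np.zeros(PHI.size), np.sin(PHI.ravel())]
        )
        heads = radial * R
        heads[:, 0] += cx
        heads[:, 2] += cz
        heads[:, 1] = Y.ravel()
        meta = {
            "geometry": geom.value,
            "axis_point": np.array([cx, cz]),
            "radius_lower": R_low,
            "box": np.array([box_xz, ext, box_xz]),
        }
        return heads, radial, meta

    # Spherical cap bulging toward +z; lower leaflet on the inner radius.
    R_low = float(gp["radius"])
    cap_deg = float(gp.get("cap_angle_deg", 60.0))
    cos_min = math.cos(math.radians(cap_deg))
    R = R_low if leaflet == LOWER else R_low + t
    pad = 2.0
    lateral = 2.0 * (R_low + t) * math.sin(math.radians(cap_deg)) + 2 * pad
    box_z = (R_low + t) * (1.0 - cos_min) + t + 2 * pad
    cx = cy = lateral / 2.0
    cap_area = 2.0 * math.pi * R**2 * (1.0 - cos_min)
    n = max(8, int(round(cap_area / sp**2)))
    radial = _fibonacci_cap(n, cos_min)
    # Shared sphere center: lower-leaflet base ring sits pad above z = 0.
    cz = pad - R_low * cos_min
    heads = radial * R + np.array([cx, cy, cz])
    meta = {
        "geometry": geom.value,
        "radius_lower": R_low,
        "cap_angle_deg": cap_deg,
        "center": np.array([cx, cy, cz]),
        "box": np.array([lateral, lateral, box_z]),
    }
    return heads, radial, meta


def generate_membrane(spec: SynthSpec) -> MembraneFrame:
    """Build a two-leaflet bead membrane on the spec's analytic surface.

    Each lipid is a phosphate head on the surface (plus Gaussian noise of sd
    ``noise_sd`` on every bead) and three tail beads along the local inward
    normal.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positions, roles, leaflets, resids = [], [], [], []
    meta: dict[str, Any] = {}
    rid = 0
    for leaflet in (UPPER, LOWER):
        heads, up, meta = _leaflet_surface(spec, leaflet)
        inward = -up if leaflet == UPPER else up
        for k, (h, d) in enumerate(zip(heads, inward)):
            beads = np.vstack([h, h + np.outer(TAIL_OFFSETS, d)])
            positions.append(beads)
            roles.extend([PHOSPHATE] + [TAIL_CARBON] * len(TAIL_OFFSETS))
            leaflets.extend([leaflet] * (1 + len(TAIL_OFFSETS)))
            resids.extend([rid + k] * (1 + len(TAIL_OFFSETS)))
        rid += len(heads)
    pos = np.vstack(positions)
    if spec.noise_sd > 0:
        pos = pos + rng.normal(0.0, spec.noise_sd, pos.shape)
    box = meta.pop("box")
    meta["spec"] = spec
    meta["thickness"] = spec.bilayer_thickness
    return MembraneFrame(
        positions=pos,
        roles=np.array(roles),
        leaflets=np.array(leaflets),
        residue_ids=np.array(resids),
        box=box,
        meta=meta,
    )


def punch_pore(
    frame: MembraneFrame, center: tuple[float, float], radius: float
) -> MembraneFrame:
    """Remove every lipid whose head lies laterally within ``radius`` of ``center``.

    Surviving beads are untouched; the removed-lipid count is recorded in
    ``meta['removed_lipids']``.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    c = np.asarray(center, dtype=float)
    if np.any(c < 0) or np.any(c >= frame.box[:2]):
        raise ValueError(f"pore center {center} outside the box {frame.box[:2]}")
    if radius > min(frame.box[:2]) / 2.0:
        raise ValueError(
            f"pore radius {radius} nm exceeds half the smallest lateral box edge"
        )
    out = frame.copy()
    if radius == 0:
        out.meta["removed_lipids"] = 0
        return out
    phos = (frame.roles == PHOSPHATE) & (frame.leaflets != NO_LEAFLET)
    d = np.linalg.norm(
        lateral_delta(frame.positions[phos], c, frame.box), axis=1
    )
    hit_res = set(frame.residue_ids[phos][d < radius].tolist())
    keep = np.array(
        [
            not (lf != NO_LEAFLET and int(r) in hit_res)
            for r, lf in zip(frame.residue_ids, frame.leaflets)
        ],
        dtype=bool,
    )
    out = out.select(keep)
    out.meta["removed_lipids"] = len(hit_res)
    return out


# ---------------------------------------------------------------------------
# Nanoparticle trajectories
# ---------------------------------------------------------------------------

LIGAND_SHELL_OFFSET = 0.5  # nm from core surface to ligand-terminal shell
LIGAND_DENSITY = 3.0  # terminals per nm^2 of core surface
DESCENT_SPEED = 0.08  # nm per frame, constant across designs
DEFAULT_FRAME_INTERVAL = 0.4  # ns, the production-trajectory frame spacing
DIMPLE_AMP = 0.5  # nm, membrane indentation under a resting wrapped NP


def _np_beads(design: NPDesign) -> np.ndarray:
    """Core bead at the origin plus a ligand-terminal shell (unit positions)."""
    r_core = design.core_diameter / 2.0
    n_lig = max(16, int(round(LIGAND_DENSITY * 4.0 * math.pi * r_core**2)))
    shell = _fibonacci_cap(n_lig, -1.0)  # full sphere
    return np.vstack([[0.0, 0.0, 0.0], shell * (r_core + LIGAND_SHELL_OFFSET)])


def np_shell_radius(design: NPDesign) -> float:
    return design.core_diameter / 2.0 + LIGAND_SHELL_OFFSET


def _scripted_z_path(
    cls: TranslocationClass,
    n_frames: int,
    z_mid: float,
    t: float,
    r_sh: float,
    v_cross: float = DESCENT_SPEED,
) -> tuple[np.ndarray, dict[str, int | None]]:
    """Piecewise-linear NP-center z path plus the schedule's knot frames."""
    z_hi = z_mid + t / 2.0 + r_sh + 3.0
    z_rest = z_mid + t / 2.0 + r_sh
    if cls is TranslocationClass.OUTER_WRAP:
        z_rest -= DIMPLE_AMP  # the particle settles into its own dimple
    finals = {
        TranslocationClass.OUTER_WRAP: z_rest,
        TranslocationClass.EMBEDMENT: z_mid,
        TranslocationClass.INNER_ATTACH: z_mid - t / 2.0 - r_sh + 0.7,
        TranslocationClass.FREE_TRANSLOCATE: z_mid - t / 2.0 - r_sh - 3.0,
    }
    z_final = finals[cls]
    v = DESCENT_SPEED
    f_touch = int(math.ceil((z_hi - z_rest) / v))
    f_nuc = f_touch + max(5, int(round(0.1 * n_frames)))
    if cls is TranslocationClass.OUTER_WRAP:
        f_settle = f_touch
        f_nuc_out: int | None = None
    else:
        # Snap the crossing to an integer frame count with uniform per-frame
        # steps, so the path reaches its final value exactly at f_settle and
        # every pre-arrest step exceeds the arrest epsilon.
        f_cross = max(1, int(math.ceil((z_rest - z_final) / v_cross)))
        f_settle = f_nuc + f_cross
        f_nuc_out = f_nuc
    if f_settle + max(5, int(round(0.1 * n_frames))) > n_frames:
        raise ValueError(
            f"n_frames={n_frames} too short for the scripted {cls.value} path "
            f"(needs > {f_settle + max(5, int(round(0.1 * n_frames)))} frames); "
            "increase n_frames or reduce the core size"
        )
    f = np.arange(n_frames, dtype=float)
    z = np.full(n_frames, z_final)
    z[: f_touch + 1] = np.maximum(z_rest, z_hi - v * f[: f_touch + 1])
    z[f_touch : f_nuc + 1] = z_rest
    if cls is not TranslocationClass.OUTER_WRAP:
        v_eff = (z_rest - z_final) / (f_settle - f_nuc)
        seg = (f >= f_nuc) & (f <= f_settle)
        z[seg] = z_rest - v_eff * (f[seg] - f_nuc)
        z[f_settle:] = z_final
    else:
        z[f_touch:] = z_rest
    knots = {"f_touch": f_touch, "f_nuc": f_nuc_out, "f_settle": f_settle}
    return z, knots


def generate_np_trajectory(
    label: TrajectoryLabel,
    design: NPDesign,
    spec: SynthSpec,
    n_frames: int = 250,
    seed: int = 0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> Trajectory:
    """Script an NP-membrane trajectory of the labelled translocation class.

    The membrane is a flat patch (curved specs are rejected); the NP follows
    the class-specific z path at constant descent speed, a transient pore is
    punched at the scripted nucleation time for the pore-forming classes, and
    every bead receives fresh Gaussian noise of sd ``spec.noise_sd`` each
    frame.  Ground truth (class, nucleation time, entry/exit/arrest times,
    duration, pore radius) is computed from the noise-free scripted path and
    stored in ``Trajectory.meta['truth']`` and in the returned frames' label.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    if Geometry(spec.geometry) is not Geometry.FLAT:
        raise ValueError("NP trajectory scripting requires a flat membrane spec")
    cls = TranslocationClass(label.true_class)
    t = spec.bilayer_thickness
    r_sh = np_shell_radius(design)
    pore_r = (
        label.true_pore_radius
        if label.true_pore_radius is not None
        else (r_sh + 0.5 if cls is not TranslocationClass.OUTER_WRAP else None)
    )
    # Make sure the box is tall enough for the full scripted path.
    box_z = t + 2.0 * (r_sh + 4.5)
    base_spec = replace(
        spec,
        noise_sd=0.0,
        geometry_params={**spec.geometry_params, "box_z": box_z},
    )
    base = generate_membrane(base_spec)
    z_mid = base.meta["z_mid"]
    # Pore transit slows with particle size (drag-like), reproducing the
    # observed growth of translocation duration with core diameter; floored
    # so every pre-arrest step stays above the arrest-detection epsilon.
    v_cross = max(
        0.06, DESCENT_SPEED * REFERENCE_DIAMETER / design.core_diameter
    )
    z_path, knots = _scripted_z_path(cls, n_frames, z_mid, t, r_sh, v_cross)
    f_nuc = knots["f_nuc"]
    f_settle = knots["f_settle"]
    f_touch = knots["f_touch"]

    # Reseal: after the NP has fully passed (free/inner), 10 frames past arrest;
    # embedment keeps the pore occupied by the particle until the end.
    if cls in (TranslocationClass.FREE_TRANSLOCATE, TranslocationClass.INNER_ATTACH):
        f_reseal: int | None = min(n_frames - 1, f_settle + 10)
    elif cls is TranslocationClass.EMBEDMENT:
        f_reseal = None
    else:
        f_reseal = None

    center_xy = base.box[:2] / 2.0
    np_unit = _np_beads(design)
    n_np = len(np_unit)

    # Lipid removal set, fixed over the open interval (from the noise-free lattice).
    if f_nuc is not None and pore_r is not None:
        phos = (base.roles == PHOSPHATE) & (base.leaflets != NO_LEAFLET)
        d = np.linalg.norm(
            lateral_delta(base.positions[phos], center_xy, base.box), axis=1
        )
        hit = set(base.residue_ids[phos][d < pore_r].tolist())
        lipid_hit = np.array(
            [int(r) in hit for r in base.residue_ids], dtype=bool
        )
    else:
        lipid_hit = np.zeros(base.n_beads, dtype=bool)

    # Ground truth from the scripted path and the analysis thresholds.
    offset = z_path - z_mid
    below_entry = offset < t / 2.0
    f_entry = int(np.argmax(below_entry)) if below_entry.any() else None
    truth: dict[str, Any] = {
        "class": cls.value,
        "nucleation_time": None if f_nuc is None else f_nuc * frame_interval,
        "reseal_time": None if f_reseal is None else f_reseal * frame_interval,
        "pore_radius": pore_r,
        "entry_time": None if f_entry is None else f_entry * frame_interval,
        "settle_time": f_settle * frame_interval,
        "duration": None,
        "z_mid": z_mid,
        "knots": knots,
    }
    if cls is TranslocationClass.FREE_TRANSLOCATE:
        below_exit = offset < -t / 2.0
        f_exit = int(np.argmax(below_exit))
        truth["exit_time"] = f_exit * frame_interval
        truth["duration"] = (f_exit - f_entry) * frame_interval
    elif cls in (TranslocationClass.INNER_ATTACH, TranslocationClass.EMBEDMENT):
        truth["duration"] = (f_settle - f_entry) * frame_interval

    rng = np.random.default_rng(seed)
    frames = []
    phos_all = base.roles == PHOSPHATE
    head_d = np.linalg.norm(
        lateral_delta(base.positions[phos_all], center_xy, base.box), axis=1
    )
    head_res = base.residue_ids[phos_all]
    dimple_by_res = dict(
        zip(
            head_res.tolist(),
            (DIMPLE_AMP * np.exp(-(head_d**2) / (2.0 * (r_sh + 0.5) ** 2))).tolist(),
        )
    )
    dimple_per_bead = np.array(
        [dimple_by_res.get(int(r), 0.0) for r in base.residue_ids]
    )
    for f in range(n_frames):
        pos = base.positions.copy()
        if cls is TranslocationClass.OUTER_WRAP and f >= f_touch:
            pos[:, 2] -= dimple_per_bead
        open_pore = (
            f_nuc is not None
            and f >= f_nuc
            and (f_reseal is None or f < f_reseal)
        )
        keep = ~lipid_hit if open_pore else np.ones(base.n_beads, dtype=bool)
        lipid_pos = pos[keep]
        np_pos = np_unit + np.array([center_xy[0], center_xy[1], z_path[f]])
        all_pos = np.vstack([lipid_pos, np_pos])
        if spec.noise_sd > 0:
            all_pos = all_pos + rng.normal(0.0, spec.noise_sd, all_pos.shape)
        frame = MembraneFrame(
            positions=all_pos,
            roles=np.concatenate(
                [base.roles[keep], [NP_CORE], [LIGAND] * (n_np - 1)]
            ),
            leaflets=np.concatenate(
                [base.leaflets[keep], [NO_LEAFLET] * n_np]
            ),
            residue_ids=np.concatenate(
                [
                    base.residue_ids[keep],
                    np.full(n_np, base.residue_ids.max() + 1),
                ]
            ),
            box=base.box.copy(),
            meta={"z_mid": z_mid, "thickness": t, "frame": f},
        )
        frames.append(frame)

    filled = TrajectoryLabel(
        true_class=cls,
        true_nucleation_time=truth["nucleation_time"],
        true_duration=truth["duration"],
        true_pore_radius=pore_r,
    ) if cls is not TranslocationClass.OUTER_WRAP else TrajectoryLabel(cls)
    return Trajectory(
        frames=frames,
        times=frame_interval * np.arange(n_frames),
        meta={
            "truth": truth,
            "label": filled,
            "design": design,
            "spec": spec,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Umbrella sampling
# ---------------------------------------------------------------------------


def generate_umbrella_samples(
    pmf_truth: PMFProfile,
    window_spacing: float = 0.1,
    spring_k: float = 5000.0,
    n_per_window: int = 10_000,
    temperature: float = 305.0,
    seed: int = 0,
) -> UmbrellaDataset:
    """Draw exact Boltzmann samples from G(x) + harmonic bias, per window.

    Window centers tile the truth profile's domain at ``window_spacing``.
    Sampling is inverse-CDF on a fine per-window grid (step sigma/20 of the
    bias Gaussian) with linear interpolation, so the samples follow the
    analytic biased density to grid precision.  Deterministic given ``seed``.
    """
    if window_spacing <= 0:
        raise ValueError("window_spacing must be positive")
    if spring_k <= 0:
        raise ValueError("spring_k must be positive")
    if n_per_window < 100:
        raise ValueError("n_per_window must be >= 100")
    x0, x1 = float(pmf_truth.x[0]), float(pmf_truth.x[-1])
    if x1 - x0 < window_spacing:
        raise ValueError(
            f"truth PMF domain [{x0:g}, {x1:g}] nm narrower than the window "
            f"spacing {window_spacing:g} nm"
        )
    kt = KB * temperature
    sigma = math.sqrt(kt / spring_k)
    n_w = int(math.floor((x1 - x0) / window_spacing + 1e-9)) + 1
    centers = x0 + window_spacing * np.arange(n_w)
    rng = np.random.default_rng(seed)
    windows = []
    for c in centers:
        lo = max(x0, c - 8.0 * sigma - 0.1)
        hi = min(x1, c + 8.0 * sigma + 0.1)
        grid = np.linspace(lo, hi, max(200, int((hi - lo) / (sigma / 20.0))))
        energy = pmf_truth(grid) + 0.5 * spring_k * (grid - c) ** 2
        logw = -(energy - energy.min()) / kt
        dens = np.exp(logw)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0)])
        cdf /= cdf[-1]
        u = rng.random(n_per_window)
        samples = np.interp(u, cdf, grid)
        windows.append(Window(float(c), spring_k, samples))
    return UmbrellaDataset(windows=windows, temperature=temperature)


def biased_density(
    pmf_truth: PMFProfile,
    center: float,
    spring_k: float,
    temperature: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Analytic normalized biased density on ``grid`` (oracle for tests)."""
    kt = KB * temperature
    e = pmf_truth(grid) + 0.5 * spring_k * (grid - center) ** 2
    d = np.exp(-(e - e.min()) / kt)
    return d / np.trapezoid(d, grid)


# ---------------------------------------------------------------------------
# Truth PMF shapes
# ---------------------------------------------------------------------------


def flip_flop_pmf(
    barrier_height: float,
    span: float = 5.0,
    barrier_pos: float = 2.5,
    width: float = 0.6,
    n: int = 1001,
) -> PMFProfile:
    """Gaussian-barrier truth PMF for a lipid flip-flop coordinate.

    x runs from the outer-leaflet head-group region (x=0, G=0 minimum) toward
    the far side; the barrier of height ``barrier_height`` kJ/mol sits at the
    bilayer midplane ``barrier_pos``.
    """
    x = np.linspace(0.0, span, n)
    G = barrier_height * np.exp(-((x - barrier_pos) ** 2) / (2.0 * width**2))
    return PMFProfile(x, G)


def harmonic_pmf(a: float, span: float = 5.0, n: int = 1001) -> PMFProfile:
    """Truth PMF G(x) = 0.5 * a * (x - span/2)^2 (kJ/mol, a in kJ/mol/nm^2)."""
    x = np.linspace(0.0, span, n)
    return PMFProfile(x, 0.5 * a * (x - span / 2.0) ** 2)


DEFAULT_CURVATURES = (0.0, 0.1, 0.13, 0.2, 0.4)  # nm^-1, the cylinder series
FLAT_BARRIER = 80.0  # kJ/mol at zero curvature
BARRIER_SLOPE = 100.0  # kJ/mol per nm^-1 of curvature


def barrier_vs_curvature(C: float) -> float:
    """Scripted ground-truth dG_flip(C): linear decrease with curvature.

    Linear dG in C makes the implied nucleation density an exact single
    exponential in C, which is the functional form the pipeline's fit assumes.
    """
    return FLAT_BARRIER - BARRIER_SLOPE * C


__all__ = [
    "Geometry",
    "TranslocationClass",
    "ChargeScheme",
    "LigandChemistry",
    "SynthSpec",
    "NPDesign",
    "TrajectoryLabel",
    "generate_membrane",
    "punch_pore",
    "generate_np_trajectory",
    "generate_umbrella_samples",
    "enumerate_design_grid",
    "biased_density",
    "flip_flop_pmf",
    "harmonic_pmf",
    "barrier_vs_curvature",
    "np_shell_radius",
    "DEFAULT_CURVATURES",
    "DEFAULT_CORE_DIAMETERS",
]
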