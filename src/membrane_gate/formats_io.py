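"""Readers and writers for GRO coordinates, XYZ trajectories, and result tables.

Units are nm (GRO native) and ns throughout.  Readers validate strictly and
raise :class:`ParseError` naming the offending line rather than guessing on
malformed input.

Bead typing on input is driven by a configurable atom-name -> role table whose
default covers the MARTINI DPPC names (PO4 -> phosphate, C-tail prefixes ->
tail_carbon, NC3/GL glycerol-choline -> other) plus the names this package
writes for nanoparticle beads, so both synthetic files and real
coarse-grained output are ingestible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .frames import (
    LIGAND,
    LOWER,
    NO_LEAFLET,
    NP_CORE,
    OTHER,
    PHOSPHATE,
    ROLE_NAMES,
    TAIL_CARBON,
    UPPER,
    MembraneFrame,
    Trajectory,
)


class ParseError(ValueError):
    """Malformed input; the message carries the file path and line number."""


#: atom-name prefix -> bead role, checked longest-prefix-first.
DEFAULT_ROLE_TABLE: dict[str, int] = {
    "PO4": PHOSPHATE,
    "NC3": OTHER,
    "GL": OTHER,
    "C": TAIL_CARBON,
    "LIG": LIGAND,
    "NPC": NP_CORE,
    "W": OTHER,
    "NA": OTHER,
    "CL": OTHER,
}

# Atom/residue names used on output.
_ROLE_ATOM = {
    PHOSPHATE: "PO4",
    TAIL_CARBON: "C1A",
    LIGAND: "LIG",
    NP_CORE: "NPC",
    OTHER: "W",
}
_ROLE_RES = {
    PHOSPHATE: "DPPC",
    TAIL_CARBON: "DPPC",
    LIGAND: "NP",
    NP_CORE: "NP",
    OTHER: "SOL",
}
_LEAFLET_TAG = {UPPER: "U", LOWER: "L", NO_LEAFLET: "X"}
_TAG_LEAFLET = {v: k for k, v in _LEAFLET_TAG.items()}


def name_to_role(name: str, table: dict[str, int] | None = None) -> int:
    table = table if table is not None else DEFAULT_ROLE_TABLE
    for prefix in sorted(table, key=len, reverse=True):
        if name.startswith(prefix):
            return table[prefix]
    return OTHER


def read_gro(
    path: str | Path, role_table: dict[str, int] | None = None
) -> MembraneFrame:
    """Read a GRO coordinate file (positions in nm, fixed columns).

    Leaflets are not stored in GRO; all membrane beads come back unlabelled
    (use :func:`membrane_gate.frames.assign_leaflets` for flat patches).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}:1: truncated GRO file ({len(lines)} lines)")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}:2: atom count is not an integer: {lines[1]!r}") from exc
    if len(lines) < n_atoms + 3:
        raise ParseError(
            f"{path}:{len(lines)}: header declares {n_atoms} atoms but only "
            f"{len(lines) - 3} atom lines and a box line fit in the file"
        )
    positions = np.empty((n_atoms, 3))
    roles = np.empty(n_atoms, dtype=np.int8)
    resids = np.empty(n_atoms, dtype=np.int64)
    for k in range(n_atoms):
        ln = lines[2 + k]
        lineno = 3 + k
        if len(ln) < 44:
            raise ParseError(f"{path}:{lineno}: atom line shorter than 44 columns")
        try:
            resids[k] = int(ln[0:5])
            positions[k] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed atom line: {ln!r}") from exc
        roles[k] = name_to_role(ln[10:15].strip(), role_table)
    box_line = lines[2 + n_atoms].split()
    if len(box_line) < 3:
        raise ParseError(
            f"{path}:{3 + n_atoms}: missing or malformed box vector line"
        )
    try:
        box = np.array([float(v) for v in box_line[:3]])
    except ValueError as exc:
        raise ParseError(
            f"{path}:{3 + n_atoms}: malformed box vector line: {lines[2 + n_atoms]!r}"
        ) from exc
    return MembraneFrame(
        positions=positions,
        roles=roles,
        leaflets=np.zeros(n_atoms, dtype=np.int8),
        residue_ids=resids,
        box=box,
        meta={"title": lines[0]},
    )


def write_gro(frame: MembraneFrame, path: str | Path, title: str = "membrane-gate") -> None:
    """Write a fixed-column GRO file (3-decimal positions, box line last).

    Atom and residue numbers wrap modulo 100000 per the format convention.
    """
    if not np.all(np.isfinite(frame.positions)):
        raise ValueError("refusing to write non-finite positions")
    path = Path(path)
    out = [title, f"{frame.n_beads:5d}"]
    for k in range(frame.n_beads):
        role = int(frame.roles[k])
        resid = int(frame.residue_ids[k]) % 100_000
        atomnum = (k + 1) % 100_000
        x, y, z = frame.positions[k]
        out.append(
            f"{resid:5d}{_ROLE_RES[role]:<5s}{_ROLE_ATOM[role]:>5s}{atomnum:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    out.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    path.write_text("\n".join(out) + "\n")


def _xyz_name(role: int, leaflet: int) -> str:
    return f"{_ROLE_ATOM[int(role)]}{_LEAFLET_TAG[int(leaflet)]}"


def write_xyz_trajectory(traj: Trajectory, path: str | Path, decimals: int = 5) -> None:
    """Write a multi-frame XYZ text trajectory (units nm, declared per frame).

    The atom name encodes role and leaflet (e.g. ``PO4U``); per-frame bead
    counts may differ when lipids were removed by pore punching.
    """
    path = Path(path)
    fmt = f"{{:.{decimals}f}}"
    chunks = []
    for frame, t in zip(traj.frames, traj.times):
        lines = [str(frame.n_beads), f"t= {t:.6f} ns units=nm"]
        for k in range(frame.n_beads):
            p = frame.positions[k]
            lines.append(
                f"{_xyz_name(frame.roles[k], frame.leaflets[k])} "
                f"{fmt.format(p[0])} {fmt.format(p[1])} {fmt.format(p[2])}"
            )
        lines.append(
            f"box {frame.box[0]:.5f} {frame.box[1]:.5f} {frame.box[2]:.5f}"
        )
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + "\n")


def read_xyz_trajectory(
    path: str | Path,
    frame_interval: float = 0.4,
    box: Iterable[float] | None = None,
) -> Trajectory:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz_trajectory`.

    Frame times are index * ``frame_interval`` (ns).  Residue identity is not
    representable in XYZ; beads come back with residue_id -1.  A trailing
    ``box`` line per frame (an extension this package writes) restores box
    dimensions; otherwise ``box`` must be given.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[MembraneFrame] = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError as exc:
            raise ParseError(
                f"{path}:{k + 1}: expected an atom count, got {lines[k]!r}"
            ) from exc
        if k + 1 + n > len(lines):
            raise ParseError(
                f"{path}:{k + 1}: frame declares {n} atoms but the file ends early"
            )
        comment = lines[k + 1]
        positions = np.empty((n, 3))
        roles = np.empty(n, dtype=np.int8)
        leaflets = np.empty(n, dtype=np.int8)
        for a in range(n):
            parts = lines[k + 2 + a].split()
            if len(parts) != 4:
                raise ParseError(
                    f"{path}:{k + 3 + a}: expected 'name x y z', got "
                    f"{lines[k + 2 + a]!r}"
                )
            name = parts[0]
            tag = name[-1] if name[-1] in _TAG_LEAFLET else "X"
            base = name[:-1] if name[-1] in _TAG_LEAFLET else name
            roles[a] = name_to_role(base)
            leaflets[a] = _TAG_LEAFLET[tag]
            try:
                positions[a] = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{k + 3 + a}: malformed coordinates: "
                    f"{lines[k + 2 + a]!r}"
                ) from exc
        k += 2 + n
        frame_box = None
        if k < len(lines) and lines[k].startswith("box "):
            frame_box = np.array([float(v) for v in lines[k].split()[1:4]])
            k += 1
        if frame_box is None:
            if box is None:
                raise ParseError(
                    f"{path}:{k}: no box line in frame and no box given"
                )
            frame_box = np.asarray(list(box), dtype=float)
        frames.append(
            MembraneFrame(
                positions=positions,
                roles=roles,
                leaflets=leaflets,
                residue_ids=np.full(n, -1, dtype=np.int64),
                box=frame_box,
                meta={"comment": comment},
            )
        )
    if not frames:
        raise ParseError(f"{path}:1: empty trajectory file")
    return Trajectory(
        frames=frames, times=frame_interval * np.arange(len(frames))
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "trajectory",
    "label",
    "nucleation_time_ns",
    "duration_ns",
    "max_pore_area_nm2",
    "final_z_offset_nm",
    "final_contact_fraction",
    "wrap_fraction",
    "no_entry",
]

NUCLEATION_COLUMNS = ["curvature_nm^-1", "dG_flip_kJ_mol", "rho_nm^-2"]


def results_to_frame(results: list, names: list[str] | None = None) -> pd.DataFrame:
    """TranslocationResult list -> tidy DataFrame (None -> NA)."""
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "trajectory": names[i] if names else f"traj{i}",
                "label": r.label.value,
                "nucleation_time_ns": r.nucleation_time,
                "duration_ns": r.duration,
                "max_pore_area_nm2": r.max_pore_area,
                "final_z_offset_nm": r.final_z_offset,
                "final_contact_fraction": r.final_contact_fraction,
                "wrap_fraction": r.wrap_fraction,
                "no_entry": r.no_entry,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def nucleation_to_frame(model) -> pd.DataFrame:
    """NucleationModel -> per-curvature table."""
    return pd.DataFrame(
        {
            "curvature_nm^-1": model.curvature,
            "dG_flip_kJ_mol": model.dG_flip,
            "rho_nm^-2": model.rho,
        },
        columns=NUCLEATION_COLUMNS,
    )


def write_results_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-delimited table; missing values serialize as ``NA``."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


__all__ = [
    "ParseError",
    "DEFAULT_ROLE_TABLE",
    "name_to_role",
    "read_gro",
    "write_gro",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "results_to_frame",
    "nucleation_to_frame",
    "write_results_table",
    "read_results_table",
]
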