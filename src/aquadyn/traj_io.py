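"""Trajectory I/O and water topology.

Reads and writes multi-frame extended-XYZ files (``Lattice="..."`` comment
header, optional velocity columns) and a plain multi-XYZ format with a
one-line cell sidecar.  All geometry in this package goes through
:func:`minimum_image_displacement`; coordinates are stored unwrapped as read.

Units: lengths in Angstrom, times in ps, velocities in Angstrom/ps.
Only orthorhombic (rectangular) cells are supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Trajectory",
    "WaterTopology",
    "minimum_image_displacement",
    "minimum_image_distance",
    "read_trajectory",
    "write_trajectory",
    "build_water_topology",
]


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file cannot be parsed consistently."""


@dataclass
class Trajectory:
    """A fixed-composition MD trajectory with an orthorhombic periodic cell.

    Parameters
    ----------
    dt : float
        Time step between stored frames, in ps.
    cell : ndarray, shape (n_frames, 3)
        Orthorhombic box edge lengths per frame, in Angstrom.
    elements : ndarray of str, shape (n_atoms,)
        Element symbol per atom; identical ordering in every frame.
    positions : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Angstrom (unwrapped, as read).
    velocities : ndarray or None, shape (n_frames, n_atoms, 3)
        Cartesian velocities in Angstrom/ps, if available.
    """

    dt: float
    cell: np.ndarray
    elements: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        self.elements = np.asarray(self.elements, dtype=str)
        cell = np.asarray(self.cell, dtype=float)
        if cell.ndim == 1:
            cell = np.broadcast_to(cell, (self.n_frames, 3)).copy()
        self.cell = cell
        if self.cell.shape != (self.n_frames, 3):
            raise ValueError("cell must have shape (n_frames, 3) or (3,)")
        if np.any(self.cell <= 0):
            raise ValueError("cell lengths must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.elements.shape[0] != self.n_atoms:
            raise ValueError("elements length does not match atom count")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def span(self) -> float:
        """Total simulated time covered by the stored frames, in ps."""
        return (self.n_frames - 1) * self.dt

    @property
    def has_velocities(self) -> bool:
        return self.velocities is not None


@dataclass
class WaterTopology:
    """O->(H, H) molecule assignment plus ion bookkeeping.

    ``molecules`` is an (n_molecules, 3) integer array of atom indices
    ``[O, H1, H2]``; ``ion_indices`` maps an element symbol (e.g. "Mg",
    "Cl") to the atom indices of that ion species.
    """

    molecules: np.ndarray
    ion_indices: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.molecules = np.asarray(self.molecules, dtype=int)
        if self.molecules.size and self.molecules.shape[1] != 3:
            raise ValueError("molecules must be (n, 3) [O, H1, H2] indices")
        self.ion_indices = {
            k: np.asarray(v, dtype=int) for k, v in self.ion_indices.items()
        }

    @property
    def n_molecules(self) -> int:
        return self.molecules.shape[0]

    @property
    def oxygen_indices(self) -> np.ndarray:
        return self.molecules[:, 0]

    @property
    def hydrogen_indices(self) -> np.ndarray:
        """(n_molecules, 2) array of the two H atom indices per molecule."""
        return self.molecules[:, 1:]


def minimum_image_displacement(a, b, cell):
    """Minimum-image displacement ``b - a`` in an orthorhombic cell.

    Each component of the result lies in ``(-L/2, L/2]``.  Broadcasts over
    leading dimensions of ``a`` and ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cell = np.asarray(cell, dtype=float)
    if np.any(cell <= 0):
        raise ValueError("cell lengths must be positive")
    d = b - a
    # ceil(x - 1/2) maps the component into (-L/2, L/2]
    return d - cell * np.ceil(d / cell - 0.5)


def minimum_image_distance(a, b, cell):
    """Minimum-image Euclidean distance between ``a`` and ``b``."""
    d = minimum_image_displacement(a, b, cell)
    return np.sqrt(np.sum(d * d, axis=-1))


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"', re.IGNORECASE)
_PROPS_RE = re.compile(r"Properties=(\S+)", re.IGNORECASE)
_DT_RE = re.compile(r"(?:dt|Timestep)=([0-9eE+.\-]+)", re.IGNORECASE)


def _parse_lattice(comment: str, frame: int) -> np.ndarray:
    m = _LATTICE_RE.search(comment)
    if m is None:
        raise TrajectoryParseError(f"frame {frame}: missing Lattice in comment line")
    vals = np.array([float(x) for x in m.group(1).split()])
    if vals.size != 9:
        raise TrajectoryParseError(f"frame {frame}: Lattice must have 9 components")
    mat = vals.reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.any(np.abs(off) > 1e-10):
        raise TrajectoryParseError(
            f"frame {frame}: non-orthorhombic (triclinic) cell is not supported"
        )
    return np.diag(mat).copy()


def _parse_properties(comment: str) -> list[tuple[str, str, int]]:
    m = _PROPS_RE.search(comment)
    if m is None:
        # extended-XYZ default
        return [("species", "S", 1), ("pos", "R", 3)]
    toks = m.group(1).split(":")
    if len(toks) % 3:
        raise TrajectoryParseError("malformed Properties specification")
    return [
        (toks[i], toks[i + 1], int(toks[i + 2])) for i in range(0, len(toks), 3)
    ]


def read_trajectory(
    path: str | Path,
    format: str = "extxyz",
    dt: float | None = None,
    cell_file: str | Path | None = None,
) -> Trajectory:
    """Read a trajectory file.

    Parameters
    ----------
    path : path
        Multi-frame XYZ-family file.
    format : {"extxyz", "xyz"}
        ``extxyz`` expects a ``Lattice="..."`` comment per frame (velocities
        picked up from a ``vel`` Properties field when present).  ``xyz``
        is plain XYZ plus a one-line cell sidecar (``cell_file``, default
        ``<path>.cell``) holding the three box lengths in Angstrom.
    dt : float, optional
        Frame spacing in ps; overrides any ``dt=``/``Timestep=`` comment
        field.  Defaults to 1 fs (0.001 ps) when neither is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format not in ("extxyz", "xyz"):
        raise ValueError(f"unknown trajectory format: {format!r}")

    sidecar_cell = None
    if format == "xyz":
        cf = Path(cell_file) if cell_file is not None else path.with_suffix(".cell")
        if not cf.exists():
            raise TrajectoryParseError(
                f"plain-XYZ input requires a cell sidecar file ({cf} missing)"
            )
        sidecar_cell = np.array(
            [float(x) for x in cf.read_text().split()[:3]], dtype=float
        )

    lines = path.read_text().splitlines()
    frames_pos: list[np.ndarray] = []
    frames_vel: list[np.ndarray] = []
    frames_cell: list[np.ndarray] = []
    elements: list[str] | None = None
    file_dt: float | None = None

    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError as exc:
            raise TrajectoryParseError(
                f"frame {frame}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + natoms > len(lines):
            raise TrajectoryParseError(f"frame {frame}: truncated frame")
        comment = lines[i + 1]
        if format == "extxyz":
            frames_cell.append(_parse_lattice(comment, frame))
            props = _parse_properties(comment)
        else:
            frames_cell.append(sidecar_cell)
            props = [("species", "S", 1), ("pos", "R", 3)]
        mdt = _DT_RE.search(comment)
        if mdt is not None:
            file_dt = float(mdt.group(1))

        col = 0
        col_species = col_pos = col_vel = None
        for name, _, ncols in props:
            if name.lower() == "species":
                col_species = col
            elif name.lower() == "pos":
                col_pos = col
            elif name.lower() in ("vel", "velo", "velocities"):
                col_vel = col
            col += ncols
        if col_species is None or col_pos is None:
            raise TrajectoryParseError(
                f"frame {frame}: Properties must include species and pos"
            )

        els, pos, vel = [], [], []
        for k in range(natoms):
            parts = lines[i + 2 + k].split()
            els.append(parts[col_species])
            pos.append([float(x) for x in parts[col_pos : col_pos + 3]])
            if col_vel is not None:
                vel.append([float(x) for x in parts[col_vel : col_vel + 3]])
        if elements is None:
            elements = els
        elif els != elements or natoms != len(elements):
            raise TrajectoryParseError(f"frame {frame}: atom count mismatch")
        frames_pos.append(np.array(pos))
        if col_vel is not None:
            frames_vel.append(np.array(vel))
        elif frames_vel:
            raise TrajectoryParseError(f"frame {frame}: velocity columns disappeared")
        i += 2 + natoms
        frame += 1

    if not frames_pos:
        raise TrajectoryParseError("no frames found")
    eff_dt = dt if dt is not None else (file_dt if file_dt is not None else 0.001)
    return Trajectory(
        dt=eff_dt,
        cell=np.array(frames_cell),
        elements=np.array(elements),
        positions=np.array(frames_pos),
        velocities=np.array(frames_vel) if frames_vel else None,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory in extended-XYZ (round-trips with the reader)."""
    path = Path(path)
    with_vel = traj.has_velocities
    props = "species:S:1:pos:R:3" + (":vel:R:3" if with_vel else "")
    out = []
    for f in range(traj.n_frames):
        lx, ly, lz = traj.cell[f]
        out.append(str(traj.n_atoms))
        out.append(
            f'Lattice="{lx:.10f} 0.0 0.0 0.0 {ly:.10f} 0.0 0.0 0.0 {lz:.10f}" '
            f"Properties={props} dt={traj.dt:.8g}"
        )
        for a in range(traj.n_atoms):
            x, y, z = traj.positions[f, a]
            line = f"{traj.elements[a]} {x:.8f} {y:.8f} {z:.8f}"
            if with_vel:
                vx, vy, vz = traj.velocities[f, a]
                line += f" {vx:.8f} {vy:.8f} {vz:.8f}"
            out.append(line)
    path.write_text("\n".join(out) + "\n")


def build_water_topology(
    traj: Trajectory, frame: int = 0, oh_cutoff: float = 1.2
) -> WaterTopology:
    """Assign each H to its nearest O within ``oh_cutoff`` (minimum image).

    The topology is built once from a reference frame and held fixed for the
    whole trajectory (no O-H dissociation is expected).  Non-O/H elements are
    collected as ions by species.

    Raises
    ------
    ValueError
        If any H has no O within the cutoff, or an O ends up with a number
        of hydrogens different from two.
    """
    if not 0 <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range")
    pos = traj.positions[frame]
    cell = traj.cell[frame]
    els = traj.elements
    o_idx = np.flatnonzero(els == "O")
    h_idx = np.flatnonzero(els == "H")
    ions: dict[str, np.ndarray] = {}
    for sp in np.unique(els):
        if sp not in ("O", "H"):
            ions[sp] = np.flatnonzero(els == sp)

    if o_idx.size == 0 and h_idx.size == 0:
        return WaterTopology(molecules=np.empty((0, 3), dtype=int), ion_indices=ions)

    assigned: dict[int, list[int]] = {int(o): [] for o in o_idx}
    if h_idx.size:
        if o_idx.size == 0:
            raise ValueError("hydrogens present but no oxygens")
        d = minimum_image_distance(
            pos[h_idx][:, None, :], pos[o_idx][None, :, :], cell
        )  # (nH, nO)
        nearest = np.argmin(d, axis=1)
        for k, h in enumerate(h_idx):
            if d[k, nearest[k]] >= oh_cutoff:
                raise ValueError(
                    f"hydrogen atom {int(h)} has no oxygen within "
                    f"{oh_cutoff} A (nearest at {d[k, nearest[k]]:.3f} A)"
                )
            assigned[int(o_idx[nearest[k]])].append(int(h))

    bad = [o for o, hs in assigned.items() if len(hs) != 2]
    if bad:
        raise ValueError(
            "oxygen atoms with a hydrogen count != 2 within "
            f"{oh_cutoff} A: indices {sorted(bad)}"
        )
    molecules = np.array(
        [[o, *sorted(assigned[int(o)])] for o in o_idx], dtype=int
    ).reshape(-1, 3)
    return WaterTopology(molecules=molecules, ion_indices=ions)
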