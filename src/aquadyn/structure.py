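"""Solvation-structure analysis: RDFs, shells, hydrogen bonds, ion pairing,
and water-exchange counting.

The radial distribution function g(r) is the probability, relative to a
random (ideal-gas) distribution at the same density, of finding a B-species
atom at distance r from an A-species atom.  Shell boundaries are the minima
of g(r); integrating g(r) to a shell boundary gives the coordination number.

Hydrogen bonds use the geometric criterion: O-O distance < 3.5 A, the donor
O-H covalent distance < 1.2 A, the H...acceptor-O distance < 2.5 A, and the
angle at the donor oxygen between the O->O and O->H vectors <= 30 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .traj_io import Trajectory, WaterTopology, minimum_image_displacement, minimum_image_distance

__all__ = [
    "RDFProfile",
    "ShellBoundaries",
    "HBCriteria",
    "SpeciationResult",
    "compute_rdf",
    "coordination_number",
    "find_shell_minima",
    "detect_hbonds",
    "hbond_statistics",
    "classify_ion_pairs",
    "count_water_exchanges",
]


@dataclass
class RDFProfile:
    """Radial distribution function on a uniform bin grid.

    ``counts`` holds the raw (frame-summed) pair counts per bin so that the
    histogram can be compared exactly against independent pair counting.
    """

    r_centers: np.ndarray
    g: np.ndarray
    pair: tuple[str, str]
    density_B: float
    bin_width: float
    counts: np.ndarray | None = None


@dataclass
class ShellBoundaries:
    """Outer edges of the first and second coordination shells (Angstrom)."""

    r_min1: float
    r_min2: float
    pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if not 0 < self.r_min1 < self.r_min2:
            raise ValueError("require 0 < r_min1 < r_min2")


@dataclass
class HBCriteria:
    """Geometric hydrogen-bond criteria (distances in A, angle in degrees).

    ``angle_vertex`` selects where the <=30 degree angle is measured:
    "donor" (default; angle at the donor O between O->O and O->H) or
    "acceptor" for sensitivity checks against the alternative reading.
    """

    r_OO_max: float = 3.5
    r_OH_cov_max: float = 1.2
    r_OH_hb_max: float = 2.5
    theta_max: float = 30.0
    angle_vertex: str = "donor"

    def __post_init__(self) -> None:
        if min(self.r_OO_max, self.r_OH_cov_max, self.r_OH_hb_max, self.theta_max) <= 0:
            raise ValueError("criteria must be positive")
        if self.r_OH_cov_max >= self.r_OH_hb_max:
            raise ValueError("covalent O-H cutoff must be below the HB O-H cutoff")
        if self.angle_vertex not in ("donor", "acceptor"):
            raise ValueError("angle_vertex must be 'donor' or 'acceptor'")


@dataclass
class SpeciationResult:
    """Percentages of contact / solvent-shared / solvent-separated ion pairs."""

    cip: float
    sship: float
    ssip: float
    n_pairs_counted: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        return {"CIP": self.cip, "SSHIP": self.sship, "SSIP": self.ssip}


def _pair_distances(pos_a, pos_b, cell, same: bool) -> np.ndarray:
    """All A-B minimum-image distances in one frame; same-species pairs
    exclude the self distance."""
    d = minimum_image_distance(pos_a[:, None, :], pos_b[None, :, :], cell)
    if same:
        d = d[~np.eye(d.shape[0], dtype=bool)]
    return np.ravel(d)


def compute_rdf(
    traj: Trajectory,
    pair: tuple[str, str],
    r_max: float,
    bin_width: float = 0.05,
) -> RDFProfile:
    """Radial distribution function g(r) for an element pair, frame-averaged.

    Normalized per frame by the ideal-gas shell count at the B-species number
    density (with the (N-1)/V self-exclusion for like pairs).
    """
    sp_a, sp_b = pair
    idx_a = np.flatnonzero(traj.elements == sp_a)
    idx_b = np.flatnonzero(traj.elements == sp_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"species pair {pair} not present in trajectory")
    if r_max > traj.cell.min() / 2 + 1e-9:
        raise ValueError(
            f"r_max={r_max} exceeds half the smallest box length "
            f"({traj.cell.min() / 2:.3f} A)"
        )
    same = sp_a == sp_b
    nbins = int(round(r_max / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    counts = np.zeros(nbins, dtype=np.int64)
    ideal = np.zeros(nbins)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    dens_acc = 0.0
    for f in range(traj.n_frames):
        d = _pair_distances(
            traj.positions[f, idx_a], traj.positions[f, idx_b], traj.cell[f], same
        )
        counts += np.histogram(d, bins=edges)[0]
        vol = float(np.prod(traj.cell[f]))
        rho = (idx_b.size - (1 if same else 0)) / vol
        dens_acc += rho
        ideal += idx_a.size * rho * shell_vol
    g = np.where(ideal > 0, counts / ideal, 0.0)
    return RDFProfile(
        r_centers=0.5 * (edges[:-1] + edges[1:]),
        g=g,
        pair=pair,
        density_B=dens_acc / traj.n_frames,
        bin_width=bin_width,
        counts=counts,
    )


def coordination_number(rdf: RDFProfile, r_cut: float) -> float:
    """Running coordination number 4 pi rho_B int_0^r_cut g r^2 dr (trapezoid
    on the bin centers, starting from the implicit g(0)=0 point)."""
    if r_cut > rdf.r_centers[-1] + rdf.bin_width / 2 + 1e-9:
        raise ValueError("r_cut beyond the RDF profile range")
    mask = rdf.r_centers < r_cut
    g_cut = float(np.interp(r_cut, rdf.r_centers, rdf.g))
    r = np.concatenate(([0.0], rdf.r_centers[mask], [r_cut]))
    y = np.concatenate(([0.0], rdf.g[mask] * rdf.r_centers[mask] ** 2,
                        [g_cut * r_cut**2]))
    return float(4.0 * np.pi * rdf.density_B * np.trapezoid(y, r))


def find_shell_minima(
    rdf: RDFProfile,
    smooth_window: int = 5,
    fallback: tuple[float, float] | None = None,
    min_prominence: float = 0.05,
) -> ShellBoundaries:
    """Locate the first and second minima of a (smoothed) g(r).

    r_min1 is the first local minimum after the first peak; r_min2 the first
    local minimum after the second peak (or the profile end if g never turns
    up again).  Raw short-trajectory RDFs are noisy, hence the centered
    moving-average smoothing.  ``fallback`` boundaries are returned when the
    peaks cannot be detected.
    """
    g = rdf.g.astype(float)
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        g = np.convolve(g, k, mode="same")
    peaks, _ = find_peaks(g, prominence=min_prominence)
    try:
        if len(peaks) < 2:
            raise ValueError(
                "fewer than two peaks detected in g(r); provide fallback boundaries"
            )
        p1, p2 = peaks[0], peaks[1]
        minima, _ = find_peaks(-g)
        after1 = minima[(minima > p1) & (minima < p2)]
        if after1.size == 0:
            raise ValueError("no minimum found between the first two peaks")
        m1 = after1[0]
        after2 = minima[minima > p2]
        m2 = after2[0] if after2.size else len(g) - 1
        return ShellBoundaries(
            r_min1=float(rdf.r_centers[m1]),
            r_min2=float(rdf.r_centers[m2]),
            pair=rdf.pair,
        )
    except ValueError:
        if fallback is not None:
            return ShellBoundaries(r_min1=fallback[0], r_min2=fallback[1], pair=rdf.pair)
        raise


def detect_hbonds(
    positions: np.ndarray,
    topology: WaterTopology,
    criteria: HBCriteria | None = None,
    cell: np.ndarray | None = None,
) -> np.ndarray:
    """Detect water-water hydrogen bonds in one frame.

    Returns an (n_bonds, 3) integer array of (donor molecule, acceptor
    molecule, H atom index) triples.  The donor is the molecule whose H is
    shared; the angle criterion is evaluated at the vertex selected in the
    criteria (donor oxygen by default).
    """
    if criteria is None:
        criteria = HBCriteria()
    if cell is None:
        raise ValueError("cell is required for minimum-image HB detection")
    mols = topology.molecules
    n = mols.shape[0]
    if n < 2:
        return np.empty((0, 3), dtype=int)
    o_pos = positions[mols[:, 0]]
    doo = minimum_image_distance(o_pos[:, None, :], o_pos[None, :, :], cell)
    cand_j, cand_i = np.nonzero((doo < criteria.r_OO_max) & ~np.eye(n, dtype=bool))
    bonds = []
    cos_max = np.cos(np.deg2rad(criteria.theta_max))
    for j, i in zip(cand_j, cand_i):
        oj = positions[mols[j, 0]]
        oi = positions[mols[i, 0]]
        v_oo = minimum_image_displacement(oj, oi, cell)
        for h in mols[j, 1:]:
            hp = positions[h]
            v_oh = minimum_image_displacement(oj, hp, cell)
            if np.linalg.norm(v_oh) >= criteria.r_OH_cov_max:
                continue  # not covalently bound to the donor in this frame
            if minimum_image_distance(oi, hp, cell) >= criteria.r_OH_hb_max:
                continue
            if criteria.angle_vertex == "donor":
                va, vb = v_oo, v_oh
            else:
                va = minimum_image_displacement(oi, oj, cell)
                vb = minimum_image_displacement(oi, hp, cell)
            cosang = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
            if cosang >= cos_max:
                bonds.append((int(j), int(i), int(h)))
    return np.array(bonds, dtype=int).reshape(-1, 3)


def hbond_statistics(
    traj: Trajectory,
    topology: WaterTopology,
    criteria: HBCriteria | None = None,
    selection=None,
):
    """Mean number of HBs per water and the distribution over n.

    ``selection`` restricts the per-molecule statistics to a subset of
    molecules; it may be a static index array or a callable
    ``frame_index -> molecule indices`` (e.g. the first shell of an ion).
    The bond count per molecule is donated + accepted bonds.

    Returns ``(mean_nhb, histogram)`` where ``histogram[n]`` is the fraction
    (percent) of selected molecule-frames engaging in exactly n HBs.
    """
    if criteria is None:
        criteria = HBCriteria()
    n_mol = topology.n_molecules
    counts_acc: list[np.ndarray] = []
    for f in range(traj.n_frames):
        bonds = detect_hbonds(traj.positions[f], topology, criteria, traj.cell[f])
        per_mol = np.zeros(n_mol, dtype=int)
        if bonds.size:
            np.add.at(per_mol, bonds[:, 0], 1)
            np.add.at(per_mol, bonds[:, 1], 1)
        if selection is None:
            sel = np.arange(n_mol)
        elif callable(selection):
            sel = np.asarray(selection(f), dtype=int)
        else:
            sel = np.asarray(selection, dtype=int)
        if sel.size:
            counts_acc.append(per_mol[sel])
    if not counts_acc:
        raise ValueError("selection is empty in every frame")
    all_counts = np.concatenate(counts_acc)
    nmax = int(all_counts.max())
    hist = np.bincount(all_counts, minlength=nmax + 1) / all_counts.size * 100.0
    return float(all_counts.mean()), hist


def classify_ion_pairs(
    traj: Trajectory,
    topology: WaterTopology,
    cation: str,
    anion: str,
    boundaries: ShellBoundaries,
    horizon: float = 8.0,
) -> SpeciationResult:
    """Classify cation-anion pairs as CIP / SSHIP / SSIP by distance shells.

    Each cation is paired with its nearest anion in each frame: contact ion
    pair (CIP) below ``r_min1``, solvent-shared (SSHIP) in
    ``[r_min1, r_min2)``, solvent-separated (SSIP) in ``[r_min2, horizon)``;
    cations whose nearest anion is beyond the horizon are not counted.
    """
    cat = topology.ion_indices.get(cation)
    an = topology.ion_indices.get(anion)
    if cat is None or an is None or cat.size == 0 or an.size == 0:
        raise ValueError(f"ion species {cation!r}/{anion!r} not present")
    tallies = {"CIP": 0, "SSHIP": 0, "SSIP": 0}
    total = 0
    for f in range(traj.n_frames):
        d = minimum_image_distance(
            traj.positions[f, cat][:, None, :],
            traj.positions[f, an][None, :, :],
            traj.cell[f],
        )
        dmin = d.min(axis=1)
        for x in dmin:
            if x < boundaries.r_min1:
                tallies["CIP"] += 1
            elif x < boundaries.r_min2:
                tallies["SSHIP"] += 1
            elif x < horizon:
                tallies["SSIP"] += 1
            else:
                continue
            total += 1
    if total == 0:
        return SpeciationResult(0.0, 0.0, 0.0, 0)
    return SpeciationResult(
        cip=100.0 * tallies["CIP"] / total,
        sship=100.0 * tallies["SSHIP"] / total,
        ssip=100.0 * tallies["SSIP"] / total,
        n_pairs_counted=total,
    )


def count_water_exchanges(
    traj: Trajectory,
    topology: WaterTopology,
    ion: int,
    boundary: float,
    t_star: float = 0.5,
    atom: str = "O",
) -> int:
    """Count shell crossings by the "direct" method.

    A water exchange is counted each time a tracked atom (water O for
    cations, H for anions) crosses the shell ``boundary`` around atom index
    ``ion`` and stays on the new side continuously for at least ``t_star``
    ps.  ``t_star = 0.5`` ps is the standard persistence threshold of the
    direct method.
    """
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    if atom == "O":
        tracked = topology.oxygen_indices
    elif atom == "H":
        tracked = topology.hydrogen_indices.ravel()
    else:
        raise ValueError("atom must be 'O' or 'H'")
    if tracked.size == 0:
        return 0
    d = np.empty((traj.n_frames, tracked.size))
    for f in range(traj.n_frames):
        d[f] = minimum_image_distance(
            traj.positions[f, ion], traj.positions[f, tracked], traj.cell[f]
        )
    inside = d < boundary
    n_star = int(np.ceil(t_star / traj.dt)) if t_star > 0 else 1
    n_events = 0
    for a in range(tracked.size):
        s = inside[:, a]
        # maximal runs of constant side; a crossing counts only when the new
        # side persists >= t_star (short flickers never change the accepted
        # side, so the return from a flicker is not an exchange either)
        change = np.flatnonzero(s[1:] != s[:-1]) + 1
        starts = np.concatenate(([0], change))
        lengths = np.diff(np.concatenate((starts, [s.size])))
        accepted_state = s[0]
        for st, ln in zip(starts[1:], lengths[1:]):
            if ln >= n_star and s[st] != accepted_state:
                n_events += 1
                accepted_state = s[st]
    return n_events
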