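"""Synthetic fixtures emulating the statistical structure of the analyses.

Three generator families:

* solutions of rigid waters around placed ions, with orientations evolving
  by isotropic rotational Brownian motion at a subpopulation-dependent rate
  (first-order Legendre correlation C1(t) = exp(-2 D t));
* Poisson hydrogen-bond breaking event series (continuous survival
  S(t) = exp(-k t));
* two-mode Debye dielectric spectra with an Ohmic loss term and
  multiplicative noise.

These emulate what the analysis chain assumes about real data - not liquid
physics: there are no forces, no translational diffusion by default, and no
water exchange between shells unless enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traj_io import Trajectory, WaterTopology, build_water_topology
from .drs import DielectricSpectrum, double_debye_eps, EPS0_SI

__all__ = [
    "SyntheticSolutionSpec",
    "SyntheticSpectrumSpec",
    "ToyConfiguration",
    "rotation_sigma",
    "gen_dipole_series",
    "gen_rotational_trajectory",
    "gen_hb_event_series",
    "gen_dielectric_spectrum",
    "gen_toy_hb_configurations",
]

# rigid water geometry (gas-phase-like): O-H bond and H-O-H angle
_R_OH = 0.9572
_HOH_DEG = 104.52


def _water_template() -> np.ndarray:
    """H offsets from O for a water whose dipole (bisector) points along +z."""
    half = np.deg2rad(_HOH_DEG) / 2
    return np.array(
        [
            [_R_OH * np.sin(half), 0.0, _R_OH * np.cos(half)],
            [-_R_OH * np.sin(half), 0.0, _R_OH * np.cos(half)],
        ]
    )


def rotation_sigma(D: float, dt: float) -> float:
    """Per-step rotation-angle scale for rotational diffusion coefficient D.

    A small rotation by angle a about a uniformly random axis displaces a
    body-fixed unit vector by <|du|^2> = (2/3) a^2, while diffusion on the
    sphere requires <|du|^2> = 4 D dt per step; hence a ~ Normal(0,
    sqrt(6 D dt)).  This calibration makes C1(t) = exp(-2 D t).  Valid for
    D dt << 1 (enforced: D dt < 0.01).
    """
    if D <= 0 or dt <= 0:
        raise ValueError("D and dt must be positive")
    if D * dt >= 0.01:
        raise ValueError(f"D*dt = {D * dt:.3g} too large for the small-angle propagator")
    return float(np.sqrt(6.0 * D * dt))


def _random_rotations(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """(n, 3, 3) small random rotation matrices (Rodrigues form)."""
    axis = rng.normal(size=(n, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    angle = rng.normal(0.0, sigma, size=n)
    K = np.zeros((n, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    eye = np.eye(3)[None]
    s = np.sin(angle)[:, None, None]
    c = (1 - np.cos(angle))[:, None, None]
    return eye + s * K + c * (K @ K)


def _random_orientations(rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 3, 3) uniformly random rotation matrices (QR-based)."""
    M = rng.normal(size=(n, 3, 3))
    Q, R = np.linalg.qr(M)
    sign = np.sign(np.einsum("nii->ni", R))
    sign[sign == 0] = 1.0
    Q = Q * sign[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 0] *= -1
    return Q


def gen_dipole_series(
    n: int, D: float, dt: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """(n_frames, n, 3) unit vectors undergoing rotational Brownian motion."""
    rng = np.random.default_rng(seed)
    sigma = rotation_sigma(D, dt)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    out = np.empty((n_frames, n, 3))
    out[0] = u
    for t in range(1, n_frames):
        R = _random_rotations(rng, n, sigma)
        u = np.einsum("nij,nj->ni", R, u)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        out[t] = u
    return out


@dataclass
class SyntheticSolutionSpec:
    """Design of a synthetic electrolyte box.

    One dissolved salt unit is one cation plus ``anions_per_cation`` anions
    (2 for an MgCl2-like salt).  Waters are placed in three designed groups:
    ``cation_shell_occupancy`` waters per cation with O on a sphere at
    ``cation_place_radius`` (inside the cation first shell), a per-anion
    number of waters with O at ``anion_place_radius`` (hydrogens then fall
    in the anion first/second shells), and bulk waters placed uniformly at
    least ``bulk_exclusion`` from every ion.  Rotational diffusion
    coefficients (rad^2/ps) are assigned per group via ``D_by_class`` with
    classes "slow_first", "slow_beyond", "bulk".
    """

    n_waters: int = 500
    n_cations: int = 1
    anions_per_cation: int = 2
    box: float = 26.0
    cation_species: str = "Mg"
    anion_species: str = "Cl"
    cation_shell_radii: tuple[float, float] = (3.0, 5.0)  # cation-O r_min1, r_min2
    anion_shell_radii: tuple[float, float] = (2.9, 5.0)   # anion-H r_min1, r_min2
    cation_place_radius: float = 2.1
    anion_place_radius: float = 3.0
    cation_shell_occupancy: int = 6
    anion_shell_occupancy: tuple[int, ...] | int = 0
    bulk_exclusion: float = 6.5
    water_min_dist: float = 2.5  # minimum O-O separation between placed waters
    D_by_class: dict = field(
        default_factory=lambda: {"slow_first": 0.02, "slow_beyond": 0.02, "bulk": 0.1}
    )
    dt: float = 0.02
    n_frames: int = 1000
    jiggle: float = 0.0
    exchange_rate: float = 0.0  # swaps per ps between bulk and slow_beyond groups
    seed: int = 0

    @property
    def n_anions(self) -> int:
        return self.n_cations * self.anions_per_cation

    @property
    def anion_occupancies(self) -> list[int]:
        occ = self.anion_shell_occupancy
        if isinstance(occ, int):
            return [occ] * self.n_anions
        occ = list(occ)
        if len(occ) != self.n_anions:
            raise ValueError("anion_shell_occupancy length must equal n_anions")
        return occ

    @property
    def designed_h(self) -> float:
        """Slow waters per salt unit implied by the design."""
        return (
            self.n_cations * self.cation_shell_occupancy + sum(self.anion_occupancies)
        ) / self.n_cations


def _sphere_points(n: int) -> np.ndarray:
    """n well-spread unit vectors (octahedral axes for n<=6, else Fibonacci)."""
    if n <= 6:
        axes = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        return axes[:n]
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _ion_sites(n: int, box: float) -> np.ndarray:
    corners = np.array(
        [
            [0.25, 0.25, 0.25], [0.75, 0.75, 0.75], [0.75, 0.75, 0.25],
            [0.25, 0.25, 0.75], [0.75, 0.25, 0.75], [0.25, 0.75, 0.25],
            [0.25, 0.75, 0.75], [0.75, 0.25, 0.25],
        ]
    )
    if n > len(corners):
        raise ValueError(
            f"infeasible packing: at most {len(corners)} ions fit the placement grid"
        )
    return corners[:n] * box


def gen_rotational_trajectory(
    spec: SyntheticSolutionSpec,
) -> tuple[Trajectory, WaterTopology, dict]:
    """Build the designed box and evolve water orientations.

    Returns (trajectory, topology, ground_truth); ground_truth records the
    class and diffusion coefficient of every water, the designed hydration
    number, and the salt-unit count.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    box = spec.box
    if box < 18.0 and (spec.n_cations + spec.n_anions) > 1:
        raise ValueError("infeasible packing: box too small to separate the ions")
    n_ions = spec.n_cations + spec.n_anions
    ion_pos = _ion_sites(n_ions, box)
    cat_pos = ion_pos[: spec.n_cations]
    an_pos = ion_pos[spec.n_cations :]

    occ_an = spec.anion_occupancies
    if spec.cation_shell_occupancy > 12 or max(occ_an, default=0) > 12:
        raise ValueError("infeasible packing: shell occupancy above 12")
    n_designed = spec.n_cations * spec.cation_shell_occupancy + sum(occ_an)
    n_bulk = spec.n_waters - n_designed
    if n_bulk < 0:
        raise ValueError("infeasible packing: more shell waters than n_waters")

    o_sites: list[np.ndarray] = []
    classes: list[str] = []
    for c in range(spec.n_cations):
        for v in _sphere_points(spec.cation_shell_occupancy):
            o_sites.append(cat_pos[c] + spec.cation_place_radius * v)
            classes.append("slow_first")
    for a in range(spec.n_anions):
        for v in _sphere_points(occ_an[a]):
            o_sites.append(an_pos[a] + spec.anion_place_radius * v)
            classes.append("slow_beyond")
    placed = 0
    attempts = 0
    while placed < n_bulk:
        attempts += 1
        if attempts > 500 * max(n_bulk, 1):
            raise ValueError("infeasible packing: cannot place bulk waters")
        p = rng.uniform(0, box, size=3)
        d = ion_pos - p
        d -= box * np.round(d / box)
        if np.min(np.linalg.norm(d, axis=1)) < spec.bulk_exclusion:
            continue
        if o_sites:
            dw = np.asarray(o_sites) - p
            dw -= box * np.round(dw / box)
            if np.min(np.linalg.norm(dw, axis=1)) < spec.water_min_dist:
                continue
        o_sites.append(p)
        classes.append("bulk")
        placed += 1
    o_sites = np.array(o_sites).reshape(-1, 3)
    n_w = o_sites.shape[0]
    D = np.array([spec.D_by_class[c] for c in classes])
    sigma = np.array([rotation_sigma(d, spec.dt) for d in np.atleast_1d(D)])

    template = _water_template()  # (2, 3)
    orient = _random_orientations(rng, n_w)  # (n_w, 3, 3)

    elements = (
        [spec.cation_species] * spec.n_cations
        + [spec.anion_species] * spec.n_anions
        + ["O", "H", "H"] * n_w
    )
    n_atoms = len(elements)
    positions = np.empty((spec.n_frames, n_atoms, 3))

    swap_p = min(spec.exchange_rate * spec.dt, 1.0)
    bulk_ids = [i for i, c in enumerate(classes) if c == "bulk"]
    beyond_ids = [i for i, c in enumerate(classes) if c == "slow_beyond"]

    sites = o_sites.copy()
    for t in range(spec.n_frames):
        if t > 0:
            orient = np.einsum("nij,njk->nik", _scaled_rotations(rng, sigma), orient)
            if spec.exchange_rate > 0 and bulk_ids and beyond_ids:
                if rng.random() < swap_p:
                    i = int(rng.choice(bulk_ids))
                    j = int(rng.choice(beyond_ids))
                    sites[[i, j]] = sites[[j, i]]
        frame_sites = sites
        if spec.jiggle > 0:
            frame_sites = sites + rng.normal(0.0, spec.jiggle, size=sites.shape)
        h_off = np.einsum("nij,kj->nki", orient, template)  # (n_w, 2, 3)
        positions[t, : n_ions] = ion_pos
        w = n_ions
        positions[t, w::3] = frame_sites
        positions[t, w + 1 :: 3] = frame_sites + h_off[:, 0]
        positions[t, w + 2 :: 3] = frame_sites + h_off[:, 1]

    traj = Trajectory(
        dt=spec.dt,
        cell=np.full((spec.n_frames, 3), box),
        elements=np.array(elements),
        positions=positions,
    )
    topology = build_water_topology(traj, frame=0)
    ground_truth = {
        "classes": classes,
        "D": D.tolist(),
        "designed_h": spec.designed_h,
        "n_salt_units": spec.n_cations,
        "slow_first_per_salt": float(spec.cation_shell_occupancy),
        "slow_beyond_per_salt": float(sum(occ_an)) / spec.n_cations,
        "seed": spec.seed,
    }
    return traj, topology, ground_truth


def _scaled_rotations(rng: np.random.Generator, sigma: np.ndarray) -> np.ndarray:
    """(n, 3, 3) random rotations with per-body angle scale ``sigma``."""
    n = sigma.size
    axis = rng.normal(size=(n, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    angle = rng.normal(0.0, 1.0, size=n) * sigma
    K = np.zeros((n, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    s = np.sin(angle)[:, None, None]
    c = (1 - np.cos(angle))[:, None, None]
    return np.eye(3)[None] + s * K + c * (K @ K)


def gen_hb_event_series(
    n_pairs: int, k_break: float, dt: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Poisson bond-breaking series: (n_frames, n_pairs) 0/1 array.

    Every pair starts bonded; each step it breaks with probability
    1 - exp(-k dt) and never reforms, so the exact continuous survival law
    is S(t) = exp(-k t).
    """
    if k_break < 0 or dt <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    p_break = 1.0 - np.exp(-k_break * dt)
    h = np.ones((n_frames, n_pairs), dtype=np.int8)
    alive = np.ones(n_pairs, dtype=bool)
    for t in range(1, n_frames):
        breaks = rng.random(n_pairs) < p_break
        alive &= ~breaks
        h[t] = alive
    return h


@dataclass
class SyntheticSpectrumSpec:
    """Parameters of a synthetic double-Debye spectrum with Ohmic loss."""

    S1: float = 72.0
    S2: float = 2.5
    tau1_ps: float = 8.3
    tau2_ps: float = 0.25
    eps_inf: float = 3.52
    conductivity: float = 0.0  # S/m
    noise: float = 0.0         # multiplicative Gaussian noise level
    f_min_GHz: float = 0.01
    f_max_GHz: float = 110.0
    n_points: int = 200
    concentration: float = 0.0
    water_concentration: float = 55.35
    seed: int = 0


def gen_dielectric_spectrum(spec: SyntheticSpectrumSpec) -> DielectricSpectrum:
    """Evaluate the Debye model on a log-spaced GHz grid, add the Ohmic term
    to the loss, and apply multiplicative Gaussian noise (seeded)."""
    rng = np.random.default_rng(spec.seed)
    f = np.logspace(np.log10(spec.f_min_GHz), np.log10(spec.f_max_GHz), spec.n_points)
    real, loss = double_debye_eps(
        f, spec.S1, spec.S2, spec.tau1_ps, spec.tau2_ps, spec.eps_inf
    )
    omega = 2 * np.pi * f * 1e9
    loss = loss + spec.conductivity / (omega * EPS0_SI)
    if spec.noise > 0:
        real = real * (1.0 + spec.noise * rng.normal(size=f.size))
        loss = loss * (1.0 + spec.noise * rng.normal(size=f.size))
    return DielectricSpectrum(
        freq_GHz=f,
        eps_real=real,
        eps_imag=loss,
        conductivity=spec.conductivity,
        concentration=spec.concentration,
        water_concentration=spec.water_concentration,
    )


@dataclass
class ToyConfiguration:
    """A labelled single-frame fixture for the HB detector."""

    name: str
    trajectory: Trajectory
    expected_total_hbonds: int
    expected_central_nhb: int | None = None


def _make_frame(molecules: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                box: float = 30.0) -> Trajectory:
    els, pos = [], []
    for o, h1, h2 in molecules:
        els += ["O", "H", "H"]
        pos += [o, h1, h2]
    return Trajectory(
        dt=1.0,
        cell=np.array([[box, box, box]]),
        elements=np.array(els),
        positions=np.array(pos)[None, :, :],
    )


def gen_toy_hb_configurations() -> dict[str, ToyConfiguration]:
    """Hand-built dimers and a tetrahedral pentamer with exact HB counts."""
    c = 15.0  # center of the 30 A box
    half = np.deg2rad(_HOH_DEG) / 2

    def water_at(o, dipole, perp):
        """Water with O at o, bisector along unit vector dipole."""
        dipole = np.asarray(dipole, float)
        perp = np.asarray(perp, float)
        h1 = o + _R_OH * (np.cos(half) * dipole + np.sin(half) * perp)
        h2 = o + _R_OH * (np.cos(half) * dipole - np.sin(half) * perp)
        return (np.asarray(o, float), h1, h2)

    out = {}

    # linear dimer: donor O-H points straight at the acceptor (angle 0)
    o_d = np.array([c, c, c])
    o_a = o_d + np.array([2.8, 0, 0])
    donor = (o_d, o_d + np.array([_R_OH, 0, 0]),
             o_d + _R_OH * np.array([np.cos(np.deg2rad(104.52)), np.sin(np.deg2rad(104.52)), 0]))
    acceptor = water_at(o_a, [1, 0, 0], [0, 1, 0])  # points away from donor
    out["ideal_dimer"] = ToyConfiguration(
        "ideal_dimer", _make_frame([donor, acceptor]), expected_total_hbonds=1
    )

    # same dimer stretched past the O-O cutoff
    o_a_far = o_d + np.array([3.6, 0, 0])
    out["far_dimer"] = ToyConfiguration(
        "far_dimer",
        _make_frame([donor, water_at(o_a_far, [1, 0, 0], [0, 1, 0])]),
        expected_total_hbonds=0,
    )

    # donated H rotated to 35 degrees off the O-O axis: distance criteria
    # still hold but the angle criterion fails
    ang = np.deg2rad(35.0)
    donor_bent = (
        o_d,
        o_d + _R_OH * np.array([np.cos(ang), np.sin(ang), 0]),
        o_d + _R_OH * np.array([np.cos(ang + np.deg2rad(104.52)),
                                np.sin(ang + np.deg2rad(104.52)), 0]),
    )
    out["bent_dimer"] = ToyConfiguration(
        "bent_dimer",
        _make_frame([donor_bent, water_at(o_a, [1, 0, 0], [0, 1, 0])]),
        expected_total_hbonds=0,
    )

    # tetrahedral pentamer: the central water donates 2 and accepts 2
    t = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3)
    center = np.array([c, c, c])
    central = (center, center + _R_OH * t[0], center + _R_OH * t[1])
    mols = [central]
    for k in (0, 1):  # acceptors along the two donated H directions
        mols.append(water_at(center + 2.8 * t[k], t[k], _perp(t[k])))
    for k in (2, 3):  # donors pointing one H back at the central O
        o = center + 2.8 * t[k]
        h_back = o - _R_OH * t[k]
        h_other = o + _R_OH * _perp(t[k])
        mols.append((o, h_back, h_other))
    out["pentamer"] = ToyConfiguration(
        "pentamer", _make_frame(mols), expected_total_hbonds=4,
        expected_central_nhb=4,
    )

    # a lone water for the zero-bond baseline
    out["monomer"] = ToyConfiguration(
        "monomer",
        _make_frame([water_at(np.array([c, c, c]), [0, 0, 1], [1, 0, 0])]),
        expected_total_hbonds=0,
    )
    return out


def _perp(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v."""
    v = np.asarray(v, float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)
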