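"""Shared fixtures: toy HB configurations and a small designed solution."""

import numpy as np
import pytest

from aquadyn.structure import ShellBoundaries
from aquadyn.synthetic import (
    SyntheticSolutionSpec,
    gen_rotational_trajectory,
    gen_toy_hb_configurations,
)
from aquadyn.traj_io import Trajectory


@pytest.fixture(scope="session")
def toy_configs():
    return gen_toy_hb_configurations()


@pytest.fixture(scope="session")
def designed_solution():
    """A small box with 6 slow waters in the cation first shell and 9 slow
    waters around the anions (designed h = 15), plus bulk waters."""
    spec = SyntheticSolutionSpec(
        n_waters=300,
        n_cations=1,
        anions_per_cation=2,
        anion_shell_occupancy=(5, 4),
        n_frames=1000,
        dt=0.02,
        seed=7,
    )
    traj, topo, truth = gen_rotational_trajectory(spec)
    return spec, traj, topo, truth


@pytest.fixture(scope="session")
def designed_shells():
    return (
        ShellBoundaries(3.0, 5.0, pair=("Mg", "O")),
        ShellBoundaries(2.9, 5.0, pair=("Cl", "H")),
    )


def make_single_frame(elements, positions, box=20.0):
    """Convenience constructor for one-frame trajectories."""
    return Trajectory(
        dt=1.0,
        cell=np.array([[box, box, box]], dtype=float),
        elements=np.array(elements),
        positions=np.asarray(positions, dtype=float)[None, :, :],
    )
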