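import numpy as np
import pytest

from ptfluct.core import Atom, Box, ConditionLabel, Topology, Trajectory
from ptfluct.synth import (
    OUProteinSpec,
    TelegraphSpec,
    generate_hbond_occupancy,
    generate_ou_protein,
)


@pytest.fixture(scope="session")
def ou_trajectory():
    """Small OU pseudo-protein: 20 atoms, 10 000 frames, MSF_true = 0.65 Å²."""
    from ptfluct.synth import KB_KCAL_MOL_K

    kappa = 3.0 * KB_KCAL_MOL_K * 279.0 / 0.65
    spec = OUProteinSpec(
        n_residues=10,
        atoms_per_residue=2,
        kappa=kappa,
        temperature=279.0,
        friction=0.2,
        n_frames=10_000,
        seed=11,
    )
    return generate_ou_protein(spec), spec


@pytest.fixture(scope="session")
def telegraph_occupancy():
    spec = TelegraphSpec(
        tau_on=25.0, tau_off=25.0, n_pairs=20, duration=10_000.0, seed=7
    )
    return generate_hbond_occupancy(spec)


def single_water_topology():
    """A 3-atom water (O, H1, H2)."""
    return Topology(
        [
            Atom(0, "O", "O", 0, "HOH", is_water=True),
            Atom(1, "H1", "H", 0, "HOH", is_water=True, bonded_heavy_partner=0),
            Atom(2, "H2", "H", 0, "HOH", is_water=True, bonded_heavy_partner=0),
        ]
    )


def make_hbond_triple_trajectory(acceptor_offsets, box_edge=50.0,
                                 frame_interval=1.0):
    """One (N, H, O) donor/acceptor triple; the acceptor position per frame
    is H + offset, with H at (11, 10, 10) and the donor N at (10, 10, 10)."""
    atoms = [
        Atom(0, "N", "N", 0, "ALA", is_protein=True),
        Atom(1, "H", "H", 0, "ALA", is_protein=True, bonded_heavy_partner=0),
        Atom(2, "O", "O", 0, "ALA", is_protein=True),
    ]
    n_frames = len(acceptor_offsets)
    coords = np.zeros((n_frames, 3, 3))
    coords[:, 0] = [10.0, 10.0, 10.0]
    coords[:, 1] = [11.0, 10.0, 10.0]
    for f, off in enumerate(acceptor_offsets):
        coords[f, 2] = coords[f, 1] + np.asarray(off, float)
    box = Box.cubic(box_edge)
    return Trajectory(
        topology=Topology(atoms),
        coordinates=coords,
        boxes=[box] * n_frames,
        frame_interval=frame_interval,
        label=ConditionLabel("TRIPLE", 300.0, 1.0),
    )
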