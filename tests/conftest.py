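"""Shared fixtures: toy structures with analytically known behaviour."""

from __future__ import annotations

import numpy as np
import pytest

import anmresponse as anm


@pytest.fixture(scope="session")
def diatomic():
    """Two 100-amu masses, one 0.1 N/m spring along x."""
    fix = anm.make_diatomic(mass_amu=100.0, separation_a=10.0)
    network = anm.build_network(fix.open_structure, cutoff=fix.cutoff, gamma=0.1)
    modes = anm.modal_analysis(
        anm.hessian(network),
        anm.mass_matrix(fix.open_structure),
        expected_rigid_modes=5,
    )
    return fix, network, modes


@pytest.fixture(scope="session")
def toy5():
    """Five-node random non-collinear cloud, fully connected, 6 rigid modes."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 8, size=(5, 3))
    structure = anm.CoarseGrainedStructure(
        coordinates=coords,
        chain_ids=np.array(["A"] * 5),
        residue_numbers=np.arange(1, 6),
        residue_names=np.array(["GLY", "ALA", "SER", "VAL", "LEU"]),
        masses=np.array([57.05, 71.08, 87.08, 99.13, 113.16]),
        source_id="toy5",
    )
    network = anm.build_network(structure, cutoff=20.0, gamma=0.2)
    modes = anm.modal_analysis(anm.hessian(network), anm.mass_matrix(structure))
    return structure, network, modes


@pytest.fixture(scope="session")
def hinge():
    """Open/closed hinge pair with mode 7 resembling the hinge motion."""
    fix = anm.make_hinge(nodes_per_lobe=8, hinge_angle_deg=20.0, seed=0)
    network = anm.build_network(
        fix.open_structure, cutoff=fix.cutoff, gamma=fix.expected["gamma"]
    )
    modes = anm.modal_analysis(
        anm.hessian(network), anm.mass_matrix(fix.open_structure)
    )
    cc = anm.conformational_change_vector(fix.open_structure, fix.closed_structure)
    return fix, network, modes, cc
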