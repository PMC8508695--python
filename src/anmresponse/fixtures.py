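"""Deterministic synthetic fixtures with analytically known behaviour.

Two recipes cover the test surface: a diatomic (two masses, one spring)
whose single internal frequency is the textbook sqrt(2 gamma / m), and a
hinged two-lobe cluster whose open/closed pair emulates a collective
domain motion — two compact random lobes bridged by a narrow neck, the
closed partner obtained by rigidly rotating one lobe about the neck.
The hinge recipe verifies at generation time that its lowest internal
mode resembles the hinge motion and reseeds itself otherwise, so every
returned fixture has a known conformational-change direction that
low-frequency forcing should reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K
from .elastic_network import (
    CoarseGrainedStructure,
    build_network,
    compute_bfactors,
    hessian,
    mass_matrix,
    modal_analysis,
)
from .errors import ANMError
from .trajectory_analysis import conformational_change_vector, overlap

__all__ = [
    "ToyFixture",
    "make_diatomic",
    "make_hinge",
    "make_synthetic_bfactors",
]


@dataclass
class ToyFixture:
    """A synthetic open structure, optional closed partner, and the
    analytic expectations the recipe guarantees."""

    open_structure: CoarseGrainedStructure
    closed_structure: CoarseGrainedStructure | None = None
    recipe: str = ""
    cutoff: float = 15.0
    expected: dict = field(default_factory=dict)


def _labels(n: int, chain: str = "A"):
    return (
        np.array([chain] * n),
        np.arange(1, n + 1),
        np.array(["ALA"] * n),
    )


def make_diatomic(mass_amu: float = 100.0, separation_a: float = 10.0) -> ToyFixture:
    """Two equal masses joined by one spring along x.

    The single internal mode is the symmetric stretch with
    omega = sqrt(2 gamma / m); the five remaining modes (3 translations,
    2 rotations perpendicular to the bond — a collinear geometry has no
    third rotation carrying elastic energy) are rigid.
    """
    coords = np.array([[0.0, 0.0, 0.0], [separation_a, 0.0, 0.0]])
    chains, resnums, resnames = _labels(2)
    structure = CoarseGrainedStructure(
        coordinates=coords,
        chain_ids=chains,
        residue_numbers=resnums,
        residue_names=resnames,
        masses=np.array([mass_amu, mass_amu]),
        source_id=f"diatomic(m={mass_amu},d={separation_a})",
    )
    return ToyFixture(
        open_structure=structure,
        recipe="diatomic",
        cutoff=max(15.0, separation_a + 1.0),
        expected={"rigid_modes": 5, "mass_amu": mass_amu, "separation_a": separation_a},
    )


def _rotate_z(coords: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return coords @ rot.T


def make_hinge(
    nodes_per_lobe: int = 8,
    hinge_angle_deg: float = 20.0,
    seed: int = 0,
    gamma: float = 0.1,
    max_attempts: int = 25,
) -> ToyFixture:
    """Open/closed pair related by a collective hinge rotation.

    Geometry: two compact random lobes (radius 2.5 A) around
    (+-7, 0, 0), bridged by a three-node neck at x = 0 that is spread
    along z but narrow in y.  With the fixture cutoff of 7.5 A the
    lobes connect only through the neck; the anisotropic neck makes
    in-plane (x-y) bending the softest internal motion, which is
    exactly the hinge rotation.  The closed partner rotates the +x lobe
    rigidly about the z axis through the neck by ``hinge_angle_deg``,
    so the conformational-change vector is localized on that lobe and
    collective within it.

    Each candidate is checked: the network must be connected, have
    exactly 6 rigid modes, and its lowest internal mode must overlap the
    hinge displacement better than mode 20 does (and above 0.7
    absolute).  Failing candidates are regenerated from the next seed.
    """
    if nodes_per_lobe < 4:
        raise ValueError("nodes_per_lobe must be >= 4")
    cutoff = 7.5
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        lobes = []
        for center in (np.array([-7.0, 0.0, 0.0]), np.array([7.0, 0.0, 0.0])):
            pts = []
            while len(pts) < nodes_per_lobe:
                p = rng.uniform(-2.5, 2.5, size=3)
                if np.linalg.norm(p) <= 2.5:
                    pts.append(center + p)
            lobes.append(np.array(pts))
        # off-axis neck: z-spread blocks torsion mechanisms about x, and
        # the small y-extent keeps x-y bending the softest direction
        neck = np.array([[0.0, 0.0, 2.2], [0.0, 0.0, -2.2], [0.0, 0.9, 0.2]])
        coords = np.vstack([neck, lobes[0], lobes[1]])
        n = coords.shape[0]
        # indices of the moving rigid body: the +x lobe
        moving = np.arange(3 + nodes_per_lobe, n)

        closed = coords.copy()
        closed[moving] = _rotate_z(closed[moving], np.deg2rad(hinge_angle_deg))

        chains, resnums, resnames = _labels(n)
        masses = np.full(n, 110.0)
        open_structure = CoarseGrainedStructure(
            coordinates=coords,
            chain_ids=chains,
            residue_numbers=resnums,
            residue_names=resnames,
            masses=masses,
            source_id=f"hinge(seed={seed + attempt})-open",
        )
        closed_structure = CoarseGrainedStructure(
            coordinates=closed,
            chain_ids=chains.copy(),
            residue_numbers=resnums.copy(),
            residue_names=resnames.copy(),
            masses=masses.copy(),
            source_id=f"hinge(seed={seed + attempt})-closed",
        )
        try:
            network = build_network(open_structure, cutoff=cutoff, gamma=gamma)
            modes = modal_analysis(hessian(network), mass_matrix(open_structure))
        except ANMError:
            continue
        if hinge_angle_deg == 0:
            # degenerate recipe: open == closed, no hinge displacement to
            # check against; return the first well-posed candidate
            return ToyFixture(
                open_structure=open_structure,
                closed_structure=closed_structure,
                recipe="hinge",
                cutoff=cutoff,
                expected={
                    "rigid_modes": 6,
                    "gamma": gamma,
                    "hinge_angle_deg": 0.0,
                    "moving_nodes": moving.tolist(),
                    "seed_used": seed + attempt,
                },
            )
        cc = conformational_change_vector(open_structure, closed_structure)
        o_first = overlap(modes.internal_modes[:, 0], cc)
        idx_cmp = min(13, modes.n_internal - 1)  # mode 20 overall
        o_high = overlap(modes.internal_modes[:, idx_cmp], cc)
        if o_first > max(o_high, 0.7):
            return ToyFixture(
                open_structure=open_structure,
                closed_structure=closed_structure,
                recipe="hinge",
                cutoff=cutoff,
                expected={
                    "rigid_modes": 6,
                    "gamma": gamma,
                    "hinge_angle_deg": hinge_angle_deg,
                    "moving_nodes": moving.tolist(),
                    "mode7_cc_overlap": o_first,
                    "seed_used": seed + attempt,
                },
            )
    raise ANMError(
        f"could not generate a hinge fixture in {max_attempts} attempts "
        f"from seed {seed}"
    )


def make_synthetic_bfactors(
    structure: CoarseGrainedStructure,
    gamma_star: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    noise_fraction: float = 0.0,
    cutoff: float = 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Model-generated "experimental" B-factors at a known spring constant.

    Computes the thermal B-factors of the network built at
    ``gamma_star`` and optionally multiplies them by unit-median-free
    lognormal noise (sigma = ``noise_fraction``, mean factor exactly 1),
    so spring-constant calibration on the noise-free output recovers
    ``gamma_star`` identically and remains unbiased in expectation under
    noise.
    """
    if gamma_star <= 0:
        raise ValueError("gamma_star must be positive")
    network = build_network(structure, cutoff=cutoff, gamma=gamma_star)
    modes = modal_analysis(hessian(network), mass_matrix(structure))
    b = compute_bfactors(modes, temperature=temperature)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_fraction
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=b.size)
        b = b * noise
    return b
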