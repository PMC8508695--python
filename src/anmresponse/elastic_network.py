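"""Calpha elastic network: structure input, Hessian/mass assembly, modes.

The model treats each residue as a point node at its Calpha position.
Every pair of nodes closer than a cutoff ``r_c`` is joined by a Hookean
spring of uniform stiffness ``gamma``.  With explicit residue masses the
free vibrations of the network are the solutions of the generalized
symmetric eigenproblem

    (H - omega_n^2 M) delta_n = 0,

whose six zero-frequency eigenvectors are the rigid-body motions and
whose remaining 3N-6 eigenpairs are the internal vibrational modes.
Predicted thermal fluctuations (B-factors) calibrate ``gamma`` against
the experimental B-factor column of the crystal structure.
"""

from __future__ import annotations

import io
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix
from scipy.spatial.distance import pdist, squareform

from .constants import (
    AMU,
    ANGSTROM,
    DEFAULT_CUTOFF_A,
    DEFAULT_TEMPERATURE_K,
    K_B,
    MEAN_RESIDUE_MASS_AMU,
    RESIDUE_MASSES_AMU,
    ZERO_MODE_RTOL,
    rad_s_to_thz,
)
from .errors import (
    CalibrationError,
    DegeneracyError,
    DisconnectedNetworkError,
    StructureError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CoarseGrainedStructure",
    "ElasticNetwork",
    "ModalDecomposition",
    "read_structure",
    "build_network",
    "hessian",
    "mass_matrix",
    "modal_analysis",
    "compute_bfactors",
    "calibrate_gamma",
]


@dataclass
class CoarseGrainedStructure:
    """One node per residue: coordinates, identity, mass and B-factor.

    Parameters
    ----------
    coordinates : (N, 3) float array, angstrom
    chain_ids : sequence of N chain identifiers
    residue_numbers : sequence of N author residue numbers
    residue_names : sequence of N three-letter residue names
    masses : (N,) float array, amu
    experimental_bfactors : (N,) float array, angstrom^2, or None
    source_id : free-text provenance (e.g. a PDB code or recipe name)
    insertion_codes : sequence of N insertion codes ('' if absent)
    """

    coordinates: np.ndarray
    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    masses: np.ndarray
    experimental_bfactors: np.ndarray | None = None
    source_id: str = ""
    insertion_codes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids)
        self.residue_numbers = np.asarray(self.residue_numbers)
        self.residue_names = np.asarray(self.residue_names)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.insertion_codes is None:
            self.insertion_codes = np.array([""] * len(self.masses))
        else:
            self.insertion_codes = np.asarray(self.insertion_codes)
        n = self.coordinates.shape[0]
        if n < 2:
            raise StructureError(f"need at least 2 nodes, got {n}")
        if self.coordinates.shape != (n, 3) or not np.all(
            np.isfinite(self.coordinates)
        ):
            raise StructureError("coordinates must be a finite (N, 3) array")
        for name, arr in (
            ("chain_ids", self.chain_ids),
            ("residue_numbers", self.residue_numbers),
            ("residue_names", self.residue_names),
            ("masses", self.masses),
            ("insertion_codes", self.insertion_codes),
        ):
            if len(arr) != n:
                raise StructureError(f"{name} has {len(arr)} entries, expected {n}")
        if np.any(self.masses <= 0) or not np.all(np.isfinite(self.masses)):
            raise StructureError("all masses must be positive and finite")
        keys = list(self.node_keys())
        if len(set(keys)) != n:
            raise StructureError("duplicate (chain, residue number, icode) node")
        if self.experimental_bfactors is not None:
            self.experimental_bfactors = np.asarray(
                self.experimental_bfactors, dtype=float
            )
            if self.experimental_bfactors.shape != (n,):
                raise StructureError("experimental_bfactors must have N entries")
            if np.any(self.experimental_bfactors <= 0):
                raise StructureError("experimental B-factors must be positive")

    @property
    def n_nodes(self) -> int:
        return self.coordinates.shape[0]

    def node_keys(self) -> list[tuple]:
        """(chain, residue number, insertion code) identity per node."""
        return [
            (str(c), int(r), str(i))
            for c, r, i in zip(
                self.chain_ids, self.residue_numbers, self.insertion_codes
            )
        ]


@dataclass
class ElasticNetwork:
    """A structure plus its spring topology.

    ``edges`` holds ``(i, j, r_ij)`` with ``i < j`` for exactly the node
    pairs within the cutoff; the network must form a single connected
    component (a free-floating fragment would make the eigenproblem
    degenerate beyond the six rigid modes).
    """

    structure: CoarseGrainedStructure
    cutoff: float
    gamma: float
    edges: list[tuple[int, int, float]] = field(repr=False, default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.structure.n_nodes


@dataclass
class ModalDecomposition:
    """Eigenpairs of ``(H - omega^2 M) delta = 0``, mass-orthonormal.

    ``mode_shapes`` holds one mode per column (3N x 3N), sorted by
    ascending frequency; columns satisfy ``Delta.T @ M @ Delta = I``.
    The first ``rigid_mode_count`` columns are zero-frequency rigid-body
    motions and are excluded from every physical sum in this package.
    """

    omega: np.ndarray  # rad/s, ascending
    mode_shapes: np.ndarray  # (3N, 3N), columns, units kg^-1/2
    rigid_mode_count: int
    n_nodes: int
    gamma_used: float | None = None
    temperature_used: float | None = None

    @property
    def frequencies_thz(self) -> np.ndarray:
        return np.array([rad_s_to_thz(w) for w in self.omega])

    @property
    def omega_internal(self) -> np.ndarray:
        """Angular frequencies of the non-rigid (internal) modes, rad/s."""
        return self.omega[self.rigid_mode_count :]

    @property
    def internal_modes(self) -> np.ndarray:
        """(3N, 3N - rigid) columns of the non-rigid mode shapes."""
        return self.mode_shapes[:, self.rigid_mode_count :]

    @property
    def n_internal(self) -> int:
        return self.mode_shapes.shape[1] - self.rigid_mode_count


def _resolve_altloc(atoms):
    """Keep, per (chain, res_id, icode, atom_name), the highest-occupancy
    altloc conformer; ties go to the first-listed one."""
    import biotite.structure as struc  # local import keeps cold start fast

    if "occupancy" in atoms.get_annotation_categories():
        occ = atoms.occupancy
    else:
        occ = np.ones(atoms.array_length())
    best: dict[tuple, int] = {}
    for idx in range(atoms.array_length()):
        key = (
            atoms.chain_id[idx],
            int(atoms.res_id[idx]),
            str(atoms.ins_code[idx]),
            atoms.atom_name[idx],
        )
        if key not in best or occ[idx] > occ[best[key]]:
            best[key] = idx
    keep = sorted(best.values())
    return atoms[np.asarray(keep, dtype=int)]


def read_structure(
    pdb_source,
    chains: Sequence[str] | None = None,
) -> CoarseGrainedStructure:
    """Read a PDB file into a one-node-per-residue structure.

    Keeps one Calpha per residue (highest-occupancy altloc, ties to the
    first listed), skips HETATM/water records and residues lacking a
    Calpha, and assigns masses from the built-in average residue-mass
    table (unknown names fall back to the table mean, with a warning).

    Parameters
    ----------
    pdb_source : path, or text stream, or PDB text
    chains : optional chain identifiers to keep; default all
    """
    from biotite.structure.io.pdb import PDBFile

    if hasattr(pdb_source, "read"):
        pdb_file = PDBFile.read(pdb_source)
        source_id = getattr(pdb_source, "name", "<stream>")
    elif isinstance(pdb_source, str) and "\n" in pdb_source:
        pdb_file = PDBFile.read(io.StringIO(pdb_source))
        source_id = "<text>"
    else:
        pdb_file = PDBFile.read(pdb_source)
        source_id = os.path.basename(str(pdb_source))

    atoms = pdb_file.get_structure(
        model=1, altloc="all", extra_fields=["b_factor", "occupancy"]
    )
    # CA name + carbon element keeps Calpha while excluding calcium ions
    # (also caught by the hetero filter).
    mask = (atoms.atom_name == "CA") & ~atoms.hetero
    mask &= (atoms.element == "C") | (atoms.element == "")
    if chains is not None:
        mask &= np.isin(atoms.chain_id, list(chains))
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise StructureError(f"no Calpha atoms found in {source_id!r}")
    ca = _resolve_altloc(ca)
    if ca.array_length() < 2:
        raise StructureError(f"fewer than 2 Calpha atoms in {source_id!r}")

    names = [str(r) for r in ca.res_name]
    masses = np.empty(len(names))
    unknown = set()
    for k, name in enumerate(names):
        if name in RESIDUE_MASSES_AMU:
            masses[k] = RESIDUE_MASSES_AMU[name]
        else:
            masses[k] = MEAN_RESIDUE_MASS_AMU
            unknown.add(name)
    if unknown:
        warnings.warn(
            f"unknown residue name(s) {sorted(unknown)}: "
            f"using mean residue mass {MEAN_RESIDUE_MASS_AMU:.2f} amu",
            stacklevel=2,
        )

    bfac = np.asarray(ca.b_factor, dtype=float)
    exp_b = bfac if np.all(bfac > 0) else None
    return CoarseGrainedStructure(
        coordinates=np.asarray(ca.coord, dtype=float),
        chain_ids=np.asarray([str(c) for c in ca.chain_id]),
        residue_numbers=np.asarray(ca.res_id, dtype=int),
        residue_names=np.asarray(names),
        masses=masses,
        experimental_bfactors=exp_b,
        source_id=source_id,
        insertion_codes=np.asarray([str(i) for i in ca.ins_code]),
    )


def build_network(
    structure: CoarseGrainedStructure,
    cutoff: float = DEFAULT_CUTOFF_A,
    gamma: float = 1.0,
) -> ElasticNetwork:
    """Place springs between all node pairs within ``cutoff`` (inclusive).

    Raises
    ------
    DisconnectedNetworkError
        If the resulting graph has more than one connected component;
        the message lists the component sizes.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    n = structure.n_nodes
    dists = squareform(pdist(structure.coordinates))
    ii, jj = np.nonzero(np.triu(dists <= cutoff, k=1))
    edges = [(int(i), int(j), float(dists[i, j])) for i, j in zip(ii, jj)]

    adj = csr_matrix(
        (np.ones(len(edges)), (ii, jj)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise DisconnectedNetworkError(
            f"network splits into {n_comp} components at cutoff "
            f"{cutoff:g} A (component sizes: {sizes.tolist()})"
        )
    return ElasticNetwork(structure=structure, cutoff=cutoff, gamma=gamma, edges=edges)


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Assemble the 3N x 3N stiffness matrix, N/m.

    Each connected pair (i, j) contributes the off-diagonal 3x3 block
    ``-gamma/r^2 * outer(d, d)`` with ``d`` the i->j separation vector;
    diagonal blocks are the negated sums of their row's off-diagonal
    blocks, which makes every row and column sum vanish (rigid
    translations cost no elastic energy).
    """
    n = network.n_nodes
    coords = network.structure.coordinates
    h = np.zeros((3 * n, 3 * n))
    g = network.gamma
    for i, j, r in network.edges:
        d = coords[j] - coords[i]
        block = -(g / r**2) * np.outer(d, d)
        h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        h[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        h[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return h


def mass_matrix(structure: CoarseGrainedStructure) -> np.ndarray:
    """Diagonal 3N x 3N mass matrix in kg (each node's mass on x, y, z)."""
    m_kg = np.repeat(structure.masses * AMU, 3)
    return np.diag(m_kg)


def modal_analysis(
    h: np.ndarray,
    m: np.ndarray,
    expected_rigid_modes: int | None = 6,
    zero_mode_rtol: float = ZERO_MODE_RTOL,
) -> ModalDecomposition:
    """Solve the generalized symmetric eigenproblem ``H delta = omega^2 M delta``.

    Eigenpairs come back sorted by ascending frequency with columns
    mass-orthonormal (``Delta.T M Delta = I``).  Eigenvalues below
    ``zero_mode_rtol`` times the largest count as rigid modes; negative
    eigenvalues within that band are clipped to zero.

    Parameters
    ----------
    expected_rigid_modes : require exactly this many zero modes (6 for a
        generic unconstrained 3-D network, 5 for a collinear one); pass
        None to accept whatever is detected.

    Raises
    ------
    DegeneracyError
        If the detected zero-mode count differs from
        ``expected_rigid_modes`` (the message reports the eigenvalue gap).
    """
    h = np.asarray(h, dtype=float)
    m = np.asarray(m, dtype=float)
    evals, evecs = scipy.linalg.eigh(h, m)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise DegeneracyError("Hessian has no positive eigenvalues")
    tol = zero_mode_rtol * lam_max
    n_zero = int(np.sum(evals < tol))
    if expected_rigid_modes is not None and n_zero != expected_rigid_modes:
        lo = evals[n_zero - 1] if n_zero > 0 else float("nan")
        hi = evals[n_zero] if n_zero < len(evals) else float("nan")
        raise DegeneracyError(
            f"detected {n_zero} zero modes, expected {expected_rigid_modes} "
            f"(eigenvalue gap at threshold {tol:.3e}: {lo:.3e} -> {hi:.3e})"
        )
    evals = np.clip(evals, 0.0, None)
    evals[:n_zero] = 0.0
    return ModalDecomposition(
        omega=np.sqrt(evals),
        mode_shapes=evecs,
        rigid_mode_count=n_zero,
        n_nodes=h.shape[0] // 3,
    )


def compute_bfactors(
    modes: ModalDecomposition, temperature: float = DEFAULT_TEMPERATURE_K
) -> np.ndarray:
    """Thermal B-factors per node, angstrom^2.

    B_i = (8 pi^2 / 3) k_B T sum_n |delta_{n,i}|^2 / omega_n^2, the sum
    running over the internal (non-rigid) modes only; |delta_{n,i}| is
    the 3-vector norm of node i's components of the mass-orthonormal
    mode n.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    omega = modes.omega_internal
    if np.any(omega <= 0):
        raise DegeneracyError(
            "zero-frequency mode inside the fluctuation sum; rigid modes "
            "must be excluded"
        )
    delta = modes.internal_modes  # (3N, n_modes), kg^-1/2
    per_node_sq = delta.reshape(modes.n_nodes, 3, -1) ** 2  # (N, 3, modes)
    node_mode = per_node_sq.sum(axis=1)  # |delta_{n,i}|^2
    msf = node_mode @ (1.0 / omega**2)  # m^2 (kg^-1 s^2 J = m^2)
    b_si = (8.0 * np.pi**2 / 3.0) * K_B * temperature * msf
    return b_si / ANGSTROM**2


def calibrate_gamma(
    structure: CoarseGrainedStructure,
    cutoff: float = DEFAULT_CUTOFF_A,
    temperature: float = DEFAULT_TEMPERATURE_K,
    gamma_trial: float = 0.1,
) -> float:
    """Spring constant (N/m) matching mean computed to mean experimental B.

    For uniform springs the mode shapes are gamma-independent and every
    computed B-factor scales as 1/gamma, so a single trial solve fixes
    the answer: gamma = gamma_trial * mean(B_calc(gamma_trial)) / mean(B_exp).
    """
    if structure.experimental_bfactors is None:
        raise CalibrationError(
            "structure has no experimental B-factors; cannot calibrate gamma"
        )
    network = build_network(structure, cutoff=cutoff, gamma=gamma_trial)
    modes = modal_analysis(hessian(network), mass_matrix(structure))
    b_calc = compute_bfactors(modes, temperature=temperature)
    gamma = gamma_trial * float(np.mean(b_calc) / np.mean(structure.experimental_bfactors))
    logger.info(
        "calibrated gamma = %.4g N/m (cutoff %.3g A, T %.4g K)",
        gamma,
        cutoff,
        temperature,
    )
    return gamma
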