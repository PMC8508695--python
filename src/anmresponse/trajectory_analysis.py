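"""Comparing computed responses with an observed conformational change.

The observed open->closed transition is encoded as a 3N displacement
vector {CC}: the superposed target coordinates minus the reference
coordinates.  Agreement between a computed displacement field u(t) and
{CC} is the overlap |u^T CC| / (|u| |CC|).  Supporting metrics: RMSD of
the displacement field, the dynamic-to-static RMSD amplification,
per-residue cosine non-linearity of the motion, principal component
analysis of the conformational ensemble, the collectivity degree of a
displacement field, and the frequency x damping x force-pattern scan
that maps where harmonic forcing best reproduces the transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .elastic_network import CoarseGrainedStructure, ModalDecomposition
from .errors import PairingError, UndefinedOverlapError
from .perturbation_response import (
    HarmonicExcitation,
    Trajectory,
    modal_response_coefficients,
    principal_coordinates,
    random_force_pattern,
    respond,
    static_response,
    synthesize_trajectory,
)

__all__ = [
    "ConformationalChange",
    "OverlapSeries",
    "PCAResult",
    "ScanResult",
    "superpose",
    "conformational_change_vector",
    "overlap",
    "overlap_series",
    "rmsd_series",
    "dynamic_amplification",
    "cosine_nonlinearity",
    "pca",
    "collectivity",
    "frequency_scan",
    "DESK_PRESET",
    "PAPER_PRESET",
]

#: Frames whose displacement norm falls below this (angstrom) have no
#: defined direction and are excluded from overlap statistics.
ZERO_DISPLACEMENT_A = 1.0e-6


@dataclass
class ConformationalChange:
    """The observed transition as a 3N displacement vector (angstrom)."""

    cc_vector: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    superposition_rmsd: float
    source_open: str = ""
    source_closed: str = ""

    def __post_init__(self) -> None:
        self.cc_vector = np.asarray(self.cc_vector, dtype=float)
        if np.linalg.norm(self.cc_vector) == 0:
            raise UndefinedOverlapError("conformational-change vector has zero norm")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("superposition rotation must be proper (det +1)")

    @property
    def collectivity(self) -> float:
        return collectivity(self.cc_vector)


@dataclass
class OverlapSeries:
    """Per-frame overlap with {CC}; NaN marks frames with ~zero displacement."""

    times_ps: np.ndarray
    values: np.ndarray

    @property
    def max(self) -> float:
        return float(np.nanmax(self.values))

    @property
    def argmax_time_ps(self) -> float:
        return float(self.times_ps[np.nanargmax(self.values)])


@dataclass
class PCAResult:
    """Eigendecomposition of the conformational covariance matrix.

    ``components`` holds one orthonormal principal component per column,
    sorted by descending eigenvalue; ``scores`` are the centered
    conformations projected onto them.
    """

    eigenvalues: np.ndarray
    components: np.ndarray
    scores: np.ndarray
    mean: np.ndarray

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Project extra conformations (rows, 3N) onto the components."""
        return (np.atleast_2d(coords) - self.mean) @ self.components


@dataclass
class ScanResult:
    """Outcome of a frequency x damping x force-pattern grid.

    ``table`` has one row per (frequency_thz, damping, seed) with the
    max overlap in the evaluation window, max dynamic RMSD, static RMSD
    and the amplification ratio; ``optima`` reduces it to the best
    frequency per (damping, seed).
    """

    table: pd.DataFrame
    optima: pd.DataFrame = field(default=None)


def superpose(
    mobile: CoarseGrainedStructure,
    reference: CoarseGrainedStructure,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[int], list[int]]:
    """Least-squares rigid superposition (Kabsch) of paired residues.

    Nodes are paired by (chain, residue number, insertion code)
    intersection, not serial order.  Returns (rotation, translation,
    transformed mobile coordinates, rmsd, mobile indices, reference
    indices); the rotation is always proper (reflections rejected).
    """
    keys_m = mobile.node_keys()
    keys_r = reference.node_keys()
    common = set(keys_m) & set(keys_r)
    if len(common) < 3:
        raise PairingError(
            f"only {len(common)} residues shared between the two structures; "
            "need at least 3 to superpose"
        )
    idx_m = [i for i, k in enumerate(keys_m) if k in common]
    idx_r_map = {k: i for i, k in enumerate(keys_r)}
    idx_r = [idx_r_map[keys_m[i]] for i in idx_m]

    x = mobile.coordinates[idx_m]
    y = reference.coordinates[idx_r]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    u_svd, _, vt = np.linalg.svd((x - xc).T @ (y - yc))
    d = np.sign(np.linalg.det(vt.T @ u_svd.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u_svd.T  # maps mobile -> reference frame
    trans = yc - rot @ xc
    x_fit = mobile.coordinates @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((x_fit[idx_m] - y) ** 2, axis=1))))
    return rot, trans, x_fit, rmsd, idx_m, idx_r


def conformational_change_vector(
    open_structure: CoarseGrainedStructure,
    closed_structure: CoarseGrainedStructure,
) -> ConformationalChange:
    """{CC}: superposed closed minus open coordinates, flattened to 3N.

    N is the number of paired residues; the open structure is the
    reference frame.
    """
    rot, trans, closed_fit, rmsd, idx_c, idx_o = superpose(
        closed_structure, open_structure
    )
    diff = closed_fit[idx_c] - open_structure.coordinates[idx_o]
    return ConformationalChange(
        cc_vector=diff.ravel(),
        rotation=rot,
        translation=trans,
        superposition_rmsd=rmsd,
        source_open=open_structure.source_id,
        source_closed=closed_structure.source_id,
    )


def overlap(u: np.ndarray, cc: ConformationalChange | np.ndarray) -> float:
    """|u^T CC| / (|u| |CC|), in [0, 1]."""
    cc_vec = cc.cc_vector if isinstance(cc, ConformationalChange) else np.asarray(cc)
    u = np.asarray(u, dtype=float).ravel()
    nu, nc = np.linalg.norm(u), np.linalg.norm(cc_vec)
    if nu == 0 or nc == 0:
        raise UndefinedOverlapError("overlap undefined for a zero-norm vector")
    return float(abs(u @ cc_vec) / (nu * nc))


def overlap_series(
    trajectory: Trajectory, cc: ConformationalChange | np.ndarray
) -> OverlapSeries:
    """Overlap per frame; near-zero-displacement frames are NaN (missing)."""
    cc_vec = cc.cc_vector if isinstance(cc, ConformationalChange) else np.asarray(cc)
    u = trajectory.displacements
    norms = np.linalg.norm(u, axis=1)
    nc = np.linalg.norm(cc_vec)
    if nc == 0:
        raise UndefinedOverlapError("conformational-change vector has zero norm")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.abs(u @ cc_vec) / (norms * nc)
    vals[norms < ZERO_DISPLACEMENT_A] = np.nan
    return OverlapSeries(times_ps=trajectory.times_ps, values=vals)


def rmsd_series(trajectory: Trajectory) -> np.ndarray:
    """Per-frame RMSD (angstrom): root mean squared nodal displacement."""
    u = trajectory.displacements.reshape(trajectory.n_frames, -1, 3)
    return np.sqrt(np.mean(np.sum(u**2, axis=2), axis=1))


def _static_rmsd(u_static: np.ndarray) -> float:
    u = np.asarray(u_static, dtype=float).reshape(-1, 3)
    return float(np.sqrt(np.mean(np.sum(u**2, axis=1))))


def dynamic_amplification(trajectory: Trajectory, static_u: np.ndarray) -> float:
    """max_t RMSD(t) divided by the RMSD of the static response."""
    denom = _static_rmsd(static_u)
    if denom == 0:
        raise UndefinedOverlapError("static response has zero RMSD")
    return float(np.max(rmsd_series(trajectory)) / denom)


def cosine_nonlinearity(trajectory: Trajectory) -> np.ndarray:
    """Per-residue cosine between each instantaneous step and the first step.

    Returns an (N, frames-1) matrix in [-1, 1]; a perfectly linear
    back-and-forth motion yields only +1 and -1, while curvilinear
    motion sweeps intermediate values.  Steps of zero norm are NaN.
    """
    if trajectory.n_frames < 3:
        raise ValueError("need at least 3 frames to evaluate step directions")
    u = trajectory.displacements.reshape(trajectory.n_frames, -1, 3)
    steps = np.diff(u, axis=0)  # (frames-1, N, 3)
    first = steps[0]  # (N, 3)
    dots = np.einsum("tnc,nc->tn", steps, first)
    norms = np.linalg.norm(steps, axis=2) * np.linalg.norm(first, axis=1)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = dots / norms
    cos[norms == 0] = np.nan
    return cos.T


def pca(conformations: np.ndarray) -> PCAResult:
    """PCA of an (s, 3N) matrix of conformations.

    The covariance over conformations is eigendecomposed; components are
    sorted by descending eigenvalue and scores are the centered rows
    projected onto them.  For s << 3N the decomposition runs through the
    SVD of the centered matrix, which spans the same column space.
    """
    x = np.asarray(conformations, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 conformations (rows)")
    s = x.shape[0]
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD route: covariance eigenvalues are singular values^2 / s
    u_svd, sing, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = sing**2 / s
    components = vt.T
    scores = xc @ components
    return PCAResult(
        eigenvalues=eigenvalues, components=components, scores=scores, mean=mean
    )


def collectivity(displacement: np.ndarray) -> float:
    """Entropy-based degree of collectivity kappa in (0, 1].

    With d_i^2 the squared displacement magnitude of residue i and
    alpha chosen so sum_i alpha d_i^2 = 1,

        kappa = (1/N) exp(-sum_i alpha d_i^2 ln(alpha d_i^2)).

    kappa = 1 iff every residue moves with the same magnitude; a single
    moving residue gives kappa = 1/N.
    """
    d2 = np.sum(np.asarray(displacement, dtype=float).reshape(-1, 3) ** 2, axis=1)
    total = d2.sum()
    if total == 0:
        raise UndefinedOverlapError("collectivity undefined for a zero vector")
    w = d2 / total
    nz = w[w > 0]
    entropy = -np.sum(nz * np.log(nz))
    return float(np.exp(entropy) / d2.size)


#: CI-scale scan grid: 25 frequencies, one damping value, 5 force patterns.
DESK_PRESET = {
    "frequencies_thz": np.linspace(0.02, 0.5, 25).tolist(),
    "damping_values": [0.01],
    "pattern_seeds": list(range(5)),
}

#: Production grid: 500 frequencies in 0.001-0.5 THz, three damping
#: values, 100 force patterns (150,000 simulations).
PAPER_PRESET = {
    "frequencies_thz": np.linspace(0.001, 0.5, 500).tolist(),
    "damping_values": [0.001, 0.01, 0.1],
    "pattern_seeds": list(range(100)),
}


def frequency_scan(
    modes: ModalDecomposition,
    cc: ConformationalChange | np.ndarray,
    frequencies_thz: Sequence[float],
    damping_values: Sequence[float],
    pattern_seeds: Sequence[int],
    amplitude_bound: float = 1.0e-10,
    cycles: int = 10,
    steps_per_cycle: int = 100,
    include_transient_window: bool = True,
    transient_cap_ps: float = 2000.0,
    transient_time_constants: float = 5.0,
) -> ScanResult:
    """Max overlap and RMSD amplification over a (f_F, xi, seed) grid.

    For each triple the analytic trajectory is evaluated over ``cycles``
    forcing periods; by default the evaluation window starts after a
    transient window of five decay constants of the slowest mode (capped),
    so the statistics describe the near-steady regime.  Setting
    ``include_transient_window=False`` starts the window at t = 0.
    The result is bit-reproducible given the seed list.
    """
    cc_vec = cc.cc_vector if isinstance(cc, ConformationalChange) else np.asarray(cc)
    rows = []
    optima = []
    for xi in damping_values:
        for seed in pattern_seeds:
            pattern = random_force_pattern(
                modes.n_nodes, seed=seed, amplitude_bound=amplitude_bound
            )
            u_static = static_response(modes, pattern)
            s_rmsd = _static_rmsd(u_static)
            best = None
            for f in frequencies_thz:
                exc = HarmonicExcitation(
                    pattern=pattern, frequency_thz=f, damping=xi
                )
                times = _eval_window_grid(
                    modes, exc, cycles, steps_per_cycle,
                    include_transient_window, transient_cap_ps,
                    transient_time_constants,
                )
                coeff = modal_response_coefficients(modes, exc)
                p = principal_coordinates(coeff, times)
                traj = synthesize_trajectory(modes, p, times)
                o = overlap_series(traj, cc_vec)
                max_rmsd = float(np.max(rmsd_series(traj)))
                row = {
                    "frequency_thz": float(f),
                    "damping": float(xi),
                    "seed": int(seed),
                    "max_overlap": o.max,
                    "max_dynamic_rmsd": max_rmsd,
                    "static_rmsd": s_rmsd,
                    "amplification": max_rmsd / s_rmsd,
                }
                rows.append(row)
                if best is None or row["max_overlap"] > best["max_overlap"]:
                    best = row
            optima.append(
                {
                    "damping": float(xi),
                    "seed": int(seed),
                    "optimal_frequency_thz": best["frequency_thz"],
                    "max_overlap": best["max_overlap"],
                }
            )
    return ScanResult(table=pd.DataFrame(rows), optima=pd.DataFrame(optima))


def _eval_window_grid(
    modes, excitation, cycles, steps_per_cycle, include_transient, cap_ps,
    time_constants=5.0,
):
    """Grid restricted to the evaluation window: ``cycles`` forcing
    periods, starting after the transient window when requested."""
    from .constants import PICOSECOND as PS

    period = excitation.period_ps
    t0 = 0.0
    if include_transient:
        xi = excitation.damping_vector(modes.n_internal)
        tau = 1.0 / (xi[0] * modes.omega_internal[0]) / PS
        t0 = min(time_constants * tau, cap_ps)
    dt = period / steps_per_cycle
    n = int(np.ceil(cycles * period / dt))
    return t0 + np.arange(n + 1) * dt
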