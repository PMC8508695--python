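"""Static and time-dependent response of the network to external forces.

A force pattern with components drawn uniformly from
``(-F0, +F0)`` newton (default ``F0 = 1e-10`` N) models one
frequency-resolved component of the random collisions a protein
experiences in solution.  Applied statically, the displacement is the
pseudo-inverse Hessian acting on the force.  Applied harmonically,
``F(t) = F sin(omega_F t)``, the equations of motion

    M u'' + C u' + H u = F(t)

decouple in the mass-orthonormal mode basis into independent damped
driven oscillators, each with the closed-form underdamped solution

    p_n(t) = exp(-xi_n omega_n t) [A_n cos(omega_dn t) + B_n sin(omega_dn t)]
             + C_n sin(omega_F t + phi_n)

under resting initial conditions.  The nodal trajectory is the modal
superposition ``u(t) = Delta p(t)`` over the internal modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGSTROM,
    DEFAULT_FORCE_BOUND_N,
    PICOSECOND,
    thz_to_rad_s,
)
from .elastic_network import ModalDecomposition
from .errors import RegimeError

__all__ = [
    "ForcePattern",
    "HarmonicExcitation",
    "ModalResponse",
    "Trajectory",
    "random_force_pattern",
    "static_response",
    "modal_response_coefficients",
    "principal_coordinates",
    "synthesize_trajectory",
    "default_time_grid",
    "respond",
]


@dataclass
class ForcePattern:
    """A 3N-component force vector (newton), regenerable from its seed."""

    components: np.ndarray
    amplitude_bound: float = DEFAULT_FORCE_BOUND_N
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if np.any(np.abs(self.components) > self.amplitude_bound * (1 + 1e-12)):
            raise ValueError("force components exceed the amplitude bound")


@dataclass
class HarmonicExcitation:
    """A force pattern oscillating harmonically at ``frequency_thz``.

    ``damping`` is the dimensionless modal damping ratio xi: a scalar
    applied to every mode (the usual choice) or a per-internal-mode
    vector.  Only the underdamped regime (0 < xi < 1) is supported.
    """

    pattern: ForcePattern
    frequency_thz: float
    damping: float | np.ndarray = 0.01

    def __post_init__(self) -> None:
        if self.frequency_thz <= 0:
            raise ValueError(f"forcing frequency must be positive, got {self.frequency_thz}")
        xi = np.atleast_1d(np.asarray(self.damping, dtype=float))
        if np.any(xi <= 0) or np.any(xi >= 1):
            raise RegimeError(
                f"damping ratio must satisfy 0 < xi < 1 (underdamped); got {self.damping}"
            )

    @property
    def omega_forcing(self) -> float:
        """Forcing angular frequency, rad/s."""
        return thz_to_rad_s(self.frequency_thz)

    @property
    def period_ps(self) -> float:
        """Forcing period, ps."""
        return 1.0 / self.frequency_thz  # 1/THz = ps

    def damping_vector(self, n_modes: int) -> np.ndarray:
        xi = np.atleast_1d(np.asarray(self.damping, dtype=float))
        if xi.size == 1:
            return np.full(n_modes, xi[0])
        if xi.size != n_modes:
            raise ValueError(f"damping vector has {xi.size} entries, expected {n_modes}")
        return xi


@dataclass
class ModalResponse:
    """Closed-form response coefficients, one entry per internal mode.

    All arrays are in SI modal units; ``amplitude_steady`` is C_n,
    ``phase`` is phi_n in (-pi, 0], ``transient_cos``/``transient_sin``
    are A_n/B_n for resting initial conditions, ``omega_damped`` is the
    reduced frequency and ``beta`` the forcing-to-natural frequency
    ratio.
    """

    amplitude_steady: np.ndarray
    phase: np.ndarray
    transient_cos: np.ndarray
    transient_sin: np.ndarray
    omega_damped: np.ndarray
    beta: np.ndarray
    omega_modes: np.ndarray
    damping: np.ndarray
    omega_forcing: float

    def __post_init__(self) -> None:
        for name in (
            "amplitude_steady",
            "phase",
            "transient_cos",
            "transient_sin",
            "omega_damped",
            "beta",
        ):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")


@dataclass
class Trajectory:
    """Time-indexed displacement field of the network.

    ``displacements`` is (n_frames, 3N) in angstrom; ``times_ps`` the
    matching uniform time grid.  ``metadata`` records the excitation
    (pattern seed, forcing frequency, damping) for provenance.
    """

    times_ps: np.ndarray
    displacements: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape[0] != self.times_ps.shape[0]:
            raise ValueError("frame count must match the time grid length")

    @property
    def n_frames(self) -> int:
        return self.times_ps.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.displacements.shape[1] // 3


def random_force_pattern(
    n_nodes: int,
    seed: int,
    amplitude_bound: float = DEFAULT_FORCE_BOUND_N,
) -> ForcePattern:
    """3N i.i.d. draws from Uniform(-bound, +bound) N, reproducible by seed."""
    if n_nodes < 2:
        raise ValueError(f"need at least 2 nodes, got {n_nodes}")
    rng = np.random.default_rng(seed)
    comps = rng.uniform(-amplitude_bound, amplitude_bound, size=3 * n_nodes)
    return ForcePattern(components=comps, amplitude_bound=amplitude_bound, rng_seed=seed)


def _modal_forces(modes: ModalDecomposition, force: np.ndarray) -> np.ndarray:
    """Projections delta_n^T F over the internal modes."""
    return modes.internal_modes.T @ force


def static_response(
    modes: ModalDecomposition,
    pattern: ForcePattern,
    hessian: np.ndarray | None = None,
) -> np.ndarray:
    """Displacement (angstrom, 3N) under the pattern applied statically.

    u = sum_n (delta_n^T F / omega_n^2) delta_n over the internal modes,
    i.e. the pseudo-inverse Hessian in the mass-orthonormal basis acting
    on F.  If ``hessian`` is supplied the identity ``H u = F`` (minus
    the rigid-body component of F) is verified to 1e-8 relative.
    """
    force = pattern.components
    q = _modal_forces(modes, force)
    lam = modes.omega_internal**2
    u_si = modes.internal_modes @ (q / lam)

    rigid = modes.mode_shapes[:, : modes.rigid_mode_count]
    # F expanded in the mass-orthonormal basis: F = sum_n (delta_n^T F) M delta_n
    elastic_frac = np.linalg.norm(q) / max(
        np.linalg.norm(modes.mode_shapes.T @ force), 1e-300
    )
    if elastic_frac < 1e-8:
        warnings.warn(
            "force pattern lies (almost) entirely along rigid-body modes; "
            "the elastic response is zero",
            stacklevel=2,
        )
    if hessian is not None:
        m_delta_r = np.linalg.solve(modes.mode_shapes.T, np.eye(len(force)))[
            :, : modes.rigid_mode_count
        ]
        f_elastic = force - m_delta_r @ (rigid.T @ force)
        resid = np.linalg.norm(hessian @ u_si - f_elastic)
        if resid > 1e-8 * max(np.linalg.norm(f_elastic), 1e-300):
            raise FloatingPointError(
                f"pseudo-inverse residual {resid:.3e} exceeds tolerance"
            )
    return u_si / ANGSTROM


def modal_response_coefficients(
    modes: ModalDecomposition,
    excitation: HarmonicExcitation,
) -> ModalResponse:
    """Steady-state and transient coefficients for every internal mode.

    C_n = delta_n^T F / (omega_n^2 sqrt((1-beta_n^2)^2 + (2 xi_n beta_n)^2)),
    phi_n = -atan2(2 xi_n beta_n, 1 - beta_n^2), which runs continuously
    from 0 (quasi-static) through -pi/2 (resonance) to -pi (inertial
    limit).  A_n and B_n enforce p_n(0) = 0 and p_n'(0) = 0.
    """
    omega_n = modes.omega_internal
    xi = excitation.damping_vector(omega_n.size)
    omega_f = excitation.omega_forcing
    q = _modal_forces(modes, excitation.pattern.components)

    beta = omega_f / omega_n
    denom = np.sqrt((1 - beta**2) ** 2 + (2 * xi * beta) ** 2)
    c = q / (omega_n**2 * denom)
    phi = -np.arctan2(2 * xi * beta, 1 - beta**2)
    omega_d = omega_n * np.sqrt(1 - xi**2)
    a = -c * np.sin(phi)
    b = (xi * omega_n * a - c * omega_f * np.cos(phi)) / omega_d
    return ModalResponse(
        amplitude_steady=c,
        phase=phi,
        transient_cos=a,
        transient_sin=b,
        omega_damped=omega_d,
        beta=beta,
        omega_modes=omega_n,
        damping=xi,
        omega_forcing=omega_f,
    )


def principal_coordinates(
    response: ModalResponse,
    times_ps: np.ndarray,
) -> np.ndarray:
    """Evaluate p_n(t) on the grid; returns (n_internal_modes, n_frames).

    The transient and steady-state parts are summed exactly as in the
    closed-form underdamped solution; resting initial conditions give
    p_n(0) = 0 and dp_n/dt(0) = 0 by construction.
    """
    t = np.asarray(times_ps, dtype=float) * PICOSECOND  # s, shape (T,)
    xi_w = (response.damping * response.omega_modes)[:, None]
    wd = response.omega_damped[:, None]
    decay = np.exp(-xi_w * t[None, :])
    transient = decay * (
        response.transient_cos[:, None] * np.cos(wd * t[None, :])
        + response.transient_sin[:, None] * np.sin(wd * t[None, :])
    )
    steady = response.amplitude_steady[:, None] * np.sin(
        response.omega_forcing * t[None, :] + response.phase[:, None]
    )
    return transient + steady


def synthesize_trajectory(
    modes: ModalDecomposition,
    p: np.ndarray,
    times_ps: np.ndarray,
    metadata: dict | None = None,
) -> Trajectory:
    """Modal superposition u(t) = Delta p(t) over internal modes, in angstrom."""
    if p.shape[0] != modes.n_internal:
        raise ValueError(
            f"p has {p.shape[0]} mode rows, expected {modes.n_internal}"
        )
    u_si = modes.internal_modes @ p  # (3N, T) in m
    return Trajectory(
        times_ps=np.asarray(times_ps, dtype=float),
        displacements=u_si.T / ANGSTROM,
        metadata=dict(metadata or {}),
    )


def default_time_grid(
    modes: ModalDecomposition,
    excitation: HarmonicExcitation,
    cycles: int = 10,
    steps_per_cycle: int = 100,
    transient_cap_ps: float = 2000.0,
    include_transient_window: bool = True,
    transient_time_constants: float = 5.0,
) -> np.ndarray:
    """Uniform grid (ps): an optional transient window plus ``cycles`` periods.

    The transient window is ``transient_time_constants`` decay time
    constants 1 / (xi * omega_7) of the slowest mode — capped at
    ``transient_cap_ps``; the sampling step is the forcing period
    divided by ``steps_per_cycle``.  When the forcing frequency far
    exceeds the slowest mode the steady amplitude is much smaller than
    the ringing transient, and isolating the steady state needs roughly
    ln(omega_F / omega_7) extra time constants.
    """
    period = excitation.period_ps
    xi = excitation.damping_vector(modes.n_internal)
    t_transient = 0.0
    if include_transient_window:
        tau = 1.0 / (xi[0] * modes.omega_internal[0]) / PICOSECOND
        t_transient = min(transient_time_constants * tau, transient_cap_ps)
    dt = period / steps_per_cycle
    total = t_transient + cycles * period
    n_steps = int(np.ceil(total / dt))
    return np.arange(n_steps + 1) * dt


def respond(
    modes: ModalDecomposition,
    excitation: HarmonicExcitation,
    times_ps: np.ndarray | None = None,
    **grid_kwargs,
) -> Trajectory:
    """Full analytic trajectory under a harmonic excitation.

    Convenience front end: coefficients, principal coordinates on the
    (default or supplied) grid, and the modal superposition, with the
    excitation recorded in the trajectory metadata.
    """
    if times_ps is None:
        times_ps = default_time_grid(modes, excitation, **grid_kwargs)
    coeff = modal_response_coefficients(modes, excitation)
    p = principal_coordinates(coeff, times_ps)
    meta = {
        "frequency_thz": excitation.frequency_thz,
        "damping": np.atleast_1d(excitation.damping).tolist(),
        "pattern_seed": excitation.pattern.rng_seed,
        "amplitude_bound_n": excitation.pattern.amplitude_bound,
    }
    return synthesize_trajectory(modes, p, times_ps, metadata=meta)
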