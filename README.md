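# anmresponse

Dynamic perturbation response of Cα elastic network models.

Proteins switch between conformations (open ↔ closed) while they work, and
coarse-grained elastic network models predict the *direction* of those
transitions surprisingly well. Two classic routes exist: compare the observed
change against individual normal modes of the anisotropic network model
(ANM), or against the static linear response to applied forces. `anmresponse`
combines them: it applies harmonic force patterns — random in space, with a
defined frequency in time, a proxy for the frequency components of solvent
collisions — to a mass- and damping-augmented ANM and computes the **full
time-dependent response** analytically, then measures how well the induced
motion reproduces an observed conformational change.

## Model

Each residue is a node at its Cα position with the residue's average mass
`m_i`; node pairs within a cutoff `r_c` (default 15 Å) are joined by springs
of uniform stiffness `γ`. Free vibrations solve the generalized eigenproblem

    (H − ω_n² M) δ_n = 0,        Δᵀ M Δ = I,

where `H` is the 3N×3N Hessian of the Hookean energy and `M` the diagonal
mass matrix; the six zero-frequency modes are rigid-body motions. `γ` is
calibrated so the mean predicted thermal B-factor,

    B_i = (8π²/3) k_B T Σ_{n≥7} |δ_{n,i}|² / ω_n²,

matches the mean experimental B-factor of the crystal structure.

Under a harmonic force pattern `F(t) = F sin(ω_F t)` with modal damping
ratios `ξ_n < 1`, the equations of motion `M ü + C u̇ + H u = F(t)` decouple
into damped driven oscillators with the closed-form underdamped solution

    p_n(t) = e^(−ξ_n ω_n t) [A_n cos(ω_{d,n} t) + B_n sin(ω_{d,n} t)]
             + C_n sin(ω_F t + φ_n),

    C_n = δ_nᵀF / (ω_n² √((1−β_n²)² + (2ξ_n β_n)²)),   β_n = ω_F/ω_n,

with `A_n`, `B_n` fixed by resting initial conditions. The trajectory is the
modal superposition `u(t) = Δ p(t)` over the internal modes.

Agreement with an observed transition `{CC}` (superposed target minus
reference coordinates) is measured by the overlap
`O(t) = |u(t)ᵀCC| / (‖u(t)‖ ‖CC‖)`, alongside RMSD, the dynamic-to-static
RMSD amplification, per-residue cosine non-linearity, PCA of the generated
ensemble and the collectivity degree of the change.

## Worked example

A synthetic hinge protein — two compact lobes bridged by a soft neck, whose
closed form rotates one lobe by 20° — stands in for an open/closed crystal
pair:

```python
import anmresponse as anm

fix = anm.make_hinge(seed=0)
network = anm.build_network(fix.open_structure, cutoff=fix.cutoff, gamma=0.1)
modes = anm.modal_analysis(anm.hessian(network),
                           anm.mass_matrix(fix.open_structure))
f7 = modes.frequencies_thz[modes.rigid_mode_count]
print(f"N = {fix.open_structure.n_nodes}, lowest internal mode f7 = {f7*1e3:.1f} GHz")

cc = anm.conformational_change_vector(fix.open_structure, fix.closed_structure)
print(f"mode-7 overlap with the hinge change: "
      f"{anm.overlap(modes.internal_modes[:, 0], cc):.2f}")
print(f"collectivity of the change: {anm.collectivity(cc.cc_vector):.2f}")

pattern = anm.random_force_pattern(fix.open_structure.n_nodes, seed=3)
excitation = anm.HarmonicExcitation(pattern=pattern, frequency_thz=f7,
                                    damping=0.01)
trajectory = anm.respond(modes, excitation, transient_cap_ps=1e9)
series = anm.overlap_series(trajectory, cc)
amp = anm.dynamic_amplification(trajectory,
                                anm.static_response(modes, pattern))
print(f"max overlap of the driven response: {series.max:.2f}")
print(f"dynamic amplification vs static forcing: {amp:.1f}")
```

prints

```
N = 19, lowest internal mode f7 = 16.9 GHz
mode-7 overlap with the hinge change: 0.94
collectivity of the change: 0.49
max overlap of the driven response: 0.95
dynamic amplification vs static forcing: 48.7
```

Driving the network at its lowest internal frequency reproduces the hinge
transition better than the best single mode does (0.95 vs 0.94 here), and a
completely random force pattern amplified ~49× at resonance (ξ = 0.01) —
the mechanism by which weak, spatially unstructured perturbations can drive
a large collective conformational change.

The same workflow runs from the shell: `anmresponse fixture`, `modes`,
`bfactors`, `respond`, `analyze` and `scan` (see `anmresponse --help`); the
`scan` subcommand sweeps frequency × damping × force-pattern grids
(`--preset desk` for a quick 25×1×5 grid, `--preset paper` for the full
500×3×100 production grid).

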