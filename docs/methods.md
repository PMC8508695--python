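# Methods

## Model and assumptions

The protein is coarse-grained to one node per residue at the Cα position.
Nodes closer than a cutoff `r_c` are joined by identical Hookean springs of
stiffness `γ`; the crystal structure is the assumed equilibrium, so the
energy is `½ Σ γ (|r_ij| − |r⁰_ij|)²` over connected pairs and the model is
valid in the small-amplitude, harmonic regime. Each off-diagonal 3×3 Hessian
block is `−γ/r² · d dᵀ` with `d` the separation vector; diagonal blocks are
the negated row sums, which guarantees zero elastic cost for rigid
translations. Residue masses make the spectrum quantitative: the generalized
eigenproblem `(H − ω²M) δ = 0` is solved densely (via
`scipy.linalg.eigh(H, M)`), yielding mass-orthonormal modes. A full dense
solve is used throughout — for single-domain proteins 3N stays in the low
thousands and a partial solver would complicate the rigid-mode bookkeeping
for no real gain.

Damping is modal: a single dimensionless ratio `ξ` applied to every internal
mode (a per-mode vector is accepted by the data model). This is equivalent
to assuming the damping matrix diagonalizes in the mode basis. Only the
underdamped regime `0 < ξ < 1` is implemented; requesting `ξ ≥ 1` is an
error, not a silent switch to the overdamped solution. Whether real protein
vibrations are underdamped is an open experimental question; the package
takes underdamping as its working regime and makes it explicit.

## Units

Internal computation is entirely in SI (kg, m, s, N/m, rad/s). Interfaces
speak Å, amu, ps, THz and Å²; `constants.py` owns every conversion factor.
Natural frequencies are reported as `f = ω/2π` in THz (GHz for the lowest
modes). Force components are newtons; the default per-component bound of
the random patterns is 1×10⁻¹⁰ N. Because the model is linear, the force
scale cancels in every overlap and amplification ratio and only sets the
absolute displacement scale.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `r_c` | 15 Å | spring cutoff, inclusive (`d ≤ r_c`) |
| `γ` | calibrated | uniform spring constant, N/m |
| `T` | 300 K | temperature in the B-factor formula |
| `ξ` | 0.01 | modal damping ratio |
| force bound | 1e-10 N | uniform-distribution half-width per component |
| cycles | 10 | forcing periods in the evaluation window |
| steps/cycle | 100 | sampling density of the time grid |

The cutoff comparison is inclusive (`≤`) — an arbitrary but fixed choice
needed for reproducibility at exact-distance edge cases. Calibration
exploits `B ∝ 1/γ` (mode shapes are γ-independent for uniform springs): one
trial solve fixes `γ = γ_trial · mean(B_calc)/mean(B_exp)` exactly, and the
result scales linearly with the assumed `T`, which B-factor data alone
cannot pin down. Masses come from a built-in 20-entry table of average
residue masses (amino acid minus water); unknown residue names fall back to
the table mean with a warning. Residues with insertion codes or non-standard
names are kept if they have a Cα; residues lacking one are skipped.

## Rigid modes and degeneracy

Eigenvalues below `1e-8 × λ_max` count as zero. A generic connected 3-D
network must produce exactly six (three translations, three rotations); a
collinear geometry such as the two-node fixture produces five, because
rotation about the bond axis carries no elastic energy. `modal_analysis`
takes the expected count as a parameter (default 6, `None` to accept what is
found) and raises a degeneracy error otherwise, reporting the eigenvalue gap
— extra near-zero modes almost always mean an internal mechanism (e.g. a
floppy collinear neck), which invalidates the thermal sums. Rigid modes are
excluded from every physical sum: B-factors, the static pseudo-inverse and
the dynamic superposition.

## Static response convention

The static displacement is `u = Σ_{n≥7} (δ_nᵀF/ω_n²) δ_n` in the
mass-orthonormal basis. This differs from the Euclidean Moore–Penrose
pseudo-inverse of `H` when the force has rigid content: here the rigid part
of `F` is removed by the *mass-weighted* projection. That convention is
deliberate — it is the exact `ω_F → 0` limit of the dynamic solution, so the
quasi-static consistency between the two code paths is an identity rather
than an approximation. When the Hessian is supplied, the implementation
verifies `H u = F − F_rigid` to 1e-8 relative.

## Time grid and the transient window

The closed-form solution has a decaying transient (time constant
`1/(ξ ω_7)` for the slowest mode) plus the steady harmonic. The default
trajectory covers a transient window of 5 time constants (capped at
2000 ps) followed by 10 forcing cycles sampled at 100 steps per cycle;
the evaluation window of a scan starts after the transient by default and
can be set to start at t = 0. One caveat matters when forcing far above the
spectrum: the steady amplitude falls as `1/ω_F²` while the transient rings
the soft modes at full strength, so isolating the steady state needs roughly
`ln(ω_F/ω_7)` additional time constants. Steady-state comparisons in the
tests therefore use a longer window (12–14 time constants, uncapped); the
5-constant default is kept for production use near the spectrum, where it is
ample.

Phases use the two-argument arctangent, `φ = −atan2(2ξβ, 1−β²)`, which runs
continuously from 0 (quasi-static) through −π/2 (resonance) to −π (inertial
limit). The transient constants enforce `p(0) = 0` and `ṗ(0) = 0` exactly;
the velocity condition fixes the second transient coefficient to
`B = (ξω A − C ω_F cos φ)/ω_d`, with the *forcing* frequency in the second
term.

## Trajectory metrics

Overlap is `|uᵀCC|/(‖u‖‖CC‖)`; frames with displacement norm below 1e-6 Å
have no defined direction and are recorded as missing rather than zero.
Superposition is Kabsch (SVD with reflection correction) over residues
paired by (chain, residue number, insertion code), not serial order.
Collectivity uses the entropy form `κ = (1/N) exp(−Σ α d_i² ln α d_i²)`
with `Σ α d_i² = 1`; it is 1 for uniform motion and 1/N for a single moving
residue. PCA runs through the SVD of the centered conformation matrix
(identical spectrum to the covariance eigendecomposition, numerically better
when frames ≪ 3N); reference structures can be projected post hoc as
supplementary points. The scan driver records, per (frequency, damping,
seed) triple, the window-maximum overlap, maximum dynamic RMSD, static RMSD
and their ratio, and reduces to the optimum frequency per (damping, seed);
it is bit-reproducible given the seed list.

## Synthetic fixtures: what they emulate and what they do not

The diatomic fixture provides an exact analytic anchor
(`ω = √(2γ/m)`, five rigid modes). The hinge fixture emulates the essential
geometry of a two-domain protein with an open/closed pair: two compact
random lobes bridged by a narrow three-node neck, the closed partner
obtained by rigidly rotating one lobe 20° about the neck axis. The neck is
spread along z and narrow in y so that in-plane bending — the hinge motion —
is the softest internal mode; torsion about the lobe axis is blocked by
anchoring cross-lobe springs off-axis (an all-collinear neck creates exact
zero-energy torsion mechanisms). Generation verifies connectivity, the
six-rigid-mode count and that the lowest mode overlaps the hinge
displacement above 0.7 (and above mode 20's overlap), reseeding otherwise,
so every returned fixture has a known, collective target direction. Note
that after least-squares superposition a one-lobe rotation appears as the
two lobes counter-rotating — localization on the moving lobe is not
preserved, and tests assert the counter-rotation instead.

What the fixtures do not capture: realistic contact topology and packing
density of a protein fold, sequence-dependent mass heterogeneity,
experimental B-factor contamination by crystal contacts and rigid-body
disorder, and anharmonicity of real transitions. Passing tests demonstrate
the mechanics of the method — eigenproblem, analytic dynamics, calibration,
metrics — not the biological accuracy of any particular prediction.
Synthetic "experimental" B-factors are generated from the model itself at a
known `γ*`, optionally with mean-one lognormal noise, so calibration
round-trips are exact by construction in the noise-free case.

## Numerical choices

- Zero-displacement overlap frames: missing (NaN), threshold 1e-6 Å.
- Eigen-residual guarantee: `‖Hδ − ω²Mδ‖ ≤ 1e-8 ‖H‖ ‖δ‖` per kept mode.
- Altloc resolution: highest occupancy, ties to the first listed.
- Kabsch reflection fix: flip the sign of the last singular vector when
  `det < 0`, guaranteeing a proper rotation.
- Random numbers: `numpy.random.default_rng` throughout; every force
  pattern and fixture records its seed and is bit-reproducible.
- Test problem sizes: 2–19 nodes; the direct ODE cross-checks
  (`solve_ivp`, DOP853, rtol 1e-11) run on ≤5-node networks over 20
  forcing cycles, which keeps the whole suite in seconds while exercising
  every code path at full numerical strictness.

## Known limitations

- Uniform springs only; distance-weighted variants (`γ ∝ r^−p`) are out of
  scope.
- No overdamped or stochastic (Langevin) forcing; single-frequency harmonic
  excitation only.
- The absolute frequency scale inherits the `T`-degeneracy of the B-factor
  calibration: reported GHz values assume 300 K unless stated.
- B-factor calibration trusts the experimental column as pure internal
  dynamics; crystal-contact and refinement contributions bias `γ` upward.
- The linear model says nothing about barrier heights or kinetics — overlap
  measures direction similarity, not a transition pathway.
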