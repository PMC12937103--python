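# Methods

This note documents the models, numerical choices and limitations of
`gpmlmm` in the package's own terms.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Energy decomposition and descriptors

The solvated (QM/MM electrostatic-embedding) energy is split into an
isolated-molecule term and an environment-induced change,
`E = E_vac + E_env`, and the two terms are modelled independently.

The internal geometry is encoded by the inverse-distance descriptor: the
strict upper triangle of the matrix 1/‖r_a − r_b‖, flattened in
lexicographic pair order (a, b), a < b.  Any fixed order would do —
kernels consume only distances and dot products of descriptors — but
serialization requires one canonical choice.  The environment is encoded
by the electrostatic potential of the MM point charges at each ML atom,
V_a = Σ_m q_m/‖r_a − r_m‖, evaluated in atomic units (positions are
converted Å → Bohr with 1 Å = 1/0.529177210903 Bohr; all conversion
constants live in `gpmlmm.units`).  Both descriptors carry closed-form
Jacobians with respect to ML and MM coordinates; finite differences
appear only as test oracles (central differences, h = 10⁻⁵ in the
differentiated variable's unit).

Units elsewhere: energies kcal/mol, forces kcal/mol/Å (declared in the
dataset and model archives), charges e, dipoles a.u., time fs, masses
amu.

## Kernels and derivative blocks

The vacuum kernel is a Matérn-5/2 on the descriptor distance
d = ‖χ_i − χ_j‖:

    K(d) = (1 + c d + c²d²/3) e^{−c d},  c = √5/λ.

The standard Matérn-5/2 form is used; the lengthscale λ is expressed in
the ID descriptor's Å⁻¹ units, and the hyperparameter grids below refer
to those units.  The radial derivatives are implemented through the two
smooth auxiliaries φ(d) = K′(d)/d = −(c²/3)(1 + c d)e^{−cd} and
ψ(d) = φ′(d)/d = (c⁴/3)e^{−cd}, which avoid any 0/0 at coincident
inputs.

The environment kernel multiplies the internal kernel by a second-order
polynomial ("direct") kernel on the potentials,
K_env = [(θ + V_i·V_j)² − θ²] · K_int, with θ = 1 fixed.  Subtracting θ²
makes the kernel vanish whenever either argument's potential is zero, so
an environment model predicts *exactly* zero environment energy and
forces in vacuum, while its potential derivatives (the charges) remain
finite — the gas-phase charge vector is the V = 0 limit of the same
model.

A fixed derivative convention is used everywhere: subscript 1 is the
first kernel argument, subscript 2 the second; training configurations
are always placed in argument 1 and queries in argument 2, exploiting
kernel symmetry.  All blocks needed by training and prediction are at
most first order per argument (value, ∇₁, ∇₂, the mixed Hessian ∇₁∇₂,
per-atom potential derivatives ∂/∂V, and their mixed combinations), so
only descriptor Jacobians — never second descriptor derivatives — enter
the chain rule.

Permutational symmetry over chemically equivalent atoms replaces every
block by its group average over permuted arguments, with gradient rows/
columns and per-atom potential components mapped back through the
permutations.  Groups are supplied explicitly as index tuples (the
closure including the identity, e.g. S = 2 for one symmetric atom pair,
S = 6 per methyl group); automatic detection of equivalent atoms is out
of scope.  Internally, symmetrization is implemented by expanding each
sample into S "virtual" copies whose Jacobians are pre-mapped to the
original coordinates, which makes the Gram assembly a single vectorized
pass; the per-pair API in `gpmlmm.kernels` is value-identical to this
path.

## Training systems

**Vacuum.**  Force-only training solves (∇₁∇₂K + σ_f²I)α = −F; the
energy is then the integral of the force and is defined up to a constant
C = mean(E_i − Ê_i) fixed on the training set.  Joint energy+force
training (useful when force-only data cannot separate distinct minima)
prepends energy rows with σ_e = σ_f and centers the energy targets by
their mean, which C absorbs.

**Environment.**  The residual targets E_env = E − E_vac and
F_env = F − F_vac are always computed inside the trainer from each
sample's total and vacuum labels, never pre-computed by the caller, to
prevent unit drift.  The linear system has three row blocks per sample —
one energy row, 3N force rows, and one total-charge row (one charge row
per sample: Σ_a q_a = Q for each training configuration) — built from
the kernel blocks above.  Defaults: σ_q = 10⁻⁵, θ = 1, σ_f = σ_e.

**Charge-row units.**  The charge observation couples an energy-like
model (kcal/mol) to a potential derivative (a.u.), and q = ∂E/∂V_a holds
in atomic units.  The trainer therefore scales the charge targets and
σ_q (both taken in e) by 627.509474 kcal/mol per Hartree when assembling
the system and scales predicted charges back, so the constraint
tolerance set by σ_q remains in e.

**Solver.**  Symmetric positive-definite Cholesky factorization, with a
jitter ladder 10⁻¹⁰ … 10⁻⁶ (relative to the mean diagonal) added on
failure; if the ladder is exhausted the error reports the smallest
eigenvalue estimate.

**Δ-learning.**  A delta model is trained on residuals between
high-level labels and base-model predictions (ΔE = E_high − Ê_base,
ΔF = F_high − F̂_base; for environment deltas also ΔQ = Q − Σq̂_base)
with the same machinery, and composed by strict addition at prediction
time.

**Model selection.**  Grid search with k-fold cross-validation (default
k = 4), scored by held-out force RMSE — chosen because forces are the
one label every model kind shares.  Fold
assignment is contiguous blocks after a seeded shuffle; the seed is
recorded in the CV table.  Default grids: λ ∈ {10, 20, 30}, vacuum
σ ∈ {10⁻⁵, 10⁻⁴, 10⁻³}, environment σ ∈ {10⁻⁴, 10⁻³, 10⁻²}.  (For the
built-in toy system, whose descriptor spread is ~0.1 Å⁻¹, λ ≈ 1 is the
appropriate scale; the grids are fully configurable.)

**Metrics.**  RMSE uses the error count N for energies, 3·N·N_QM for
forces and 3N for dipoles — i.e. a plain element-wise mean over the
stacked arrays; MAE likewise.

## Artificial environments

Around each molecule, four layers of points are placed on the fused
outer surface of atom-centred spheres of radius
r_vdW(element) + 3 Å + ℓ·2 Å (ℓ = 0..3), cut off at 11 Å.  "Minimum
distance from the molecule" is interpreted as added to per-element
Bondi van-der-Waals radii (a flat-offset mode ignoring r_vdW is a config
switch, since the phrase equally supports it).  Sphere surfaces are
deterministic equal-area spiral (Fibonacci) lattices at a configured
area density (default 1 pt/Å²; scaled-down densities in tests).  The
1.3 Å discard is point-to-point thinning, greedy in layer-major
generation order — point-to-atom would be vacuous given the 3 Å minimum
distance.

The molecular ESP at the surviving points is computed from fixed atomic
charges (the oracle's gas-phase charges stand in for population-analysis
charges).  n_select points (default 3000) are selected by drawing
ξ ~ U[0, 1) and keeping the smallest ratios ξ_i/p_i, with
p_i = |V_i|/Σ|V_j| exactly as normalized absolute potentials.  Note this
ranked-ratio rule is only *approximately* probability-proportional
selection (exact proportionality would require exponential keys
−ln ξ/p); for weight vectors of moderate spread the win-probability
deviation is second order in the spread, which is why the χ² frequency
check in the tests uses a mildly non-uniform 5-point grid.

Charges are drawn from N(0, σ = 0.2 e) — the σ is taken to be in e —
then damped: q̃ = f(qV)/V with f(x) = (2a/π)arctan(x/a), a = 0.1, which
bounds every single-point interaction |q̃V| ≤ a; at V = 0 the analytic
small-x limit q̃ = (2/π)q applies.  (The small-x slope of f is 2/π
rather than 1, so even weakly interacting sites are mildly rescaled;
the damping is implemented exactly as defined.)  Finally the mean charge
is subtracted, making each environment exactly neutral.

## The analytic reference oracle

The oracle replaces the quantum-chemistry engine in every test and
example:

- E_vac = ½ Σ_p k_p (d_p − d⁰_p)², a pair-distance spring surface.  It
  is written in interatomic distances — not as a Cartesian quadratic
  form — deliberately: a Cartesian quadratic is not an exact function of
  the internal descriptor (it changes under finite rotations that leave
  all distances fixed), which would put a floor under every recovery
  test and break exact single-sample force interpolation.  Its Hessian
  at the reference equals the corresponding quadratic form and drives
  normal-mode sampling.
- q(V) = q⁰ + A·V with A symmetric and rows summing to zero, and
  E_env = (q⁰·V + ½VᵀAV)·627.509… so ∂E/∂V_a equals q_a exactly and
  Σq_a = Q for any environment.  All forces, including the Coulomb
  back-reaction on MM sites, are analytic.

The default toy molecule is a planar 4-atom fragment (C, O, and a
symmetric H pair) so permutational symmetrization is exercised with
S = 2.  Pure distance springs leave out-of-plane motion of a planar
fragment at zero curvature, so the fragment has 5 finite-frequency
modes and sampled geometries stay in-plane.

Normal-mode sampling diagonalizes the mass-weighted Hessian, excludes
zero-frequency (translation/rotation/out-of-plane) modes, and draws each
normal coordinate from a zero-mean normal with the classical thermal
standard deviation √(k_BT/ω²) at a configurable temperature (default
300 K) times an amplitude scale — the displacement-magnitude
distribution is a documented choice exposed in config.  Geometries with
interatomic clashes below a cutoff are redrawn with bounded retries.
The "higher level of theory" for Δ-learning is the same oracle with
springs scaled by 1.1 and a zero-sum shift of q⁰.

What the oracle does *not* emulate: real anharmonicity beyond the
distance-spring form, exchange/charge-transfer and mutual polarization
with the solvent, vdW repulsion (bare point charges are attractive
singularities, so long unconstrained MD inside a fixed environment can
collapse — production QM/MM setups delegate short-range repulsion to the
MD engine), and any conformational multiplicity.  Passing recovery tests
therefore demonstrates the correctness of the regression and derivative
machinery, not chemical accuracy on real systems.

## Dynamics

A BAOAB-splitting Langevin integrator (exact Ornstein-Uhlenbeck "O"
step between velocity-Verlet half-steps) with friction in ps⁻¹;
friction = 0 reduces identically to velocity Verlet.  Velocities are
initialized from per-component Maxwell-Boltzmann draws with the net
linear momentum removed.  Trajectories are bit-reproducible from the
seed.  Kinetic-energy statistics carry the usual O((ωΔt)²) splitting
bias on stiff modes; thermalization tests therefore use soft toy systems
where the bias is far below the stochastic tolerance.  Timestep defaults
to 1 fs with 1 ps⁻¹ friction; the toy-scale runs in the tests use
0.5–1 fs and 10–100 ps, sizes chosen so the whole suite stays
desk-scale.  No barostat, periodic boundaries or Ewald summation are
provided.

## Spectra

Pipeline: central-difference dipole time derivative (one-sided at the
ends) → vector autocorrelation summed over Cartesian components
(FFT-based with zero padding, biased 1/N normalization, so acf(0) is the
mean squared signal) → multiplication by a Gaussian window
exp(−t²/2σ²), σ = 1 ps by default (the window is not renormalized; any
normalization is absorbed by spectrum normalization) → one-sided cosine
transform of the even-extended, zero-padded sequence (next power of two,
≥ 4× the signal length, giving ≲ 0.3 cm⁻¹ bins at 20 ps) → thermal
prefactor 2πβ/(3cV) → optional max-normalization.  The harmonic quantum
correction of the underlying line-shape theory is taken as embodied in
that prefactor; no extra ω-dependent factor is applied.  A real cosine
transform of the even extension is used rather than a complex FT; both
peak identically.  The power spectrum applies the same transform to
mass-weighted velocities without the thermal prefactor.  Trajectories
shorter than ~3 window widths get a resolution warning in the spectrum
metadata.

## Interfaces

Plain XYZ, extended XYZ with key=value comment fields (time, energy,
per-frame dipole), 4-column point-charge text (x y z q in Å and e),
2-column spectrum text with a JSON metadata sidecar, and HDF5 archives
for datasets (one group per sample, units declared) and models (kernel
spec, hyperparameters, featurized training set, coefficient vectors;
bit-exact round trip).  The CLI writes a provenance JSON (resolved
parameters, seed, package version) next to every output; YAML configs
reject unknown keys.

## Known limitations

Kernel models are molecule-specific (fixed atom count and order).  Gram
assembly is dense, O((nS(3N+2))²) memory, fine for the 10³-sample regime
the method targets.  The environment descriptor carries no directional
information (a potential-only representation), no periodic images, and
higher multipole descriptors are not implemented.  MM charges feel
forces but no vdW repulsion (see above).  The CV search trains
O(|λ||σ|k) models and is meant for the same data scale.
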