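# Methods

This note documents the models, algorithms, numerical choices and
study conditions implemented in `alfpot`, and what the test suite does
and does not demonstrate.

## Atomic-energy Gaussian processes

Each atom of a molecule carries an independent GP regression of its
(recovery-corrected) atomic energy on atomic-local-frame features.
The posterior mean used for prediction is

    Ê_A(R) = m_A + Σ_i ω_i k(R^i, R),    (K + σ_n² I) ω = y − m_A,

so the model is an exact interpolator in the vanishing-noise limit and
reverts to the prior mean m_A wherever the kernel sees no training
data. The molecular energy is the sum of atomic predictions, and its
far-field limit is M = Σ_A m_A.

**Prior means.** Six statistics of the atom's own training energies
are supported: MF1 = μ, MF2 = μ+σ, MF3 = max, MF4 = max+H,
MF5 = max+5H, MIN = min, with H the energy range. σ is the population
standard deviation (divisor N): the training set is treated as the
complete population the statistic describes, not a sample from a
larger one. The ordering MIN ≤ MF1 ≤ MF3 ≤ MF4 ≤ MF5 holds by
construction; MF2 ≤ MF3 holds whenever σ ≤ max−μ.

**Why the prior mean matters.** Outside the training domain the energy
surface relaxes from the data edge toward M over roughly one kernel
length. A low prior (MIN/MF1) therefore creates an *attractive* basin
beyond the edge — once a thermal fluctuation carries a bond past the
sampled range, the model accelerates the escape and the simulation
breaks. A high prior (MF4/MF5) erects a wall whose height grows with
the shift, producing restoring forces that push the system back. All
of this is invisible to static test-set errors, which probe only the
sampled region.

## ALF features and their Jacobian

Per atom: distance to the x-axis atom, distance to the xy-plane atom,
the frame valence angle, then (r, θ, φ) of every remaining atom in the
right-handed local frame, atoms ordered by ascending global index —
3N−6 features, with every azimuthal φ periodic (1-based indices d > 3,
d mod 3 = 0). Frame atoms are chosen by bonded-neighbour mass priority
(ties to the lowest index); a terminal atom borrows the heaviest
neighbour-of-its-neighbour. Any deterministic convention works — the
features are exact internal coordinates — and the chosen frame is
stored in the model archive.

**Units.** Distance features are expressed in **Bohr**, angles in
radians. The kernel weights are searched in the fixed box θ ∈ [0, 1];
with Å-valued distances that box cannot produce kernel length scales
below 1 Å, which makes the surface beyond a stretched bond
trend-dominated for every prior mean and erases the restoring-force
distinction the prior is supposed to control. Atomic units give the
unit box a chemically sensible resolution. Coordinates in files and
in all MD/optimization code remain in Å; the B-matrix is reported as
feature-unit per Å.

The B-matrix (∂features/∂Cartesians) is assembled analytically —
frame-axis differentials propagated through the spherical coordinates —
and is validated against central finite differences to <1e-7
(observed ~1e-9, the finite-difference truncation floor). Frames whose
three defining atoms are collinear within 1e-8 rad raise a
degenerate-frame error; the polar singularity of θ_n (an atom exactly
on the local z-axis) is clamped at sin θ ≥ 1e-10 rather than raised,
since transient near-polar configurations occur in hot MD.

Two-atom systems cannot define a frame; they run in an explicit
distance-only degenerate mode (one feature) that the diatomic toy uses.

## Recovery-error correction

Partitioned atomic energies carry integration noise, so their sum
misses the reference molecular energy by ΔE. The correction
redistributes ΔE across atoms in proportion to each atom's share of
the raw molecular energy plus its deviation from the mean absolute
integration error; the corrected energies sum to the reference exactly
(algebraic identity, tested to 1e-12 Ha). ΔE is signed as
E_ref − Σ E_raw, the unique sign for which the identity holds. ΔE = 0
makes the correction the identity regardless of the integration
errors, because the whole bracket is scaled by ΔE.

## Forces

F_{A,κ} = −Σ_models ωᵀ(∂k/∂R)·(∂R/∂κ_A), with
∂k/∂R_d^j = 2 k θ_d ΔR_d for ordinary features and ½ k θ_d sin ΔR_d
for periodic ones (the exact derivative of −θ sin²(½Δ)). Because all
features are rotation/translation invariant, net force and net torque
vanish identically (observed <1e-15 Ha/Bohr). Forces are converted to
Ha/Bohr for reporting and to amu·Å/fs² for dynamics; all conversion
constants live in `units.py`.

The jit-compiled core (`_core.py`, numba) evaluates features, B-matrix
and GP energy/gradient in ~50 µs for a 5-atom model with 240 training
points, which is what makes the 50-ps deployments in the test suite
cheap. Without numba the same source runs unmodified but slowly.

## Grey-wolf hyperparameter search

Per atom, the 3N−6 kernel weights (box [0,1]) plus log10 σ_n²
(box [−10,−4]; log scale because the bounds span six decades) minimize
the validation mean-squared error; the weights ω are refitted for every
candidate. σ_f stays fixed at √(N_train·N_feats). The optimizer is
canonical GWO (three leaders, a(t) linear 2→0 with a = 0 exactly at
the final iteration, fresh r₁, r₂ per leader and dimension) with two
enhancements: move-level elitism (an agent reverts any move that
worsens its loss, making the best-so-far trace monotone) and lucky-wolf
promotion (every 5 iterations, 5 random non-leaders teleport to
(1+ε)·centroid of the leaders, ε ~ U(0, 0.25)); promotions are
unconditional, since their purpose is to concentrate the pack, while
elitism guards the ordinary moves. Non-finite losses count as +∞ so
failed Cholesky factorizations can never lead the pack. Fixed seeds
give bit-identical traces.

Counting all tunables of one molecule's model family gives 3N−4
hyperparameters (3N−6 kernel weights, the noise, the pre-factor); here
each atomic model searches its own (3N−6)+1 dimensions with σ_f held
fixed.

## Molecular dynamics and deployment

Velocity-Verlet in Å/fs/amu at dt = 0.25 fs. Thermostats: single
Nosé–Hoover (production; coupling time 100·dt, Trotterized half-kicks)
and BAOAB Langevin (sampling; friction 0.01 fs⁻¹). Velocities
initialize Maxwell–Boltzmann with zeroed total momentum; temperature
is measured with 3N−3 degrees of freedom (3N for Langevin, which does
not conserve momentum). Observed: NVE drift ~6e-6 Ha over 10 ps on the
toy GP model; NVT mean temperature within ~1% of target over 50 ps.

Stability: every step, each bond of the reference connectivity
(distance cutoff 1.2× summed covalent radii on a user-supplied
reference structure) is compared with its equilibrium length; the
first ratio outside [1/1.65, 1.65] ends the run, and a non-finite
energy or force counts as a crash at that step with a distinct tag.
Robustness is the mean stability time over repeated runs.

BFGS geometry optimization delegates to scipy with the analytic
gradient, converging on the infinity-norm of the gradient at
0.00045 Ha/Bohr (restarting up to three times if a line search stalls
short of the threshold). Structural comparison uses Kabsch
superposition RMSD (proper rotations only, residual evaluated
explicitly for machine-precision zeros) and signed dihedrals in
(−180°, 180°].

## Diversity-aware sub-sampling (DAS)

Greedy farthest-point selection under superposition RMSD: the first
pick is the pool geometry nearest the seed structure, every later pick
maximizes the minimum RMSD to the already-selected set (ties to the
lowest index; heavy-atom-only metric optional; no atom-permutation
matching — atom order is assumed consistent within a dataset). The
greedy-maximin reading of farthest-point selection is an
interpretation, fixed here and verified exhaustively against a
brute-force oracle on small pools. Coverage (directed Hausdorff
distance from pool to selection) is non-increasing in k.

DAS is not cosmetic in this package: training sets thinned from
correlated trajectory samples without it produced near-singular Gram
matrices, regression weights of order 1e6, and ringing extrapolation
that crashed even high-prior MD runs.

## Synthetic data generator

`ToyPES` is an analytic valence force field — harmonic bonds
(0.4–0.5 Ha/Å², equilibrium 0.96–1.5 Å), harmonic angles
(0.1 Ha/rad², tetrahedral), 3-fold cosine torsions (0.004–0.006 Ha;
the glycine-like toy also has a 2-fold backbone torsion giving two
metastable conformers), per-element baselines (−0.5 Ha for H-like,
−37.8 C, −54.4 N, −75.0 O) — partitioned exactly over atoms: ½ of
each bond to its two atoms, angles to the apex, ½ of each torsion to
the two central atoms, baselines to their own atom. Toys: `diatomic`
(degenerate mode), `chain4`, `chain5` (the workhorse: O–C–C–C–H, nine
features per atom, two torsions), `glycine-like` (7 atoms).

Labels add Gaussian per-atom noise (default sd 1e-4 Ha; heavy atoms
5×, mirroring the wider energy ranges of heavy atoms), store its
absolute value as the per-atom integration error, and keep the exact
total as the reference energy — so the recovery error equals minus the
summed noise and the correction is exactly checkable.

Configuration pools come from Langevin dynamics on the analytic
surface. Temperatures are *effective*: the toys are far floppier than
real molecules, so e.g. "800 K" marks a sampling intensity (bond
coverage ±25%, full torsion circle), not a physical temperature.

**What the toys do not emulate:** electronic structure, element-true
stiffnesses, many-body exchange effects, conformational complexity of
real peptides, and dataset sizes (hundreds of configurations, not
thousands). Passing tests demonstrates the machinery — exact algebra,
exact derivatives, correct integrators, the qualitative prior-mean
mechanism — not chemical accuracy on real systems.

## Study conditions of the validation suite

* chain5 models: pool 1200 @ T_eff 800, DAS-select 300, GWO 40
  iterations × 25 agents, validation block 60 (shared across atoms).
  The search is scaled down from 200×50; on these 10-dimensional
  problems the loss trace is flat well before iteration 40. Typical
  molecular test MAE (150 held-out configurations): 0.7–1.0 kcal/mol
  depending on the sampling seed.
* diatomic models: 40 noise-free bond lengths evenly on [0.8, 1.2] Å,
  θ fixed mid-box at 0.55, σ_n² = 1e-8. With smooth noise-free 1-D
  data the validation loss is flat in θ, so a searched value would be
  arbitrary; 0.55 sits in the regime where the posterior still feels
  the data one bond-length out while the prior governs the energy
  there — the regime the restoring-force experiment probes.
* deployment: Nosé–Hoover, dt 0.25 fs; robustness at 1150 K effective,
  5 velocity seeds, 50 ps cap. The temperature is chosen hot enough
  that a plain-mean (MF1) model almost always escapes within a few ps
  while the max+H wall of MF4 delays and the max+5H wall of MF5
  prevents escape — the regime where the prior-mean ordering is
  measurable with 5 runs. (Verified with 15-seed pilot distributions;
  at mild temperatures MF1 and MF4 are statistically indistinguishable
  because neither escapes often.)
* high-energy relaxation: bond C–C stretched to 1.5× its training
  mean, NVT 500 K; recovery to within 10% of the training mean in
  ~0.02 ps, full 50 ps survival.
* BFGS deployment: 25 starts perturbed by U(−0.25, 0.25) Å per
  coordinate; the GP-optimized geometry is compared with the
  analytic-surface optimum *of the same basin* (BFGS on the toy PES
  from the identical start), because the chain toys have several
  symmetry-equivalent torsional minima.

## Known limitations

* Single molecules only: no periodic boundaries, neighbour lists,
  virial/stress, or condensed-phase machinery.
* No GP posterior variance; only the posterior mean is modelled.
* The ALF frame-selection rule is a documented stand-in for priority
  conventions defined elsewhere in the descriptor literature; models
  store their frame, so archives remain reproducible even if the
  default rule changes.
* The Nosé–Hoover implementation is a single thermostat, not a chain;
  for the small toys its sampling is adequate (mean temperature within
  a few percent) but ergodicity for stiff or near-harmonic systems is
  not guaranteed.
* Model archives are JSON: exact (shortest-round-trip decimal floats)
  but not compact; fine for hundreds of training points per atom.
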