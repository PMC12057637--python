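# Methods

`aimpot` implements a charge-aware message-passing interatomic potential:
a learned short-range energy term combined with physics-based point-charge
electrostatics and two-body dispersion, together with the multi-target
training loss, a teacher→student data-distillation loop, simulation
drivers, and an analytic toy reference potential that stands in for
quantum-chemical labels at desk scale.  This note records the model, the
numerical choices, and what the desk-scale experiments do and do not show.

## Energy model

The total energy of a system of `N` atoms with coordinates `R`, atomic
numbers `Z` (14 supported elements: H, B, C, N, O, F, Si, P, S, Cl, As,
Se, Br, I) and integer net charge `Q` decomposes as

    U_total = U_local + U_disp + U_coul.

All internal units are eV, Å, and elementary charge; periodic support is
orthorhombic cells with the minimum-image convention.

### Radial featurization

Interatomic distances are expanded in `s = 16` Gaussian shells
`g_ijs = exp(-η (r_ij - r_s)²) · f_c(r_ij)` damped by the cosine cutoff
`f_c(r) = ½(cos(π r/R_c) + 1)` with `R_c = 5.0 Å`.  Shell centers are
evenly spaced on `[0.8, 5.0] Å` and `η = 1/(2Δ²)` with `Δ` the shell
spacing, giving roughly 50% overlap between adjacent shells; both are
exposed in `RadialBasisSpec`.  Every feature and its radial derivative
vanish at the cutoff, so the local term is C¹ as atoms cross it.

### Message passing with charge refinement

Each atom carries a 2-D embedding `a_ds(z)` (`d = 16` feature channels ×
16 shells) initialized per element.  A pass builds

* the scalar (l = 0) contraction `v_isd = Σ_j g_ijs a_ds(j)`;
* the vector (l = 1) contraction: per-pair messages `Σ_s g_ijs a_ds(j)
  w_dsh` are mixed by a learned `w_dsh` (`h = 8` vector channels),
  accumulated along the unit bond vectors `û_ij`, and reduced by a
  Euclidean norm over the Cartesian axis — rotation-invariant, and
  opposite neighbors cancel;
* from pass 2 on, the same two contractions with the neighbor embedding
  replaced by its current partial charge.

The concatenated features drive two heads per pass: an update MLP that
emits a residual embedding update, and a small dedicated charge head that
emits a raw charge `q̃_i` (a refinement `δq̃_i` after pass 1) and a
non-negative weight `f_i = softplus(·) + 10⁻⁶`.  Every charge update is
followed by Neural Charge Equilibration

    q_i = q̃_i + f_i (Q − Σ_j q̃_j) / Σ_j f_j,

so the charges sum to the exact molecular charge after every pass (to
1e-10 e over `|Q| ≤ 9` in the acceptance suite).  The final pass's
embedding, concatenated with the final charge, is the per-atom AIM vector
feeding a feed-forward energy head on top of per-element reference
energies `E0(z)` (initialized by least-squares regression of training
energies on element counts).

The charge head is separate from the update trunk because, for molecules
that fit inside the local cutoff, the energy objective cannot constrain
the charge assignment (the local head can absorb any electrostatic
contribution) — a shared output layer then starves the charge channel of
gradient signal.  Default widths are 256/128 for the trunk and energy
head, 64 for the charge head; the desk-scale experiments use 128/64
(stated below).  The default number of passes is 3; the update MLPs use a
sigmoid-weighted linear unit activation.

### Electrostatics

`U_coul` is point-charge Coulomb over the model's own charges.  Isolated
systems use the full direct sum (`k_e = 14.399645 eV·Å/e²`).  Periodic
systems use the damped-shifted-force (DSF) form with `α = 0.2 Å⁻¹` and a
15 Å cutoff (capped below half the box), whose pair energy *and* force
vanish smoothly at the cutoff.  Because the charges depend on the
coordinates through the network, forces are exact gradients of the whole
composition, including the equilibration chain.

### Dispersion

`U_disp` is a two-body dispersion correction in the rational
(Becke–Johnson) damping form

    E = -½ Σ_{i≠j} [ s6 C6_ij/(r⁶ + f(R0)⁶) + s8 C8_ij/(r⁸ + f(R0)⁸) ],
    f(R0) = a1 R0 + a2,   R0 = sqrt(C8/C6),   C8 = 3 C6 r4r2_i r4r2_j,

with C6 interpolated over per-element coordination-number reference
points by Gaussian weights (`k3 = 4`), and the standard smooth CN
counting function (`k1 = 16`) over covalent radii.  Forces include the CN
chain (verified against finite differences to 1e-5 eV/Å).  **The shipped
reference tables are synthetic**: smooth free-atom-scale C6 values with a
CN-dependent decay, geometric-mean pair combination, and generated r4r2
factors (see `data/d3_params.json`, which documents this and can be
swapped for the published tables).  No published parameter set or
reference implementation is redistributed with the package.  Two damping
parameter sets are selectable (`b97-3c`: s6=1.0, s8=1.50, a1=0.37,
a2=4.10; `wb97m`: adopted values of the same magnitude); with synthetic
C6 tables these choices affect only internal consistency, which is what
the tests check (vectorized evaluation against an independently coded
scalar evaluator to 1e-6 eV).  Under a periodic cutoff, pair terms are
tapered by a cosine switch over the last 10% of the cutoff so MD forces
stay continuous.

### Differentiation

No autodiff framework ships in the target environment, so the package
carries a small reverse-mode engine (`aimpot.autodiff`) whose primitives
define their vector-Jacobian products in terms of other primitives; the
backward pass is therefore differentiable and `grad` nests.  Forces are
`-∂U/∂R` through the full graph; force-matching training differentiates
those forces again with respect to the parameters.  The engine is tested
against finite differences to second order.

## Training

The loss is a weighted MSE over energy (per-molecule error divided by
√N before squaring, so per-atom noise weighs equally across sizes),
force components, partial charges, dipole and quadrupole (both computed
from the predicted charges about the center of mass).  Weights are
1.0 / 0.2 / 0.05 / 0.02 for energy, forces, dipole, quadrupole, and 1.0
for the direct charge term; the set is normalized to sum to one.  The
charge weight is this package's choice (see the charge-head rationale
above): without a direct term, desk-scale charges are pinned only by the
weakly weighted multipoles and converge impractically slowly.

Minibatches contain molecules of identical atom count (no padding);
gradient accumulation provides larger effective batches; the optimizer is
decoupled-weight-decay Adam with a reduce-on-plateau schedule (factor
0.5, patience 10, min-lr 1e-5 as library defaults).  Dispersion carries
no learnable parameters, so per-sample dispersion energies and forces are
computed once and moved to the label side.  Because training geometries
never change, the pair featurization and its coordinate Jacobians are
precomputed per batch and enter the graph as leaves; forces are assembled
by the chain rule from `∂E/∂(g, û, r)` — tested to be identical (1e-12)
to the direct coordinate graph.  Training runs in float32 by default
(`TrainConfig.dtype`); the trained parameters are returned as float64 and
all inference is float64, so prediction-side invariance properties hold
at 1e-8 regardless of the training precision.

## Toy reference potential and generators

The toy potential supplies exactly self-consistent labels (analytic
forces are the exact negative gradient; multipoles are charge moments):

* **bonded**: Morse wells per element pair (`D_e` by geometric-mean
  combination of per-element depths ~3–4.5 eV, `r_e` the sum of covalent
  radii, `a = 1.8 Å⁻¹`) plus harmonic bending in `cos θ` at every bonded
  triple (`k = 3 eV`, tetrahedral reference);
* **nonbonded** (1-2 and 1-3 excluded): damped `−C6/(r⁶ + r₀⁶)`
  dispersion plus exponential Pauli repulsion `A e^{−3.5 r}`;
* **electrostatics**: point charges over all pairs from a fixed
  electronegativity rule `q_i = (χ̄ − χ_i)/κ + Q/N` with `κ = 5`
  (uniform net-charge redistribution — deliberately within the NQE
  representable family, so the learning task is well-posed).

Generators: random valence-limited molecular graphs (tree plus occasional
ring) hydrogen-saturated and embedded/relaxed in 3-D; Gaussian-plus-
torsion conformer sampling with clash rejection; randomized packing of
2–5 molecules into 20–30 Å periodic cells with a 1.5 Å intermolecular
clearance; N-mer extraction with a 6.0 Å contact rule.  Everything is
deterministic under its seed.

What the toy data does *not* emulate: real electronic structure
(polarization, charge transfer beyond the fixed rule, reactivity),
conformer ensembles of large flexible molecules, and label noise.
Passing the recovery experiment shows the model/trainer can fit a
smooth charge-aware reference to stated accuracy — not that it matches
quantum-chemical data.

## Simulation drivers

Batched FIRE (literature hyperparameters: dt0 0.1, f_inc 1.1, f_dec 0.5,
α0 0.1, N_min 5, displacement cap 0.2 Å) runs the identical per-system
update sequence in lockstep, so batched ≡ serial exactly.  L-BFGS keeps a
10-pair history with a hard 0.02 Å per-step displacement cap.  Relaxed
torsion scans constrain the dihedral by projecting its gradient mode out
of the forces and re-imposing the angle after each optimizer cycle; every
scan point restarts from the input geometry rotated to the target angle,
which makes the profile exactly 360°-periodic (no relaxation hysteresis).
MD is velocity Verlet (0.5 fs default) with stochastic velocity-rescaling
NVT (τ = 100 fs default; exact kinetic-energy propagator with the χ²
draw); initial velocities are Maxwell–Boltzmann with net linear (and, for
isolated systems, angular) momentum zeroed; degrees of freedom are 3N−3
periodic, 3N−6 isolated.  Self-diffusion uses the Einstein relation,
D = slope/6 of the mean-squared displacement averaged over particles and
all time origins (FFT algorithm); the default fit window is the [2%, 25%]
lag range, where the origin average is well conditioned — the long-lag
half of an MSD curve carries too few independent segments for a stable
slope.

## Distillation

Round 0 trains on `n_init` random teacher samples.  Each round scans the
remaining teacher in size order and selects up to `n_add` samples whose
energy *or* force error exceeds `threshold_factor = 3` × the current
per-channel training error (energy: mean |ΔE|/√N; force: mean per-sample
RMS component error — the statistic is a package choice and is logged),
then continues training from the previous weights.  The loop stops when a
full scan selects nothing or at `max_rounds`; finally an ensemble
(default 4 members) is retrained from scratch on the student set, and the
member standard deviation is the query-by-committee uncertainty score.

## Desk-scale problem sizes and what the checks show

The acceptance suite runs on one CPU:

* recovery: 100 random molecules (2–5 backbone atoms, hydrogen-saturated,
  charges in {−1, 0, +1}) × 52 near-equilibrium conformers (0.08 Å
  Cartesian scale, 0.25 rad torsion twists); 5000 train, 200 held-out
  conformers of the same molecules; model 128/64 trunk, 2 passes; batch
  128 (memory-bounded); energies compared per molecule;
* distillation: 1600-sample teacher, `n_init` 320, `n_add` 240, equal
  total epoch budgets (16) for the student-vs-full comparison (the
  script uses a 2000-sample teacher);
* dynamics: toy-potential NVE over 10 ps at 0.5 fs (drift measured as the
  difference of the first/last 5% window means), the neural model over a
  1.5 ps window at the same per-atom bound, NVT averages over 50 ps on a
  dense 56-atom periodic box (a single near-harmonic molecule mixes
  vibrational-mode energies too slowly for a global-rescaling thermostat
  to average well; intermolecular collisions restore ergodic sampling), Brownian-walk
  diffusion recovery with 256 walkers × 4000 frames and a short-lag fit
  window matched to pure Brownian data;
* training epoch budgets are the largest that fit the suite's runtime
  envelope; the per-epoch convergence trajectory is monotone, so longer
  schedules only improve the reported errors.

## Known limitations

* The dispersion parameter tables are synthetic stand-ins (above); swap
  in published tables for production use.
* No Ewald summation: periodic electrostatics are DSF-only, and cutoffs
  must stay below half the smallest box length.
* No spin/open-shell handling; no l ≥ 2 equivariant features; no stress
  tensor.
* The NumPy training stack is ~2 orders of magnitude slower than a GPU
  framework; production-scale schedules (hundreds of epochs on millions
  of samples) are out of reach, which bounds the accuracy reachable in
  the packaged experiments.
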