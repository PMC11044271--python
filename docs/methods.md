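# Methods

`swishx` is a desk-scale implementation of SWISH-X — lambda-scaled
Hamiltonian replica exchange with an OPES MultiThermal expanded-ensemble
bias — together with the trajectory-analysis protocol used to read out
cryptic-pocket opening.  The simulation half runs on reduced-unit toy
particle systems; the analysis half operates on any coordinates
(toy frames, synthetic pseudo-residue trajectories, or PDB/XTC/DCD/XYZ
input).  This note records the models, the defaults and why, the numerical
choices, and what the toy scale does and does not demonstrate.

## Scaled Hamiltonian (engine)

Nonbonded energy is decomposed into water-water (ww), water-solute (ws) and
solute-solute (ss) buckets and the ws bucket is multiplied by a scaling
factor lambda:

    U_total(lambda; R) = U_ww(R) + lambda * U_ws(R) + U_ss(R).

Only solvent <-> *apolar*-solute pairs enter the scaled ws bucket: the
physical picture is water's affinity being raised specifically for apolar
atoms, which is what drives hydrophobic-cavity wetting.  Solvent <->
polar-solute and all probe interactions are grouped unscaled in the ss-like
bucket.  The identity `U(lambda) - U(1) = (lambda - 1) U_ws` holds to
machine precision by construction and is asserted property-style in the
tests.

The pair potential is a truncated-and-shifted 12-6 Lennard-Jones form with
per-role-pair (epsilon, sigma) and cutoff 2.5 sigma; reduced units
(epsilon = sigma = k_B = m = 1) throughout the engine.  Dynamics is BAOAB
Langevin (accurate configurational sampling at large steps; reduces exactly
to velocity Verlet at zero friction).  Default timestep 0.004, friction 1.
Two protocol restraints are implemented: a half-harmonic upper wall on a
contact-map CV (sum of rational switching values over chosen pairs), and a
half-harmonic interprobe repulsion `k_rep (d_rep - r)^2` for r < d_rep
(default d_rep = 1.5 sigma_probe), which prevents probe phase separation —
the published protocols cite such a term without giving its form, so the
minimal monotone choice is used.  The wall threshold w_max is
auto-calibrated as mean + 3 SD of the CV over a short unbiased run,
automating the "inspect the unbiased fluctuations" recipe.

All randomness flows through numpy Generators; per-replica streams,
initial velocities, the wall calibration and exchange decisions are
children of one `SeedSequence(master_seed)`.  The inner Langevin loop is a
numba kernel, cross-checked bitwise-level against the pure-numpy reference
path in the test suite.

## OPES MultiThermal (bias)

The bias acts on the potential energy U and makes one run sample a
multicanonical ensemble spanning [T_min, T_max].  With a temperature grid
T_j uniform in beta (both endpoints included) and expansion shifts
`du_j(U) = (beta_j - beta) U`:

    V_n(U)   = -(1/beta) ln[ (1/N_T) sum_j exp(-du_j(U) + beta_j dF_n(T_j)) ]
    dF_n(T_j) = -(1/beta_j) ln[ sum_k w_k exp(-du_j(U_k)) / sum_k w_k ],
    w_k      = exp(+beta V(U_k))  (the bias acting when U_k was sampled).

`dF(T_j)` converges to `-(1/beta_j) ln(Z(beta_j)/Z(beta))` — exactly the
normalisation each expansion term needs — and is zero at T_j = T by
construction.  Note this is *not* the canonical free-energy difference
F(T_j) - F(T), which differs by `(T_j - T) ln Z(beta)` and is not estimable
from reweighted samples alone.  For the 1-D harmonic well (k = 1) the
analytic limit is `dF(T_j) = -(T_j/2) ln(T_j/T)`, which the estimator
recovers to better than 1e-4 after 1e6 biased steps in the validation run.

Estimates refresh every 500 steps (bias piecewise-constant in between, the
standard on-the-fly compromise); all exponentials go through log-sum-exp
and accumulators live in log space.  Biased forces are
`(1 + dV/dU) * (-grad U)` with the analytic dV/dU bounded in
[(beta_min - beta)/beta, (beta_max - beta)/beta].  An "auto" grid size
grows N_T until neighbouring canonical energy distributions overlap
(|<U>_{j+1} - <U>_j| <= 2 sigma_U, estimated by reweighting a short
unbiased calibration sample) — the reference implementation's auto rule is
not published, so this overlap heuristic stands in.

## Replica exchange and the four strategies

SWISH runs a ladder of replicas at uniformly spaced lambda from 1.00
(nonscaled) to 1.35 — six replicas by default, matching the published
protocol — each with probes, the contact wall and a shared thermostat.
SWISH-X adds one OPES MultiThermal estimator per replica, all sharing one
[T_min, T_max] range by default (the shared-range tempering scheme;
incremental/broadened per-replica ranges are configurable).  Exchange uses
nearest-neighbour Metropolis with alternating even/odd phases every 1000
steps:

    P_acc = min(1, e^{-beta Delta}),
    Delta = [E_i(R_j) + E_j(R_i)] - [E_i(R_i) + E_j(R_j)],
    E_k(R) = U_total(R; lambda_k) + V_k(U(R; lambda_k))  (bias term in SWISH-X only).

Configurations and velocities swap on acceptance; lambda and the bias
estimator stay with the ladder slot, so all recorded series are
lambda-resolved.  With N_T = 1 and T_1 = T the bias is identically zero
and SWISH-X reproduces SWISH bitwise at equal seeds (asserted in the
tests).  A replica whose wall CV exceeds w_max + 5 SD in more than 10% of
frames is flagged "excluded", mirroring the exclusion of an unfolded
highest-lambda replica in the published analyses.

Before production every replica equilibrates at its own lambda for 4000
steps with the gate restrained closed (the analogue of the per-lambda
equilibration runs of the real protocols); nothing is recorded and the
bias estimator is not updated during equilibration.

## The gated-cavity toy

The synthetic "protein" is a frozen spherical shell of apolar particles
(radius 1.8, 60 Fibonacci-lattice sites) with a 35-degree mouth, an apolar
gate particle that fills the cavity when closed (x = 0) and sits
solvent-exposed outside when open (x = 3), 24 solvent particles and
optionally 2 probe particles confined to a 4.0-radius sphere.  The gate
carries a quartic double well of configurable barrier height B (the
"cryptic" barrier; B = 8 k_B T in the headline comparison) plus a y/z
tether.  The construction gives a genuine cryptic-opening mechanism:

* closed is metastable at lambda = 1 — the gate's shell contacts
  (eps_ss = 1) offset the solvation it would gain by leaving;
* raising lambda strengthens solvent <-> apolar attraction, so wetting of
  the vacated cavity and of the exposed gate preferentially stabilises
  open states (measured on this system: the open-minus-closed ws energy
  is several epsilon, i.e. a tilt of order (lambda-1) * 10 epsilon);
* the narrow mouth keeps solvent off the gate until it has actually left,
  which is what makes the closed state long-lived rather than leaky.

The toy's MultiThermal range defaults to reduced T in [1.0, 2.0].  A
Kramers estimate fixes this choice: an 8 k_B T barrier heated by the
300->350 K ratio (x1.167) gains only ~e^1.1 = 3x in rate — invisible in
desk-scale runs — while T_max = 2 gains ~e^4.  The range is a
system-specific tuning parameter of the method itself ("broad enough to
allow significant sampling"); the harmonic-well validation of the bias
keeps the 300->350 ratio exactly.

Pocket exposure on the toy is measured with the same grid machinery as for
proteins, using only solute (shell + gate) atoms as occluders — as in
protein pocket analysis, solvent and probes do not occlude; a
water-flooded open pocket is still open.  The reference ("holo") state is
the solute with the gate at its open minimum; the region radius is derived
from the geometry so that a closed gate occludes the entire region even
under thermal jitter.

In the ten-seed comparison (100k steps, frames every 500 steps, opening =
exposure >= 60% with lining RMSD < 2), median first-opening steps order as
SWISH-X < SWISH < unbiased (500 / 2500 / 11000 in the validation run),
which is the qualitative content of the method's claim at this scale.

## Pocket metrics

Pocket volume is a grid flood fill: grid points (default spacing 0.5 A)
inside a spherical region (default 8 A) around the pocket center count
when farther than atom_radius + probe_radius (probe 1.4 A) from every atom
and face-connected to the empty cell nearest the center — the connectivity
step drops disconnected bulk-solvent voids.  The published work does not
name its volume tool, so absolute volumes here are not comparable to the
paper's; exposure (volume as % of the holo-crystal pocket volume,
unclipped above 100%) is the scale-free readout.  An empty 5-A test sphere
reproduces its analytic volume within the grid discretisation error
(<2% at 0.5 A, converging under refinement).

Lining residues are those whose center of mass lies within 7 A (inclusive)
of the pocket center in the reference; frames are Kabsch-aligned on lining
heavy atoms before volume evaluation, and pocket RMSD is the superposed
heavy-atom RMSD over the same selection.  Opening time is the first time
exposure >= threshold AND RMSD < ceiling jointly hold (60%/80% and 2 A are
the published criteria); it is monotone non-decreasing in the exposure
threshold and non-increasing in the RMSD ceiling.  Replica-merged
("violin") summaries pool frames across non-excluded replicas; medians use
the standard mean-of-central-pair convention.

## Cluster maps

Contacts are all unordered pairs of lining-shell residues; each contact is
the residue-COM distance through the rational switch
`S(r) = (1-(r/r0)^4)/(1-(r/r0)^8)`, r0 = 0.8 nm (the removable singularity
at r = r0 is evaluated as the limit n/m = 0.5).  The m x n matrix is
reduced to min(50, n, m-1) principal components and embedded in 2-D with
t-SNE (scikit-learn, default perplexity 30, PCA initialisation, fixed
seed), fitted jointly on apo-run and holo-like frames so the open state is
a landmark in map space.  HDBSCAN (min_cluster_size default 100, inside
the published 75-200 range; min_samples = min_cluster_size) clusters
non-holo points only; noise stays "unclustered" and holo frames are
embedded but never clustered.  The holo region is summarised by Gaussian-KDE
(Scott's rule) iso-contours at 10% and 50% of peak density.  Per-cluster
summaries report member count, median exposure and RMSD, and the k = 10
frames nearest the embedding centroid for structure export.

The synthetic two-state generator stands in for protein trajectories: 8
pseudo-residues on a ring (radius 4 A closed, 7 A open, alternating +-0.8 A
z offsets) with Gaussian coordinate noise (default sigma 0.05 nm) and a
planted transition schedule.  It reproduces the statistical structure the
pipeline assumes — distinct open/closed contact signatures and an
exposure-relevant cavity — but none of the things that make real proteins
hard: correlated residue motions, partial/intermediate states, force-field
artefacts, or microsecond kinetics.  Passing tests therefore validate the
*pipeline*, not protein-scale discovery performance.

## Problem sizes and limitations

The validation suite uses 1e6-step 1-D bias runs, 100k-step toy MD (about
77 particles), 1000-frame synthetic sets and 10-seed repetitions; these
sizes make every check reproducible on a single CPU in minutes.  Known
limitations: the engine is non-periodic in its accelerated path and O(N^2)
in pairs (fine for tens of particles, not thousands); absolute pocket
volumes depend on the grid algorithm and radius table; t-SNE cluster maps
are seed-dependent in layout (memberships are stable, label ids and
geometry are not); and the toy's effective opening barrier is the double
well plus solvation terms, so B is the controlled parameter, not a
measured free-energy difference.
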