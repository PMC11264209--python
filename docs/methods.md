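# Methods

`tisdesign` implements a dynamics-guided redesign workflow for rare-event
(activated) transitions: sample reactive and nonreactive turnover attempts
with transition interface sampling (TIS), assemble rate constants from a flux
factor and interface-crossing probabilities, profile the free energy along
the progress coordinate with umbrella sampling and WHAM, train classifiers
that recognize reactive-like conformations from prereaction geometry, and use
those conformations in a multistate design objective whose candidates are
screened by equilibrium populations and screening-mode barriers.  Everything
runs on bundled desk-scale surrogate systems that expose the same interfaces
(potential, gradient, order parameter) a QM/MM enzyme Hamiltonian would.

Units throughout: kcal/mol (energy), Å (length), fs (time), amu (mass), K
(temperature).  Rates are reported in 1/s.

## Order parameter and state definitions

The scalar progress coordinate is λ = d(breaking bond) − d(forming bond) in
Å.  The reactant state A is λ < −0.8 Å and the product state B is λ > 0.8 Å;
comparisons are strict, so λ exactly at a boundary belongs to neither state.
Paths terminate on first entry into A or B.  The nonreactive pathway class
NR₋₀.₄ contains failed attempts that reach at least λ = −0.4 Å — the
"bottleneck", the λ at which the incremental progress probability
P(λ + 0.05 Å | λ) is smallest — before returning to A.

## Surrogate systems

**Double well** (`make_double_well`): a quartic bistable potential along λ
with minima placed exactly at the requested well centers and a barrier of
exactly the requested height, plus harmonically coupled environment
coordinates.  Its free-energy profile along λ is the quartic itself (the
linear environment coupling integrates out), so WHAM output and barrier
estimates have closed-form references.  Default barrier 4 kcal/mol at 300 K:
rare enough that crossing is an activated event, frequent enough that a
brute-force transition count with hundreds of events is affordable.

**Migration mimic** (`make_migration_mimic`): a 3D group-transfer model —
donor D, migrating group M, acceptor A — with λ = d(D–M) − d(M–A), a stiff
restraint on d(D–M) + d(M–A) (k = 300 kcal/mol/Å², so the individual bonds
vibrate with a ~25 fs period, the "compression clock" used for time
alignment), and a quartic exchange barrier in λ (default 7 kcal/mol).  Gate
particles tethered to M modulate the instantaneous barrier through a bounded
function of each gate distance g = d(G–M):

    ΔV = s · tanh((g − g_ref)/w) · exp(−λ² / 2σ²),   s = 3 kcal/mol each,
    w = 0.8 Å, σ = 0.2 Å.

Small g lowers the barrier.  The bump is narrow and centered at the barrier
top, so reaching the bottleneck (λ ≈ −0.4) is nearly gate-independent while
passing the top is strongly gate-dependent: that makes the gate distances
the planted discriminators between R and NR₋₀.₄ approaches.  There are two
gate particles by default: a single bounded (saturating) modulation caps the
linear separability of the pathway classes near AUROC ~0.8 — the reactive
tilt exp(−βΔV(g)) concentrates the reactive class at "equilibrium restricted
to small g", which overlaps heavily with the near-equilibrium nonreactive
class — while two independent gates combine to a much stronger linear
discriminant.  Distractor particles are tethered to M by harmonic *distance*
restraints and carry no class signal; absolute-position anchors were
rejected because distances to fixed points proxy the molecule's displacement
and orientation, which correlates with reaction progress.  The ground truth
is recorded in `metadata["gate_truth"]`.

The gate mass sets a gate's oscillation period and therefore how long a gate
configuration persists relative to one barrier approach (~100 fs).  The
default (12 amu, ~530 fs period) gives a slowly varying environment whose
prereaction value strongly predicts the attempt's outcome — the regime the
classifier study assumes.  A light gate (2 amu) relaxes several times
faster; see "Redesign study" below for why the rate-tested variant family
uses it.  Donor and acceptor are light (3 amu) so the bond-compression clock
runs several cycles per barrier approach, and distractors are light (2 amu)
so the uninformative noise they emulate mixes within a single path-sampling
chain (a slow uninformative coordinate would otherwise act as a spurious
chain-identity marker in few-chain studies).

**Toy design space** (`make_toy_design_space`): a finite sequence space with
reproducible random additive (site × token × conformation) and pairwise
(site,token × site,token) effect tables, WT = token 0 everywhere with all its
effects zeroed, so every mutation effect can be read back from the tables.

## Dynamics

Langevin dynamics with the BAOAB splitting and an exact Ornstein–Uhlenbeck
O-step; defaults dt = 1 fs, friction 1 ps⁻¹, 300 K.  At zero friction the
scheme reduces to velocity Verlet and is exactly time-reversible.  Umbrella
production uses dt = 0.5 fs by default because the stiff restraint
(200 kcal/mol/Å²) on light surrogate particles reaches ω·dt ≈ 0.4 at 1 fs,
which measurably biases sampled variances (barrier estimates inflate by
~0.15 kcal/mol at dt = 1 fs).

Backward segments of two-sided (shooting) propagation are generated by
forward integration from the momentum-reversed state with fresh noise, then
time-reversed and joined to the forward segment with the shared midpoint
appearing once.  This is a convention choice: the stochastic path measure
does not single out a backward rule, and the deterministic momentum-reversal
alternative is recovered at friction 0.  Trial paths that exhaust the step
budget without committing to A or B are rejected, never truncated.

The two bundled potentials carry numba-compiled kernels for serial path
propagation (the sampler's hot loop); user-defined systems run on a generic
numpy path.  Both are deterministic given the seed, but they consume
distinct noise streams, so numeric trajectories differ between the paths.

## Shooting moves and path ensembles

A shooting move picks a frame uniformly from the current path, perturbs the
momenta, and regenerates a trial path by two-sided propagation.  The momentum
update has two parts: a Gaussian direction kick of dimensionless scale σ_p
rescaled back to the original kinetic energy (a symmetric proposal on the KE
shell), then a kinetic-energy redraw from the exact equilibrium Γ(n/2, kT)
marginal (an independence proposal whose density ratio cancels).  The
acceptance probability is therefore the ensemble-condition indicator times
min(1, L_old/L_new), the flexible-path-length factor for uniform
shooting-point selection.  Rejected moves increment the current path's
multiplicity, so stored multiplicities sum exactly to the number of counted
moves.  σ_p defaults to 0.35, which lands in the ~25–60% acceptance band on
the bundled surrogates.

Interface ensembles condition on "begins in A and reaches λᵢ"; paths that
reach B are retained and count as crossing every higher interface.  Interface
chains are sampled in ascending order and *staged*: each chain is seeded with
a recent path from the previous (lower) interface that already crosses the
new one, so slow environment modes relax incrementally instead of
re-relaxing from the fully reactive seed at every interface.

Time alignment defines t = 0 at the trough of the last compression of the
breaking bond before the final barrier passage (for reactive paths: before
the last frame with λ < 0; for nonreactive paths: before the λ maximum —
the anchor event is a convention, since "final rupture" is only unambiguous
for reactive paths).  Ballistic paths without an interior compression trough
cannot be aligned and are skipped by the pipeline with a warning.  Frame
sampling windows are half-open [t_lo, t_hi) so 5-fs-stepped windows tile
without double counting.

## Rate constants

k = Φ_A · P(λ_B|λ_A), with the probability factor factored over interfaces:
P(λ_B|λ_A) = P(λ_B|λ_n) · Π P(λᵢ₊₁|λᵢ).  The default grid has 30 interfaces
(29 conditional steps) from −0.8 to 0 Å; the last interface's ensemble
supplies the final leg as the multiplicity-weighted fraction of its paths
committing to B.

Φ_A uses the effective-positive-flux convention: one count per excursion
from A, divided by the time the trajectory is *assigned* to A, where
assignment is history-based (A from each entry into the reactant region
until the first entry into B).  The matching brute-force oracle counts one
A→B event per first entry into B since last residing in A, per A-assigned
time.  This history-based transition frequency is the estimand of the TIS
assembly; a mean-first-passage-style counter that resets walkers after each
event measures a different quantity whenever the B boundary allows fast
recrossings (on the bundled double well, whose λ_B boundary sits only
~0.9 kT below the product minimum, the two differ by roughly 4×), so the
equivalence check uses the history-based counter.

Replicate aggregation reports mean ± SEM with the n−1 sample standard
deviation; the replicate design mirrors 3 seeds × 3 repeats = 9 independent
estimates, treated as a flat sample.  Eyring conversions use
k = (k_B T/h)·exp(−ΔG‡/RT) with CODATA constants (k_B T/h ≈ 6.25×10¹² s⁻¹ at
300 K).

## Free-energy profiles

Umbrella windows span λ = −1.2 to 1.2 Å, spaced 0.0325 Å apart for
|λ| < 0.5 and 0.0975 Å outside, endpoints included.  The restraint is
k_f (λ − center)² with k_f = 200 kcal/mol/Å² and *no* ½ factor (the
convention of the restraint module this mirrors; a switch restores the ½
convention).  Screening mode runs 5 ps per window with no discard; detailed
mode 100 ps with the first 50 ps discarded, three replicate calculations.
Per-window initial states walk out sequentially from the neighboring
window's final state; production then runs all windows as one batch.

WHAM iterates the self-consistent window free energies to a 1e-7 kcal/mol
tolerance (max 1e5 iterations), with bin width half the inner window
spacing, raising a diagnostic error when the pooled histograms leave a gap.
ΔG‡ is max(F) over a barrier region minus min(F) over a reactant region,
with SEM over replicates.  Accuracy depends on histogram overlap: bias
stiffness should match window spacing (σ_window = √(kT/2k_f) of at least
~half the spacing).

## Reactive-conformation classifiers

Datasets take one frame per unique path per 30-fs window (windows slid in
5 fs steps over −200 to 0 fs; on the surrogates, paths are short and the
informative windows are the latest ones), weighted by TIS path counts.
Cross-validation is 5-fold with folds partitioning *unique paths*, so a
path's frames never straddle train and test; conformation-level splitting
would leak and inflate metrics.  Features are z-scored inside each training
fold.  Sample weights enter the logistic models directly and the scaler in
weight-aware form; the NN trainer realizes integer weights by row
duplication, which is exactly equivalent.

LR subsets of 5/10/20 features come from an L1 (LASSO) regularization path
bisected until exactly k coefficients survive (ties broken by coefficient
magnitude, then schema order), followed by an unregularized refit on the
subset; the selection runs once on the full dataset and the refit model is
cross-validated.  The NN is a single 70-unit ReLU hidden layer trained with
Adam (learning rate 0.001, L2 penalty α = 1e-4, batch size 200), with
subsets chosen by greedy forward selection on mean CV AUROC.  "Reactive-like"
classification uses the 0.5 probability threshold.

## Redesign

The design objective is f(s) = Σᵢ E_R,i(s) − Σᵢ E_NR,i(s) over N_R = N_NR = 3
representative structures, reported as f(s) − f(WT) (WT scores exactly 0).
Representative structures are the most confidently classified frames of each
true pathway class, by the mean of the LR and NN reactive probabilities
(ties broken by frame position).  Feasible designs must keep the reactive
structures no more than 5 kcal/mol less stable than WT's — applied to the
*sum* of reactive energies by default, mirroring the objective's sum (a
per-structure variant is available) — and results are returned within
20 kcal/mol of the best feasible sequence.  Search is exhaustive (vectorized
over the planted tables when available) or depth-first branch-and-bound with
an admissible additive+pairwise lower bound; the two provably return
identical sets and are cross-checked up to ~10⁵ sequences.

Screening a candidate measures (i) the weighted fraction of equilibrium
reactant-well frames classified reactive-like by each model, normalized by
the reference sequence, and (ii) a screening-mode ΔG‡.  Priority tiers:
tier 1 = negative objective score AND increased reactive-like population
under both models AND ΔG‡ ≤ reference; tier 2 = any two; tier 3 = the rest;
ties ordered by objective score.

## Redesign study on the surrogate family

The end-to-end study (`run_design_study`) uses a two-site toy space whose
"mutations" shift the gate tether's rest distance (site 0, token 1: −0.5 Å —
the planted accelerator; site 1, token 1: +0.15 Å — a mild decelerator), on
a family with the gate modulation midpoint at 1.7 Å, below the WT rest
distance of 2.0 Å: WT sits mostly on the barrier-raising flank and the
accelerator moves the gate onto the barrier-lowering side (~14× rate
contrast).  The energy model evaluates each variant's potential at the fixed
representative structures.

Two parameterizations of the *same* energy surface appear, differing only in
gate mass.  Pathway ensembles for classifier training use the slow (12 amu)
gate, where prereaction structure is informative.  Replicate TIS rates use
the fast (2 amu) gate: a single shooting-move chain cannot equilibrate a
~530-fs-memory environment coordinate at desk-scale move counts (the
replicate spread of log k reaches 1–2 without it), while the fast gate keeps
chains ergodic.  Equilibrium populations and PMF barriers are
mass-independent, so the trained classifiers and screening quantities apply
to both.  Rate significance uses the one-sided Mann–Whitney U test (mutant
larger) across 9 replicate estimates per variant with Benjamini–Hochberg
selection at α = 0.05.

Default study sizes (chosen to resolve the planted effects): 3 seed paths
per pathway type, 400 shooting moves per pathway ensemble (first 100
equilibration), training window (−30, 0) fs, k = 5 features; 9 interfaces
with 800 moves each (250 equilibration) and 30 ps × 4 flux replicas per rate
estimate; 8 × 40 ps equilibrium replicas for population screening.

## Statistics

Mann–Whitney U p-values are exact (scipy's exact method; full enumeration of
rank assignments, validated against a brute-force enumeration oracle) for
combined n ≤ 20 without ties — covering the 9-vs-9 replicate design — and a
tie-corrected normal approximation above.  Benjamini–Hochberg rejects the k*
smallest p-values where k* is the largest k with p₍ₖ₎ ≤ kα/m (boundary
inclusive).  The generic two-group gate pre-tests each group with
Shapiro–Wilk (normality) and the variance ratio with a two-sided F-test,
both at α = 0.05, dispatching to the pooled t-test only when both pass;
zero-variance groups go to Mann–Whitney.

## Sampling slow environments with shooting-move chains

A single shooting-move chain updates slow environment coordinates (the
gates) only through the ~100 fs dynamics segments of each move, so one
chain is effectively a single realization of the gate environment: class-
conditioned gate marginals estimated from few chains are realization noise,
inflating or deflating the apparent planted signal.  The classifier studies
therefore use many short chains (48 per pathway type, 150 moves each, the
first 50 discarded) started from diverse pools of 32 barrier-region
configurations; interface chains in rate calculations are staged instead
(seeded from the previous interface's ensemble).  The textbook cure —
replica-exchange TIS — is out of scope here.

Two honest limitations measured on the bundled mimic and worth knowing:
(i) the NR₋₀.₄ class inherently contains gate-favorable "near-miss" attempts
that climbed deep into the barrier-top modulation region before returning,
which compresses the realized linear R-vs-NR margin below the naive
committor-tilt prediction; the linear model's cross-validated AUROC in the
latest window consequently fluctuates around ~0.85–0.95 across sampling
realizations while the network (which exploits feature interactions) stays
above 0.9.  (ii) Strengthening the gate coupling does not widen the linear
margin, because near-miss contamination scales with the same modulation.

## What the surrogates do and do not show

The surrogates reproduce the *statistical structure* the pipeline assumes:
metastable states separated by a rare barrier along a scalar order
parameter, environment coordinates whose prereaction values carry (or,
for distractors, do not carry) information about attempt outcomes, and
sequence-dependent conformational energetics.  They do not contain real
force-field physics, solvent, electrostatics, or protein degrees of freedom,
and their barrier passage times (~100 fs) compress the enzyme's hierarchy of
timescales.  Passing tests therefore demonstrate correctness of the
sampling, estimation, learning and search machinery and the recoverability
of planted effects at matched statistical structure — not transferability of
any specific threshold or hyperparameter to a particular enzyme system.

## Numerical choices and degenerate inputs

WHAM anchors profiles to min F = 0 and is invariant to additive potential
constants.  Crossing profiles resample log-cumulative probabilities onto the
0.05 Å reporting grid; bottleneck ties break toward smaller λ.  The
decomposition at the bottleneck reconstructs the total probability to 1e-12
relative.  Degenerate cases are explicit errors: empty ensembles name their
interface, non-overlapping umbrella windows list their gaps, monotone
breaking-bond series raise an alignment error, zero total frame weight and
single-class training data are rejected, and SEM requires at least two
replicates.
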