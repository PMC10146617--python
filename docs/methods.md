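# Methods

This note documents the models, algorithms, and design choices behind
`tmslandscape`, in the order the pipeline runs them, together with what
the synthetic cohorts do and do not emulate.

## Overview

The pipeline analyzes EEG responses to a single subthreshold TMS pulse
delivered at one of three cortical sites (left motor cortex, left
prefrontal cortex, posterior cerebellar vermis) in two groups (patients
and healthy controls). Per subject it proceeds:

1. **ERP preprocessing** — artifact rejection, trial averaging,
   bandpass, decimation, re-referencing;
2. **source localization** — sLORETA inversion of the ERP, alpha-band
   (8–12 Hz) power, ROI aggregation;
3. **energy-landscape analysis** — binarization of network ROI activity,
   pairwise maximum-entropy (Ising) fits, stable-state (local minimum)
   selection, disconnectivity graphs, subject-wise pattern energies;
4. **statistics** — four paired/two-sample t-test comparisons per
   selected pattern, Bonferroni gating at α/n per network, a stricter
   relevance gate at p ≤ 5×10⁻⁵, and Cohen's d effect sizes.

Because no real recordings ship with the package, a synthetic-data
module generates all inputs with known ground truth: a toy head model,
planted Ising parameters per (group, condition), and multi-trial scalp
EEG in which binary network states amplitude-modulate alpha-band
sources.

## ERP preprocessing

Epochs are 2 s at 1000 Hz, with the TMS pulse at mid-epoch. The stage
order is fixed: trials whose absolute amplitude exceeds ±75 µV on any
channel are dropped; survivors are averaged pointwise into the ERP
x′(t) = (1/N) Σₖ x(t,k); the ERP is zero-phase FIR bandpassed to
1–50 Hz; decimated by 2 (anti-alias low-pass at 0.8× the new Nyquist,
then subsampled, so 2000 samples at 1000 Hz become 1000 samples at
500 Hz — the duration is unchanged); and finally re-referenced to the
common average. The pulse-locked halves are then exactly 500 samples
each (pre-TMS: samples 1–500; post-TMS: 501–1000).

Filters are Hamming-window FIRs applied forward-backward (zero phase;
the magnitude response is squared, so single-pass stopband figures
double in dB). The 1–50 Hz default uses ~0.5 s of taps, shifted to sum
exactly to zero so a DC offset is nulled exactly despite the low 1 Hz
band edge. Zero-phase filtering is implemented as one FFT convolution
with the filter's autocorrelation kernel after odd-reflection edge
padding, which is algebraically the forward-backward pass but a factor
of several faster on the many-channel source matrices.

## sLORETA inversion

The forward model is φ = K J + c·1 with lead field K (11 × 3N_V, three
free-orientation dipole components per voxel) and an arbitrary reference
constant c. The centering matrix H = I − 11ᵀ/N_E absorbs c; with
K_c = H K the operator is

    T = K_cᵀ (K_c K_cᵀ + α H)⁺,     ĵ = T H φ,

where the pseudoinverse is computed by eigendecomposition with a 1e-10
relative cutoff. Each voxel's estimate is standardized by its 3×3
diagonal block of the resolution matrix S = T K_c:

    power_v(t) = ĵ_v(t)ᵀ [S_vv]⁻¹ ĵ_v(t) ≥ 0.

For noiseless single-dipole data and α = 0, the standardized power is
maximal at the true voxel (zero localization error); the test suite
verifies this exhaustively for every voxel of a 60-voxel toy model. The
regularization weight α defaults to "auto" in the pipeline
(1e-4 · trace(K_c K_cᵀ)/N_E), a small value appropriate for
trial-averaged, high-SNR ERPs; it is exposed on the CLI.

Alpha-band power bandpasses each dipole component to 8–12 Hz (default
~0.2 s of taps — after the zero-phase double pass this still attenuates
a 20 Hz tone by >70 dB, while keeping the kernel short enough that
envelope modulation on a tenth-of-a-second scale survives), then
recomputes the standardized quadratic form, i.e. instantaneous squared
amplitude rather than a Hilbert envelope — the simpler estimator, and
monotone in the same quantity. ROI activity is the mean standardized
power over the ROI's voxels; windows are the two 500-sample epoch
halves.

## Energy-landscape analysis

Within each window, each network region is binarized against its own
window mean (strictly above → +1, else −1, so ties map to inactive).
The binary patterns σ ∈ {−1,+1}^M are modelled by the pairwise
maximum-entropy distribution

    P(σ) = exp(−E(σ)) / Z,   E(σ) = −Σᵢ hᵢσᵢ − Σ_{i<j} J_ij σᵢσⱼ.

All computations enumerate the 2^M patterns exactly (networks here have
M ≤ 7; the implementation allows M ≤ 12). The likelihood is concave and
is maximized by L-BFGS-B with analytic gradients and box bounds
|θ| ≤ 20; convergence means every model moment ⟨σᵢ⟩, ⟨σᵢσⱼ⟩ matches its
empirical counterpart within 1e-4. A plain gradient-ascent solver
(learning rate 0.1) is available as `method="gd"` and agrees with the
default at the optimum; the default exists because the calibration
studies fit tens of thousands of models. Degenerate data — a region
constant across a window — put the empirical mean on the boundary of
the achievable set; the corresponding field then saturates at the bound
with a warning rather than diverging. Subject-level fits add a small
ridge (l2 = 0.01 on the per-sample negative log-likelihood) because a
500-sample window visits only a fraction of patterns; the induced
moment mismatch is of order 0.02·|θ|.

Group-level landscapes are fitted per (group, condition) on all
subjects' binarized windows concatenated, which makes them invariant to
subject order. **Stable states** are patterns whose energy is no higher
than that of any of their M single-flip neighbors, ranked by energy with
ties broken by ascending pattern code; by default all local minima are
kept (the count is configurable). The selected set per network is the
union over the four group-condition landscapes. **Disconnectivity
graphs** are built by threshold filtration: states are activated in
ascending energy order while a union-find structure tracks connected
components of the activated hypercube; when two components each holding
a minimum merge, the activation energy is recorded as the barrier —
equal to the minimax single-flip path value, which the tests verify
against an independent Dijkstra-style widest-path oracle.

**Subject-wise energies**: for each subject and window, a subject-level
model is fitted to that subject's binarized series and the energies of
the selected group-level patterns are evaluated under it. (Evaluating
the group model on subject data instead is available via
`per_subject_model=False`.)

## Statistics

For every (site, network, selected pattern) cell, four comparisons are
run on the subject energies: controls pre vs post and patients pre vs
post (paired t-tests — the same subjects contribute both windows), and
controls vs patients within the pre and within the post window (Welch
two-sample t-tests — the groups differ in size). All tests are
two-sided. Cells with fewer than two observations per arm are flagged
untestable, never silently dropped; identical arms yield p = 1 with a
zero-variance note.

Bonferroni gating divides α = 0.05 by n, the number of selected patterns
for that network's landscape (per site by default; pooling across sites
is an option). Because each of the four comparison families tests n
patterns at α/n, the family-wise error is controlled at α *per family*;
jointly across the four families the bound is 4α, which is why the
calibration study reports per-family rates. The relevance gate
additionally requires p ≤ 5×10⁻⁵ and marks the most reliable
signatures. Cohen's d uses the pooled-SD convention for independent
arms and mean(diff)/sd(diff) for paired arms.

Measured calibration (reduced null cohorts, M = 5, 10+10 subjects,
1000 replicates): the largest per-family rate of any gated finding was
0.059, consistent with the nominal 0.05 up to Monte-Carlo error. The
mild excess sits in the within-group families, where the data-driven
selection of stable patterns is weakly correlated with the
pre/post contrast being tested — an inherent property of the
select-then-test procedure.

## Synthetic cohorts

Default cohort sizes follow the three-site study design (22/27, 9/18,
12/25 patients/controls) with 60 trials per subject. Ground truth draws
one base (h, J) per network (h ~ N(0, 0.3²), J ~ N(0, 0.15²)) shared by
all four (group, condition) cells; a planted effect adds a constant to
every patients-post coupling. A zero planted effect makes the groups
exchangeable, which the null-calibration study relies on.

The toy head model places 11 electrodes at fixed 10–20-style positions
on a unit sphere and voxels uniformly in an inner ball, assigned
round-robin to the 26 ROIs of the shipped network tables so every ROI
owns at least one voxel. The forward model is the current-dipole
potential in an unbounded homogeneous conductor — linear and full row
rank, with no claim of anatomical realism.

Binary network states are sampled i.i.d. from the cell's Boltzmann
distribution (no temporal Markov dynamics — the fitted model class is
itself static), dwell for 100 ms each (10 states per 1 s window), and
set each region's alpha carrier amplitude: 8 source units when active,
1 when inactive; non-network voxels hum at 0.5. Regions carry slightly
different carrier frequencies (8.8–11.2 Hz). The subject's clean source
time course is mixed through K once and repeated over trials with fresh
Gaussian sensor noise (σ = 2 µV) — the trial-locked signal-plus-noise
decomposition that ERP averaging assumes. A configurable 10% of trials
receive a 100 ms ±120 µV square pulse on one random channel to exercise
the rejection gate. One global seed fans out to per-subject substreams,
so enlarging a cohort leaves existing subjects bit-identical.

Two deliberate idealizations make the planted signal transmissible
through an 11-channel inverse, and should be read as properties of the
synthetic study, not of real data:

- **Resolution-matched source orientations.** Each voxel's rotating
  (quadrature) dipole pair is planted along the top two eigenvectors of
  its sLORETA resolution block, scaled so the standardized power of the
  reconstruction is independent of carrier phase. With arbitrary
  orientations, the rank-10 reconstruction is anisotropic and every
  power trace carries a large ripple at twice the carrier frequency.
- **A cohort-level alpha channel.** Carrier phases and background
  frequencies are drawn once per cohort, not per subject, so every
  subject's activity passes through the same lead-field mixing and
  group contrasts are not diluted by per-subject re-randomization.
- **Pulse-locked carrier phase.** The carrier time base restarts at the
  TMS pulse (emulating pulse-triggered alpha phase reset), so the pre
  and post windows see the identical carrier/dwell alignment. With a
  cohort-shared channel this matters for calibration: if the two windows
  passed through *different* effective mixings, that difference would be
  common to all subjects and the paired pre-vs-post tests would read it
  as a condition effect. With the reset in place, full-chain null
  cohorts show paired-family false-positive rates at the nominal level.

What the generator does *not* emulate: realistic head geometry or
BEM/FEM forward fields, eyeblink/muscle/TMS-pulse artifact morphology,
broadband or phase-varying alpha, per-subject anatomical or parameter
heterogeneity, and temporal state dynamics. Passing tests therefore
demonstrate that the implementation is correct and that the procedure
recovers planted effects under these controlled conditions — not that
11-channel sLORETA resolves 26 cortical ROIs in real recordings.
Indeed, the inverse operator's rank is at most 10, and the tests
document the consequences: with five simultaneously active incoherent
sources, inter-region leakage (~40% power per region pair) produces
slow beat interference, and exact per-sample state recovery is
impossible even without sensor noise. The test suite pins the exact
identity chain in the one regime where it holds (a single isolated
modulated source — the same regime as sLORETA's zero-error theorem) and
asserts a majority-contrast property for the full five-region network.

## Study sizes used by the replication suites

- Null calibration: 1000 replicates of a reduced cohort (M = 5, 10+10
  subjects, 500 i.i.d. patterns per subject-window), run at the
  landscape+statistics level — re-simulating scalp EEG would add
  runtime without touching the quantity under test, and the EEG stages
  are exercised end-to-end elsewhere.
- Planted-effect power: 50 replicates of the full pipeline (synthesis
  through statistics) at the left-motor cohort size (22/27), planted
  patients-post coupling shift +0.5, single analyzed network.
- Max-ent recovery: M = 5, 10⁵ samples. Landscape oracles: 100 random
  models, M ≤ 8. Localization sweep: all 60 voxels of the default toy
  head.

## Known limitations

- Exact enumeration restricts networks to M ≤ 12 regions (the shipped
  tables use 5–7); larger networks would need MCMC fitting, which is
  out of scope.
- The Bonferroni rule divides by the number of selected patterns only,
  as specified; the four comparison families are not jointly corrected.
- Subject-level fits on 500-sample windows are high-variance; the ridge
  stabilizes them but biases energies toward zero. Group-model
  evaluation is available as an alternative.
- The default-mode network ships without a constituent list and must be
  supplied by the user to be analyzed.
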