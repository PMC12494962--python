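# Methods

## The model

`ctcloop` simulates the loop between sensorimotor cortex and the
cerebellum as a network of 15 neural-mass populations: two laminar
modules (superficial and deep, each an excitatory/inhibitory pair) for
whisker M1 and S1, and single-population nodes for the pontine nuclei
(PN), cerebellar granule cells (GrC), Purkinje cells (PC), cerebellar
nuclei (CN), zona incerta (ZI), ventrolateral thalamus (VL) and the
medial posterior thalamic nucleus (Pom).  Cortical populations follow

    tau dr/dt = -r + F(I) + sqrt(tau) * sigma * xi(t),
    F(x) = x / (1 - exp(-beta x)),  beta = 1,

with tau_E = 6 ms, tau_I = 15 ms, sigma = 0.3 in superficial modules and
tau_E = 48 ms, tau_I = 120 ms, sigma = 0.45 in deep modules; constant
background currents drive the excitatory populations (4 superficial,
1 deep).  Local module weights are E->E 1.5, I->E -3.25, E->I 3.5,
I->I -2.5, with interlaminar projections supE->deepE (1) and
deepE->supI (0.75), plus the published S1<->M1 long-range set.
Subcortical populations are noise-free first-order nodes
(tau = 6 ms) with transfer `A * g(I + theta)`, `g(u) = u/(1-e^(-15u))`,
gains A = (PC 10, CN 1, ZI 1, VL 5, Pom 0.2, PN 1, GrC 1) and
backgrounds theta = (0.1, 21, -12, 0, 30, 0, 0).

**Why theta is an additive background.**  A common way to print this
transfer is `A x / (1 - exp(-beta (x - theta)))`, which reads theta as a
threshold.  Under that reading CN (theta = 21) and Pom (theta = 30) can
never fire: CN's only input is Purkinje inhibition, so its drive can
never reach a 21-unit threshold, and the entire ascending limb is dead.
Treating theta as a background current — CN is tonically active and held
down by PC, exactly the physiological picture — produces a functioning
loop; the package therefore evaluates `rate = A * g(I_syn + theta)`.
The literal printed form (which additionally has a pole at x = theta) is
retained behind `subcortical_transfer(..., form="printed")` and warns
near the pole.  Under either reading ZI (theta = -12, input -CN <= 0)
stays silent; its edges are carried but inert.

Connectivity of the subcortical limb: PC -| CN (-1), CN -| ZI (-1),
CN -> VL (+1), CN -> Pom (+0.2), ZI -| VL (-3), ZI -| Pom (-0.5),
Pom -> S1 (E +0.3 / I +0.1), Pom -> M1 (E +0.33 / I +0.5),
VL -> deep M1 excitatory (+0.6).

### Structured inputs

Three Ornstein-Uhlenbeck processes (`tau_x dx = -x dt +
sqrt(tau_x) sigma_x dW`; stationary SD `sigma_x/sqrt(2)`):

* **PC-private** (tau_x 80 ms, sigma_x 0.5), always on;
* **shared sensory** (80 ms, 2.0) to PC and superficial S1, always on —
  the joint sensory afferent responsible for the high S1-cerebellar
  coherence.  The cortical copy is delayed by 10 ms
  (`target_delays`), reflecting the shorter trigemino-cerebellar than
  lemniscal-thalamocortical latency;
* **preparatory ramp** (200 ms, 100) to the deep M1 module, on only
  during the pre-movement stage and switched off at movement onset.  It
  engages deep E with weight 1.0 and deep I with 0.85: joint E/I
  targeting lets the module cancel most of the enormous common drive,
  leaving a controlled net preparatory signal (a pure-E target would
  swing deep rates by ~25 units and leave a large switch-off transient
  inside the movement window).

**OU coupling.**  The processes enter the rate equation additively, like
the white-noise term (`ou_coupling="rate"`, the default).  Coupling them
into the input current instead (`"current"`) multiplies the shared
sensory input by the Purkinje gain A = 10, producing PC rate
fluctuations of SD ~14 that turn CN/VL into a dominant high-variance
relay and make the 0.6-magnitude stimulation currents irrelevant; both
conventions are implemented and the choice is logged in the config.

### Integration

Euler-Maruyama at dt = 0.1 ms (<= min tau / 60); noise applied as
`sigma * sqrt(dt/tau) * N(0,1)`; rates clipped at zero after each step
(transfer outputs are positive but additive noise is not).  Identical
(config, protocol, seed) give bit-identical traces.  A trial spans
[-600, +400) ms around movement onset; the analysis epochs are
[-200, 0) and [0, 200); the first 400 ms serve as burn-in.  The model
LFP of an area is `0.2 * r_supE + 0.8 * r_deepE` (deep pyramidal cells
dominate the field potential).

### Descending weights and their calibration

The four mossy-fiber-path strengths (M1deep->PN, S1deep->PN, PN->GrC,
GrC->PC) are not published.  They were calibrated once, with the
baseline stage-dependent phase structure as the objective and the other
parameters at their published values, and frozen at

    M1deep_E -> PN : 0.1      PN  -> GrC : 1.0
    S1deep_E -> PN : 0.02     GrC -> PC  : 2.0

A coarse grid restricted to 0.25-2 was evaluated first; at every such
point the operating currents at PN and VL are tens of units, so the
published 0.6-magnitude optogenetic currents cannot gate anything and
all perturbation experiments degenerate.  The frozen values place PN at
an O(1) input (a -0.6 pulse suppresses most of its drive) and keep
CN (~5) and VL (~24) active and responsive.

### Dynamical character of the working point, and a known limitation

At the calibrated working point the closed loop is a damped ~6 Hz
oscillator (the deep laminar modules resonate near 6.5 Hz and the loop
delay matches); with all noise removed the network settles onto a stable
limit cycle rather than a fixed point, so "noiseless steady state equals
the fixed-point solution" holds only for open-loop configurations (e.g.
GrC->PC = 0), which is how the integrator/solver cross-check is run.

The model reproduces: cortex-leads (negative) phase relations before
movement onset for both pairs; S1-PC correlations exceeding M1-PC
correlations in both epochs with the S1 correlation growing from
preparation to movement; unchanged pre-movement phases under VL
inhibition; and much larger M1 than S1 LFP responses to PC stimulation.
It does **not** reproduce the positive (cerebellum-leads) movement-epoch
phase relation for M1 (S1 is weakly positive).  The obstruction is
structural: every ascending route (PC -| CN -> VL/Pom -> cortex) passes
through exactly one inhibitory stage, so Purkinje influence on cortex is
negatively correlated and cannot create a positive cerebellum-leads
correlation peak; such a peak can only arise from common-input relay
(the shared sensory afferent), and the descending return of the deep
modules' intrinsic fluctuations always contributes a stronger
cortex-leads lobe at minus the descending delay.  This held across every
reading explored (OU coupling, ramp targeting, sensory delays,
descending source layers, CN-silent versus CN-pinned branches); the
corresponding acceptance tests are left failing rather than weakened.

## The in-silico experiments

Ensembles of 10 independent simulations (distinct noise seeds, 200
trials each).  Per simulation the phase relation — the signed lag of the
maximum of the +-100 ms normalised cross-correlogram, negative when the
cerebral signal precedes the cerebellar one — and the zero-lag Pearson
correlation between each cortical LFP proxy and the PC rate are averaged
over trials per epoch.  Perturbation ensembles are paired: the control
and perturbed arms of a simulation share every random draw; inhibition
pulses (-0.6 to PN or VL) last 500 ms with the analysed 200 ms epoch
centred in the pulse, run separately per epoch.  PC stimulation uses
trains of +0.6, 100 ms pulses at 2 s intervals (the experimental
photostimulation protocol); responses are peak absolute deviations of
the stimulus-locked average LFP from the 200 ms pre-pulse baseline —
single-pulse responses are buried in the loop's ongoing ~6 Hz
fluctuations.  Ensemble contrasts are paired t-tests with Cohen's
d_z = t/sqrt(n); Mann-Whitney contrasts report the rank-biserial
r = 1 - 2U/(n1 n2).

## The analysis chain

Applied identically to model traces and (synthetic) recordings:

* **Movement onsets** — absolute angular speed of the 10 ms-smoothed
  whisker trace, differentiated over the smoothing scale, thresholded at
  50 deg/s with 25 ms gap closing; onsets require >= 200 ms of movement
  preceded by >= 400 ms of quiescence; resting windows are 200 ms
  centred in >= 400 ms quiescent stretches.  Per-sample gradients are
  unusable at 1 kHz: at a realistic 0.5 deg noise SD they cross any
  threshold constantly, hence the scale-matched differentiation.
* **Phase relation** — within-window demeaned cross-correlogram in
  correlation-coefficient units, lags +-100 ms; peak ties resolve to the
  smallest |lag| (a +- tie to the negative lag, flagged); zero-variance
  windows are flagged invalid and excluded from averages.
* **Shuffle null** — the observed peak is z-scored against peaks of 100
  window pairs drawn at independent random positions of the two
  recordings; Z > 2 is called significant.  False-positive rate on
  independent signals is <= 5% (verified over 1000 pairs).
* **Peak counting** — topographic prominence >= 0.01, width >= 20 ms at
  half prominence, separation >= 20 ms (500 samples at the 25 kHz grid).
* **Mutual information** — plug-in histogram estimate; continuous
  variables are quantile-binned with ceil(n^(1/3)) equal-occupancy bins
  per dimension.  No bias correction: for independent inputs the
  estimate approaches (k-1)^2/(2 n ln 2) bits (~0.015 at n = 1e5)
  rather than zero.  A sqrt(n)-bin rule was rejected: its plug-in bias
  (~0.7 bits at n = 1e5) would swamp the Gaussian closed-form check.
* **Spike density** — 1 ms binned counts convolved with a unit-area 8 ms
  Gaussian kernel; the integral equals the spike count.
* **Trial correlation matrix** — Pearson r across trials between 10 ms
  bins of two units' spike densities over -400..+400 ms (80 x 80, not
  baseline-aligned); the asymmetry index is mean(below diagonal) -
  mean(above diagonal) of the 20 x 20 epoch submatrix, diagonal
  excluded; zero-variance bins give flagged NaN.
* **Whisker-LFP phase** — computed in the +20..+170 ms post-onset window
  with the LFP as first argument (negative = LFP precedes movement), on
  the 1 kHz-downsampled LFP (8th-order anti-aliased decimation).
* **Band power** — analytic Morlet scalogram (omega0 = 6, 48
  geometrically spaced frequencies over 1-30 Hz), averaged over 3-10 Hz
  in the 500 ms before/after each stimulus.  Implemented in-package
  (no wavelet library in the environment); comparisons are ratio-based
  and insensitive to the wavelet details.
* **Evoked LFP responses** — stimulus-locked mean, zero-phase 4th-order
  Butterworth low-pass at 80 Hz, differentiated; onset is the first
  post-stimulus crossing of the identically processed non-stimulation
  baseline's mean +- 2 SD; the peak is the furthest deviation from the
  pre-stimulus mean and is reported regardless of onset significance.

## The synthetic-recording generator

`ctcloop.synth` emulates the statistical structure the analyses assume,
with every injected dependency recorded as ground truth: whisker traces
(quiescence plus sinusoid-with-jitter bouts, raised-cosine envelopes,
>= 500 ms enforced gaps; defaults 0.3 bouts/s, 250-700 ms, 6-12 Hz,
15 deg, 0.5 deg noise), multichannel LFP (16 M1 + 16 S1 + 12 cerebellar
channels; per-area latent pink-noise sources band-limited to 1-80 Hz,
cerebral copies delayed by the target phase relation, with configurable
shared-variance fraction and SNR, and a 20 ms crossfade where the lag
flips at movement onset), Purkinje spike trains (inhomogeneous Poisson
with 3 ms simple-spike dead time, independent ~1 Hz complex spikes each
followed by >= 8 ms simple-spike silence, optional rate modulation locked
to a driver), and stimulus trains (gaps drawn uniformly from 0.5-3.5 s
in 0.5 s steps).  The pink-noise spectrum is a stand-in; real
per-channel LFP spectra differ, so green round-trip tests establish that
the analyses recover injected structure, not that the surrogates are
biophysically realistic.

## Numerical choices

Transfer functions are evaluated through a stable rectifier (series
expansion within |beta*u| < 1e-4 of the removable singularity,
asymptotic branch below beta*u = -30).  The fixed-point solver uses
damped iteration (damping 0.05) with a root-finder fallback, and prefers
a CN-silent solution branch when one exists.  Cross-correlations are
FFT-based; normalisation is n * sd_x * sd_y (window-length n), so lag 0
equals the Pearson coefficient.  All generators and simulations take
explicit seeds; no global RNG state is used anywhere.
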