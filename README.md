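# ctcloop

Neural-mass simulation and electrophysiology analysis of the
cerebello-thalamo-cortical loop during whisker sensorimotor behaviour.

The package is for computational and systems neuroscientists who want to
study **stage-dependent communication between cerebral cortex and
cerebellum**: before a self-initiated movement, cortical activity leads
cerebellar activity (a copy of the motor plan descending via the pontine
nuclei); during execution the directionality reverses (cerebellar output
ascending via the thalamus).  It provides

* a 15-population firing-rate model of the loop — laminar M1 and S1
  modules, pontine nuclei (PN), granule cells (GrC), Purkinje cells
  (PC), cerebellar nuclei (CN), zona incerta (ZI), ventrolateral (VL)
  and medial posterior (Pom) thalamus — with anatomically signed
  connectivity, Ornstein-Uhlenbeck sensory/preparatory inputs and
  simulated optogenetic current pulses;
* the analysis chain used on such recordings: cross-correlogram **phase
  relations** (the signed lag of the peak, negative = cerebrum leads)
  with shuffle-null Z-scores, mutual information, spike-density
  functions and trial-by-trial correlation matrices, whisking-bout
  detection and event statistics, wavelet band power, and evoked-LFP
  onset/peak measures;
* a **synthetic-recording generator** (whisker angle, 16+16+12 LFP
  channels with controlled inter-area lags, Purkinje simple/complex
  spike trains) whose ground truth validates every analysis by round
  trip.

## Model

Cortical populations obey Wilson-Cowan-type rate dynamics

$$\tau\,\dot r = -r + F(I) + \sqrt{\tau}\,\sigma\,\xi(t),\qquad
F(x) = \frac{x}{1 - e^{-\beta x}},$$

with fast superficial ($\tau_E$=6, $\tau_I$=15 ms) and slow deep
($\tau_E$=48, $\tau_I$=120 ms) laminar modules; subcortical nodes are
noise-free with transfer $A\,g(I+\theta)$, where $\theta$ is a tonic
background (the cerebellar nuclei fire tonically, $\theta$=21, and are
held down by Purkinje inhibition).  The area LFP proxy weights
superficial:deep excitatory rates 20:80.  Movement stages differ only in
a preparatory ramp input to deep M1 that is on before movement onset and
switched off at it.  See `docs/methods.md` for every parameter, the
calibration of the four unpublished descending weights, and the known
limitations (including one honestly unreproduced result).

## Worked example

```python
from ctcloop import ExperimentSpec, run_baseline_ensemble

result = run_baseline_ensemble(
    ExperimentSpec("baseline", n_sims=4, trials_per_sim=60, seed=7))
```

`examples/baseline_phase_relations.py` runs exactly this and prints

```
epoch  pair   phase (ms)  Pearson R
pre    M1-PC       -6.27     +0.741
pre    S1-PC       -1.39     +0.836
move   M1-PC       -9.28     +0.765
move   S1-PC       +1.88     +0.886
```

Reading: in the pre-movement epoch both cortical LFP proxies *lead*
Purkinje activity (negative phase relations — the preparatory signal
travels down through the pons), S1 correlates more strongly with PC
than M1 does in both epochs (the shared sensory afferent), and the S1
correlation grows from preparation to movement.  The other scripts in
`examples/` demonstrate the in-silico PN/VL inhibition and PC
stimulation experiments (`perturbations.py`, `pc_stimulation.py` — the
M1 response to Purkinje stimulation is about 2.3x the S1 response,
paired d_z ≈ 6) and the analysis round trips on synthetic recordings
(`synthetic_round_trip.py`, `spike_and_behavior_analysis.py`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's core pipeline from scratch — a reduced baseline
ensemble of the loop model (per-epoch phase relations and correlations)
and a ground-truth round trip on a synthetic recording (bout detection,
injected-lag recovery) — printing the measures and writing the results
file.  All randomness derives from `--seed`.

## Layout

```
src/ctcloop/
  populations.py  connectome.py  transfer.py   # model structure
  noise.py        network.py                   # OU inputs, simulation
  experiments.py                               # ensemble experiments
  analysis.py     behavior.py                  # analysis chain
  synth.py        io.py                        # surrogate data, HDF5
  stats.py                                     # paired t / MWU contrasts
examples/          # one narrative script per capability
docs/methods.md    # model, assumptions, calibration, limitations
```
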