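"""In-silico optogenetic inhibition of the pontine and thalamic relays.

Runs paired control-vs-inhibition ensembles: a -0.6 current is applied to
the pontine nuclei (descending relay) or the ventrolateral thalamus
(ascending relay) in 500 ms pulses covering the analysed epoch; the
control arm of each simulation shares every noise draw.  Printed per
epoch and pair: control and inhibited mean phase relations with the
paired test.  The VL manipulation leaves the pre-movement phases
untouched (they are set by the descending pathway).
"""

from ctcloop import ExperimentSpec, run_perturbation_ensemble

for target in ("PN", "VL"):
    res = run_perturbation_ensemble(
        target, ExperimentSpec(f"{target.lower()}_inhibition", n_sims=4,
                               trials_per_sim=60, seed=11))
    print(f"\n=== {target} inhibition (-0.6, 500 ms pulses) ===")
    for epoch in ("pre", "move"):
        for pair in ("M1", "S1"):
            ctrl = res.sim_values("phase_ms", epoch=epoch, pair=pair,
                                  condition="control")
            inhib = res.sim_values("phase_ms", epoch=epoch, pair=pair,
                                   condition="perturbed")
            c = res.contrasts[f"phase_{epoch}_{pair}"]
            print(f"{epoch:5s} {pair}-PC: control {ctrl.mean():+6.2f} ms, "
                  f"inhibited {inhib.mean():+6.2f} ms  (p={c.p:.4f}, "
                  f"d_z={c.effect_size:+.2f})")
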