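"""Baseline stage comparison of the loop model.

Simulates a small ensemble of movement trials and prints the phase
relation (signed lag of the peak cross-correlation; negative = cortex
leads the Purkinje cells) and the zero-lag Pearson correlation of each
cortical LFP proxy with PC activity, per epoch.  Expected structure:
cortex leads before movement onset (negative phases, driven by the
preparatory ramp descending through the pons), S1 correlates more
strongly with PC than M1 does (shared sensory input), and the S1
correlation grows from preparation to movement.
"""

from ctcloop import ExperimentSpec, run_baseline_ensemble

result = run_baseline_ensemble(
    ExperimentSpec("baseline", n_sims=4, trials_per_sim=60, seed=7))

print(f"{'epoch':6s} {'pair':6s} {'phase (ms)':>10s} {'Pearson R':>10s}")
for epoch in ("pre", "move"):
    for pair in ("M1", "S1"):
        ph = result.sim_values("phase_ms", epoch=epoch, pair=pair)
        r = result.sim_values("pearson_r", epoch=epoch, pair=pair)
        print(f"{epoch:6s} {pair}-PC  {ph.mean():+10.2f} {r.mean():+10.3f}")

c = result.contrasts["pearson_M1_vs_S1_move"]
print(f"\nmovement epoch, M1 R vs S1 R (paired): {c}")
print("negative t/d_z: the S1 correlation exceeds the M1 correlation")
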