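"""Does the reversion screen detect a known fitness cost?

Simulates four cages of 800 mosquitoes founded all-heterozygous, with a 20%
viability cost to resistant homozygotes (w_SS, w_RS, w_RR = 1, 1, 0.8), drift,
and genotyping subsamples of 90 every other generation - then runs the same
selection-vs-drift screen used on the real cage data.
"""

import kdrcost as k

cfg = k.CageSimConfig(
    N=800, founder=(0.0, 1.0, 0.0), fitness=k.FitnessSpec(1.0, 1.0, 0.8),
    sampled_generations=(1, 3, 5, 7, 9), sample_size=90, n_cages=4, seed=3,
)
series, truth = k.simulate_cage_experiment(cfg)
report = k.reversion_analysis(series, k.DriftConfig(N=800, n_sims=10_000, seed=4))

for s in series:
    true_final = truth["allele_freq"][s.cage_id][9]
    obs_final = k.allele_frequency(s.samples[-1]).p_R
    print(f"cage {s.cage_id}: true R freq at F9 = {true_final:.3f}, sampled = {obs_final:.3f}")
print(f"\nFisher combined HWE p:   {report.hwe_global.global_p:.2e}")
print(f"Fisher combined drift p: {report.drift_global.global_p:.2e}")
print(f"OLS slope: {report.trend.slope:+.4f} per generation")
print()
print("Reading: with a 20% homozygote cost the R allele declines from 0.5 and")
print("the combined drift p-value is far below 0.05 - the screen attributes")
print("the decline to selection, as designed.")
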