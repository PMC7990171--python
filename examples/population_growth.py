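"""Life-table growth components and fitness-cost ratios.

Builds a small synthetic adult-female cohort (50 females, Gompertz mortality,
eggs every 3 days) to show the schedule arithmetic, then applies the growth
algebra (T = ln(R0)/r, cost ratio = 1 - R0_res/R0_susc) to the published
strain means of the four congenic strains.
"""

import kdrcost as k

# -- synthetic cohort: records -> schedule -> R0, r, T ------------------------
cfg = k.CohortSimConfig(n0=50, replicates=1, seed=42)
(records,), vitals, truth = k.simulate_life_table(cfg)
g = k.growth_summary(records, vitals, replicate="demo")
print(f"synthetic cohort: R0 = {g.R0:6.1f} (analytic truth {truth['R0']:.1f}), "
      f"r = {g.r:.3f}/day (truth {truth['r']:.3f}), T = {g.T:.2f} days")

# -- growth algebra on the published strain means ------------------------------
R0 = {"ROCK": 304.0, "KR": 302.0, "CR": 207.0, "CKR": 179.0}
r = {"ROCK": 0.80, "KR": 0.83, "CR": 0.79, "CKR": 0.75}
print("\nstrain   R0      r     T=ln(R0)/r   cost ratio vs ROCK")
for strain in ("ROCK", "KR", "CR", "CKR"):
    T = k.generation_time(R0[strain], r[strain])
    cost = k.fitness_cost_ratio(R0[strain], R0["ROCK"])
    print(f"{strain:<6} {R0[strain]:5.0f}  {r[strain]:.2f}   {T:6.2f}       {cost:5.2f}")

print("\nReading: the strains carrying CYP-mediated resistance (CR, CKR) pay a")
print("32-41% cost in net reproduction; kdr alone (KR) costs nothing by this")
print("metric, and generation times barely differ.")
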