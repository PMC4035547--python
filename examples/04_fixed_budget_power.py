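"""Design question: given a fixed sequencing budget, go wide or deep?

Compares four designs spending almost the same number of reads
(families x depth between 12,000 and 15,000) at p=0.3, sigma_e=4, b=1.
Many shallowly sequenced families beat few deeply sequenced ones.
"""

from poolassoc import budget_grid_designs, fixed_budget_grid, power_table

results = fixed_budget_grid(
    13000, budget_grid_designs(p=0.3, sigma_e=4.0), n_reps=400, seed=11
)
table = power_table(results)
print(table[["n_families", "mean_depth", "effort", "power", "mc_se"]].to_string(index=False))
print("\nPower falls as depth replaces sample size at a fixed read budget.")
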