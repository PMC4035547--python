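"""Attenuation of the allele-effect estimate across sequencing depths.

Replicates the estimator 200 times per depth at n=4000 families, p=0.5,
b=1, sigma_e=4, and compares the replicate-mean raw slope with the theory
b/(1 + 3/S_T), plus the recovered slope after correction.
"""

from poolassoc import DepthModel, DesignPoint, run_effect_study

print("depth   mean raw   theory   mean corrected")
for j, depth in enumerate((3, 7, 15, 30)):
    design = DesignPoint(
        n_families=4000,
        depth_model=DepthModel("constant", depth),
        p=0.5,
        sigma_e=4.0,
        b=1.0,
    )
    res = run_effect_study(design, n_reps=200, seed=7, design_index=j)
    print(
        f"{depth:5d}   {res.mean_b_hat:8.3f} {res.expected_attenuation:8.3f} "
        f"{res.mean_b_corrected:10.3f}"
    )
print("\nRaw slopes track 1/(1+3/depth); corrected slopes recover the true b=1.")
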