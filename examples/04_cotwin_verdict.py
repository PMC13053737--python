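"""Run the co-twin control analysis and classify the confounding pattern.

Generates a cohort where the SES-outcome association is purely genetic
(direct path zero, genetic cross-path positive): the within-pair effect
should vanish in MZ pairs but persist in DZ pairs, and the classifier should
call genetic confounding.
"""

from cotwin import (
    classify_confounding,
    compare_within_mz_dz,
    fit_cotwin_models,
    oracle_coefficients,
    scenario_config,
    simulate_cohort,
)

cfg = scenario_config(
    "genetic", n_pairs_mz=1500, n_pairs_dz=1500, dz_opposite_sex_fraction=0.0,
    n_waves=3, dropout=0.1, pair_sd=(3.5, 0, 0), individual_sd=(3.5, 0, 0),
)
cohort, _ = simulate_cohort(cfg, seed=4)
cohort.persons["ses_z"] = (cohort.persons["ses"] - cfg.ses_mean) / cfg.ses_sd

result = fit_cotwin_models(cohort, "ses_z", cohort.visits[["person_id", "age_years", "y"]])
print(result.table[["stratum", "component", "estimate", "se", "p"]].round(3).to_string(index=False))

o = oracle_coefficients(cfg)
print(f"\nanalytic oracle: within_MZ = {o.within_mz:.2f}, within_DZ = {o.within_dz:.2f}, "
      f"between_MZ = {o.between_mz:.2f}, between_DZ = {o.between_dz:.2f}")

z, p = compare_within_mz_dz(result)
print(f"MZ vs DZ within-effect comparison: z = {z:.2f}, p = {p:.4f}")

verdict = classify_confounding(result)
print(f"verdict: {verdict.verdict}")
print(f"attenuation ratios: MZ {verdict.evidence['ratio_MZ']:.2f}, DZ {verdict.evidence['ratio_DZ']:.2f}")
# A within/between ratio near zero in MZ pairs only -- with a significant
# MZ-vs-DZ contrast -- is the genetic-confounding signature; equal
# attenuation in both zygosity groups would point to the shared environment.
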