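"""Calibrate the participation logit and wage-based productivity weights.

Draws survey-like microdata (ages 15-74) from known coefficients, refits
both regressions and derives the education-specific productivity factors
W_e = exp(beta_edu), anchored at 1 for upper secondary.
"""

import demodep as d

spec = d.SyntheticWorldSpec()
survey, (true_lfp, true_wage) = d.make_survey_microdata(spec, n=57_411, seed=0)

lfp = d.fit_lfp_logit(survey)
wage = d.fit_wage_poisson(survey)
weights = d.derive_productivity_weights(wage)

print(f"survey records: {len(survey)} (share active {survey.in_labor_force.mean():.3f})")
for sex in ("male", "female"):
    diag = lfp.diagnostics[sex]
    print(
        f"{sex:>6}: max-rescaled R2 = {diag['max_rescaled_r2']:.3f}, "
        f"c-statistic = {diag['c_statistic']:.3f} (n = {diag['n']})"
    )
print()
print("productivity weights (reference upper_secondary = 1):")
for lvl in spec.ladder.levels:
    import numpy as np
    truth = float(np.exp(true_wage.edu.get(lvl, 0.0)))
    print(f"  {lvl:<16} fitted {weights[lvl]:.3f}   generating value {truth:.3f}")
print()
print("predicted participation, postsecondary vs no education (males):")
for band in ("25-29", "45-49", "65-69"):
    hi = d.predict_participation_rate(lfp, "male", band, "postsecondary")
    lo = d.predict_participation_rate(lfp, "male", band, "no_education")
    print(f"  {band}: postsecondary {hi:.3f}, no education {lo:.3f}")

# A weight of 2 means one such worker counts as two reference-education
# workers in the productivity-weighted dependency ratio's denominator.
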