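"""Build a weighted base population from aggregate estimates.

Generates a synthetic age x sex x education table for a stylised ageing
population of 1,000,000 persons, then samples it down to a weighted case
file at a 0.5% fraction (small cells are oversampled with reduced weights).
"""

import demodep as d

spec = d.SyntheticWorldSpec(total_population=1_000_000)
estimates = d.make_aggregate_estimates(spec, seed=0)
cfg = d.ScenarioConfig(tfr=1.7, sampling_fraction=0.005)
base = d.build_base_population(estimates, cfg)

print(f"aggregate cells:   {len(estimates)}")
print(f"cases generated:   {base.n_cases}")
print(f"weighted persons:  {base.weighted_total:,.0f}")
print(f"invariant check:   {d.validate_frame(base) or 'no violations'}")
print()
print("age pyramid by education tier (weighted persons, top rows):")
print(d.pyramid_summary(base).head(8).to_string(index=False))

# The weighted total reproduces the aggregate table exactly; each case in a
# cell carries count / n_cases persons, so small cells keep extra cases with
# proportionally smaller weights to damp Monte Carlo noise.
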