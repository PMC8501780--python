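"""The three dependency ratios on a small, fully transparent frame.

ADR counts heads by age; LFDR counts actual labour-force status; PWLFDR
additionally weighs each worker by the wage-derived productivity of their
education level.
"""

import pandas as pd

import demodep as d

rows = [
    # 30 weighted children, 12 weighted elderly, 60 working-age
    {"age_group": "5-9",   "sex": "female", "education": "none",
     "activity": "not_applicable", "weight": 30.0},
    {"age_group": "70-74", "sex": "male",   "education": "primary",
     "activity": "inactive", "weight": 12.0},
    {"age_group": "35-39", "sex": "male",   "education": "no_education",
     "activity": "active", "weight": 20.0},
    {"age_group": "40-44", "sex": "female", "education": "upper_secondary",
     "activity": "active", "weight": 25.0},
    {"age_group": "45-49", "sex": "male",   "education": "postsecondary",
     "activity": "active", "weight": 10.0},
    {"age_group": "50-54", "sex": "female", "education": "upper_secondary",
     "activity": "inactive", "weight": 5.0},
]
frame = d.PopulationFrame(pd.DataFrame(rows), 2015)
weights = d.ProductivityWeights(
    weights={"no_education": 0.36, "primary": 0.58, "lower_secondary": 0.78,
             "upper_secondary": 1.0, "postsecondary": 2.03}
)

print(f"ADR    = {d.adr(frame):.4f}   (children + elderly per working-age person)")
print(f"LFDR   = {d.lfdr(frame):.4f}   (inactive of any age per active person)")
print(f"PWLFDR = {d.pwlfdr(frame, weights):.4f}   (inactive per reference-worker equivalent)")

unit = d.ProductivityWeights(weights={lvl: 1.0 for lvl in d.DEFAULT_LADDER.levels})
print(f"PWLFDR with unit weights = {d.pwlfdr(frame, unit):.4f} (equals the LFDR exactly)")

# (30 + 12) / 60 = 0.70 dependents per working-age head, but only
# (30 + 12 + 5) / 55 ~= 0.855 inactives per active; weighting the 55 actives
# by productivity (0.36*20 + 1.0*25 + 2.03*10 = 52.5) gives 47/52.5 ~= 0.895.
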