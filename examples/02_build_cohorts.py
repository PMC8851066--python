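"""Select the prevalent and newly taken-in-care cohorts and standardise rates.

Prevalent cases: ages 18-65 with a schizophrenia-spectrum contact during the
2015 recruitment year. Newly taken-in-care: the 18-40 subset with a clean
history (no prior diagnosis ever; no psychiatric admission or two consecutive
antipsychotic dispensings in the 2-year lookback).
"""

import quadim as q
from quadim.model import default_standard_population

params = q.SimulationParams(seed=7, regions=[
    q.RegionParams(name=f"R{i}", n_inhabitants=100_000) for i in range(3)])
tables = q.simulate(params)

prevalent = q.select_prevalent(tables)
new = q.select_new(prevalent, tables)

print(f"prevalent cohort:          {len(prevalent):5d} members")
print(f"newly taken-in-care:       {len(new):5d} members")

rate = q.standardised_treatment_rate(prevalent, tables.patients,
                                     tables.standard_population, (18, 65))
irate = q.standardised_treatment_rate(new, tables.patients,
                                      default_standard_population(18, 40), (18, 40))
print(f"age-standardised treated prevalence: {rate:5.1f} per 10,000 aged 18-65")
print(f"age-standardised incidence:          {irate:5.2f} per 10,000 aged 18-40")
print("\nWith default parameters the generator plants 39.2 and 3.1 per 10,000 —")
print("the recovered rates differ from those only by binomial noise.")
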