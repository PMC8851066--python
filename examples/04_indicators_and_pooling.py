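"""Compute the indicator catalogue per region, pool across regions and test
between-region homogeneity (chi-square / ANOVA) with I-squared heterogeneity.
"""

import pandas as pd

import quadim as q

params = q.SimulationParams(seed=3, regions=[
    q.RegionParams(name="A", n_inhabitants=60_000, prevalence_per_10k=300),
    q.RegionParams(name="B", n_inhabitants=60_000, prevalence_per_10k=300,
                   mean_outpatient_contacts_py=16.0, p_psychotherapy=0.05),
    q.RegionParams(name="C", n_inhabitants=60_000, prevalence_per_10k=300),
])
tables = q.simulate(params)
prevalent = q.select_prevalent(tables)
estimates = q.compute_indicators(tables, prevalent)
pooled = q.pool_indicators(estimates)

show = ["mean_outpatient_contacts", "access_psychotherapy", "persistent_community",
        "readmission_30d"]
wide = estimates[estimates.indicator_id.isin(show)].pivot_table(
    index="indicator_id", columns="region", values="estimate")
table = wide.join(pooled.set_index("indicator_id")[["pooled", "p_homogeneity", "I2"]])
pd.set_option("display.width", 120)
print(table.round(3).to_string())
print("\nRegion B was generated with fewer contacts and lower psychotherapy access:")
print("those two rows show small homogeneity p-values and high I2 (most of the")
print("between-region variability is real heterogeneity, not sampling noise),")
print("while the rows with identical planted values do not.")
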