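"""Generate a small two-region synthetic HCU dataset with planted indicator values.

The generator writes the full CSV suite (registry, contacts, admissions,
dispensings, labs, deaths, reference tables) plus planted_truth.csv, the table
of true values every downstream indicator estimate can be checked against.
"""

from pathlib import Path

import quadim as q

out = Path("scratch_example_data")
params = q.SimulationParams(seed=42, regions=[
    q.RegionParams(name="nord", n_inhabitants=20_000, prevalence_per_10k=300),
    q.RegionParams(name="sud", n_inhabitants=20_000, prevalence_per_10k=300,
                   mean_outpatient_contacts_py=18.0, p_psychosocial=0.35),
])
tables = q.simulate(params)
q.validate_tables(tables)
q.write_tables(tables, out)
q.planted_truth(params).to_csv(out / "planted_truth.csv", index=False)

for name, n in tables.counts().items():
    print(f"{name:22s} {n:>7d} rows")
print(f"\nWrote the table suite to {out}/.")
print("Row counts scale with the planted prevalence (~300/10,000 here): each case")
print("gets an index contact plus a year of service, drug and lab events.")
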