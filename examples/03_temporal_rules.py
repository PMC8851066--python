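"""The temporal rules on one hand-made patient history.

Days are integer offsets from the index date; follow-up is [0, 365).
"""

import pandas as pd

import quadim as q
from quadim import episodes as ep

ddd = pd.DataFrame({"atc_code": ["N05AH03", "N05AX12"], "ddd": [10.0, 15.0]})

# three olanzapine dispensings: 30 days supply each, gaps of 59 and 95 days
disp = pd.DataFrame({
    "patient_id": ["p"] * 3,
    "day": [0, 89, 214],
    "atc_code": ["N05AH03"] * 3,
    "total_amount": [300.0, 300.0, 300.0],
})
episodes = ep.build_supply_episodes(disp, ddd)
for e in episodes:
    print(f"episode: days [{e.start_day}, {e.end_day}) from {e.n_dispensings} dispensing(s)")
print("The 59-day gap chains (gap < 90); the 95-day gap starts a new episode,")
print("so this patient discontinued treatment:")
segs = ep.supply_segments(disp["day"].to_numpy(), disp["total_amount"].to_numpy(), 10.0)
print("  persistent over follow-up?", ep.is_persistent_drug(segs, (0, 365)))

# community continuity: contacts + a residential stay bridging the summer
coverage = [(0, 1), (85, 86), (160, 290), (350, 351)]  # contact, contact, CRF stay, contact
print("\ncommunity persistence (contacts every <=90 days, inpatient days count):",
      ep.is_persistent_community(coverage, 0))

# polytherapy: a second antipsychotic overlapping days 20..80
poly = ep.polytherapy_days({"N05AH03": segs, "N05AX12": [(20, 80)]}, (0, 365))
print(f"days on >=2 antipsychotics: {poly} (>30 counts as polytherapy)")

# readmission and post-discharge timeliness
adm, dis = [100, 131], [124, 140]
print("readmission within 7 days of each discharge: ",
      ep.readmission_within(adm, dis, 7).tolist())
print("CMHC contact within 14 days of each discharge:",
      ep.contact_within_after_discharge([85, 138, 150], dis, 14).tolist())
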