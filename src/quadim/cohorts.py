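"""Cohort phenotyping: prevalent and newly taken-in-care patients.

*Prevalent* cases are residents aged 18-65 with at least one mental-health
service contact (outpatient/home/day-care contact or GHPW/CRF admission)
carrying a schizophrenia-spectrum diagnosis during the recruitment window;
the index date is the first such contact and follow-up runs 365 days from it.
Patients whose registry coverage does not span the full follow-up year are
excluded, except that patients who die during follow-up are retained with
person-years censored at death: they contribute to the mortality indicator
(otherwise the SMR would be undefined) but are excluded from the denominators
of proportion and mean indicators (``full_follow_up == False``).

*Newly taken-in-care* cases are the prevalent subset aged 18-40 with
(i) no schizophrenia-spectrum diagnosis at any time before the index date,
(ii) no psychiatric-ward (GHPW) hospital admission in the lookback window, and
(iii) no two consecutive antipsychotic dispensings (gap < 90 days between the
end of one supply and the next dispensing) dated within the lookback window.
The lookback window defaults to 2 years for (ii) and (iii); (i) is lifetime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .episodes import GAP_DAYS, build_supply_episodes
from .model import CodeConfig, EventTables, age_years, to_day

__all__ = ["select_prevalent", "select_new", "DEFAULT_RECRUITMENT"]

FOLLOW_UP_DAYS = 365
DEFAULT_RECRUITMENT = ("2015-01-01", "2016-01-01")  # half-open calendar-year window

MEMBER_COLUMNS = [
    "patient_id", "region", "cohort", "index_date", "follow_up_end",
    "age_at_index", "sex", "person_years", "died", "full_follow_up",
]


def _qualifying_events(tables: EventTables, codes: CodeConfig) -> pd.DataFrame:
    """All diagnosis-qualifying DMH events (contacts + GHPW/CRF admissions)."""
    con = tables.contacts
    parts = []
    if len(con):
        m = codes.is_diagnosis(con["diagnosis_code"])
        if m.any():
            parts.append(pd.DataFrame({"patient_id": con.loc[m, "patient_id"].values,
                                       "day": to_day(con.loc[m, "date"])}))
    adm = tables.admissions
    if len(adm):
        m = codes.is_diagnosis(adm["diagnosis_code"]) & adm["ward"].isin(["GHPW", "CRF"]).values
        if m.any():
            parts.append(pd.DataFrame({"patient_id": adm.loc[m, "patient_id"].values,
                                       "day": to_day(adm.loc[m, "admission_date"])}))
    if not parts:
        return pd.DataFrame({"patient_id": pd.Series(dtype=object), "day": pd.Series(dtype=int)})
    return pd.concat(parts, ignore_index=True)


def select_prevalent(
    tables: EventTables,
    recruitment_window: tuple = DEFAULT_RECRUITMENT,
    code_config: CodeConfig | None = None,
    age_range: tuple[int, int] = (18, 65),
) -> pd.DataFrame:
    """Build the prevalent cohort; returns one row per member (MEMBER_COLUMNS)."""
    codes = code_config or CodeConfig()
    w0, w1 = to_day(pd.Series(list(recruitment_window)))
    if w1 <= w0:
        raise ValueError(f"empty recruitment window: {recruitment_window!r}")

    ev = _qualifying_events(tables, codes)
    ev = ev[(ev["day"] >= w0) & (ev["day"] < w1)]
    if not len(ev):
        return pd.DataFrame(columns=MEMBER_COLUMNS)
    idx = ev.groupby("patient_id")["day"].min().rename("index_day").reset_index()

    pat = tables.patients
    m = idx.merge(pat, on="patient_id", how="left")
    age = age_years(m["birth_date"], pd.Series(m["index_day"].values.astype("datetime64[D]")))
    lo, hi = age_range
    keep = (age >= lo) & (age <= hi)

    cov_end = to_day(m["coverage_end"])
    fu_end = m["index_day"].values + FOLLOW_UP_DAYS

    deaths = tables.deaths.set_index("patient_id")["death_date"] if len(tables.deaths) else pd.Series(dtype="datetime64[ns]")
    death_day = m["patient_id"].map(deaths)
    death_day = pd.Series(np.where(death_day.notna(), to_day(death_day.fillna(pd.Timestamp("1970-01-01"))), np.nan))
    died_in_fu = death_day.notna() & (death_day.values < fu_end) & (death_day.values >= m["index_day"].values)

    # full-year observability required, except death during follow-up
    observable = cov_end + 1 >= fu_end
    keep &= observable | died_in_fu.values

    m = m[keep].reset_index(drop=True)
    age = age[keep]
    fu_end = fu_end[keep]
    died = died_in_fu.values[keep]
    ddays = death_day.values[keep]

    py = np.where(died, (ddays - m["index_day"].values) / 365.0, 1.0)
    out = pd.DataFrame({
        "patient_id": m["patient_id"],
        "region": m["region"],
        "cohort": "prevalent",
        "index_date": pd.to_datetime(m["index_day"].values.astype("datetime64[D]")),
        "follow_up_end": pd.to_datetime(fu_end.astype("datetime64[D]")),
        "age_at_index": age,
        "sex": m["sex"],
        "person_years": py,
        "died": died,
        "full_follow_up": ~died,
    })
    return out.sort_values(["region", "patient_id"], kind="stable").reset_index(drop=True)


def select_new(
    prevalent: pd.DataFrame,
    tables: EventTables,
    lookback_years: int = 2,
    code_config: CodeConfig | None = None,
    age_range: tuple[int, int] = (18, 40),
    gap_days: int = GAP_DAYS,
) -> pd.DataFrame:
    """Restrict the prevalent cohort to newly taken-in-care cases (18-40)."""
    codes = code_config or CodeConfig()
    if not len(prevalent):
        return prevalent.copy()
    cand = prevalent[(prevalent["age_at_index"] >= age_range[0]) &
                     (prevalent["age_at_index"] <= age_range[1])].copy()
    if not len(cand):
        cand["cohort"] = pd.Series(dtype=object)
        return cand
    index_day = pd.Series(to_day(cand["index_date"]), index=cand["patient_id"].values)
    lookback = int(round(lookback_years * 365.25))

    excluded = set()

    # (i) any prior qualifying diagnosis, lifetime
    ev = _qualifying_events(tables, codes)
    ev = ev[ev["patient_id"].isin(index_day.index)]
    if len(ev):
        prior = ev["day"].values < index_day.loc[ev["patient_id"]].values
        excluded.update(ev.loc[prior, "patient_id"])

    # (ii) any GHPW admission within the lookback window
    adm = tables.admissions
    if len(adm):
        a = adm[(adm["ward"] == "GHPW") & adm["patient_id"].isin(index_day.index)]
        if len(a):
            d = to_day(a["admission_date"])
            idx = index_day.loc[a["patient_id"]].values
            hit = (d < idx) & (d >= idx - lookback)
            excluded.update(a.loc[hit, "patient_id"])

    # (iii) two consecutive antipsychotic dispensings within the lookback window
    disp = tables.dispensings
    if len(disp):
        is_ap = codes.is_antipsychotic(disp["atc_code"])
        d = disp[is_ap & disp["patient_id"].isin(index_day.index)].copy()
        if len(d):
            d["day"] = to_day(d["date"])
            idx = index_day.loc[d["patient_id"]].values
            d = d[(d["day"].values < idx) & (d["day"].values >= idx - lookback)]
            if len(d):
                for ep in build_supply_episodes(d, tables.ddd_reference, gap_days=gap_days):
                    if ep.n_dispensings >= 2:
                        excluded.add(ep.patient_id)

    out = cand[~cand["patient_id"].isin(excluded)].copy()
    out["cohort"] = "newly_taken_in_care"
    return out.reset_index(drop=True)
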