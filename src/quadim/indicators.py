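"""Per-region clinical indicators for the two cohorts.

The catalogue covers three quality domains — accessibility & appropriateness,
continuity, and safety — each indicator a proportion, a mean per person-year,
an admission-level statistic or an SMR. Computation is two-stage: a feature
pass derives one row per cohort member (counts, access flags, persistence,
polytherapy, monitoring) and one row per GHPW admission (length of stay,
readmission, post-discharge timeliness), then each indicator aggregates a
feature column within each (region, cohort) cell.

Denominator conventions:

* Proportion and mean indicators use members with a complete 365-day
  follow-up (decedents are excluded; they count only for the SMR).
* "Among users" means restrict to members with at least one event of that
  kind (e.g. mean psychotherapy sessions among patients with any
  psychotherapy); cohort-wide means (outpatient contacts, psychiatric visits)
  divide total events by total person-years.
* Admission-level indicators use GHPW admissions starting within follow-up
  as the statistical unit; stay lengths are counted in full (not clipped at
  the end of follow-up), and readmissions/post-discharge contacts may be
  observed past the follow-up end.
* An empty denominator yields an undefined (NaN) estimate, never zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import episodes as ep
from .model import (
    COMMUNITY_SETTINGS,
    CodeConfig,
    EventTables,
    age_band,
    to_day,
)

__all__ = [
    "Thresholds",
    "IndicatorDefinition",
    "default_catalogue",
    "build_member_features",
    "build_admission_features",
    "compute_indicators",
    "age_standardised_rate",
    "standardised_treatment_rate",
]

FOLLOW_UP_DAYS = 365


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Clinical rule thresholds (days), with the standard defaults."""

    gap_days: int = 90
    polytherapy_min_days: int = 30   # "more than 30 days" -> strictly greater
    readmission_short: int = 7
    readmission_long: int = 30
    post_discharge_days: int = 14
    long_stay_days: int = 30         # LoS "more than 30 days"


@dataclasses.dataclass(frozen=True)
class IndicatorDefinition:
    """One catalogue entry, resolvable to a feature column + statistic."""

    id: str
    label: str
    domain: str          # accessibility_appropriateness | continuity | safety
    statistic: str       # proportion | mean_per_py | mean_among_users |
    #                      admission_proportion | admission_mean | smr
    feature: str = ""    # column in the member/admission feature frame
    among: str = ""      # optional boolean column restricting the denominator
    unit: str = ""


def default_catalogue() -> list[IndicatorDefinition]:
    A, C, S = "accessibility_appropriateness", "continuity", "safety"
    d = IndicatorDefinition
    return [
        d("access_outpatient_dc", "≥1 outpatient or day-care intervention", A, "proportion", "has_outpatient"),
        d("mean_outpatient_contacts", "Outpatient/DC contacts per person-year", A, "mean_per_py", "n_outpatient", unit="contacts/py"),
        d("mean_psychiatric_visits", "Outpatient psychiatric visits per person-year", A, "mean_per_py", "n_psychiatric", unit="visits/py"),
        d("access_home_visit", "≥1 home visit", A, "proportion", "has_home_visit"),
        d("access_structured_assessment", "≥1 structured assessment", A, "proportion", "has_structured"),
        d("access_psychosocial", "≥1 psychosocial intervention", A, "proportion", "has_psychosocial"),
        d("mean_psychosocial_sessions", "Psychosocial sessions per person-year among users", A, "mean_among_users", "n_psychosocial", among="has_psychosocial", unit="sessions/py"),
        d("access_psychotherapy", "≥1 psychotherapy session", A, "proportion", "has_psychotherapy"),
        d("mean_psychotherapy_sessions", "Psychotherapy sessions per person-year among users", A, "mean_among_users", "n_psychotherapy", among="has_psychotherapy", unit="sessions/py"),
        d("access_psychoeducation", "≥1 psychoeducation session", A, "proportion", "has_psychoeducation"),
        d("mean_psychoeducation_sessions", "Psychoeducation sessions per person-year among users", A, "mean_among_users", "n_psychoeducation", among="has_psychoeducation", unit="sessions/py"),
        d("access_family_intervention", "≥1 intervention addressed to the family", A, "proportion", "has_family"),
        d("mean_family_interventions", "Family interventions per person-year among users", A, "mean_among_users", "n_family", among="has_family", unit="sessions/py"),
        d("access_antipsychotic", "≥1 antipsychotic dispensing", A, "proportion", "has_antipsychotic"),
        d("polytherapy_gt30d", "Antipsychotic polytherapy > 30 days (among treated)", A, "proportion", "polytherapy_gt", among="has_antipsychotic"),
        d("access_crf", "≥1 admission to a community residential facility", A, "proportion", "has_crf"),
        d("mean_crf_days", "Days in residential facility among admitted", A, "mean_among_users", "crf_days", among="has_crf", unit="days"),
        d("access_ghpw", "≥1 admission to a general-hospital psychiatric ward", A, "proportion", "has_ghpw"),
        d("mean_ghpw_los", "Mean GHPW length of stay (admission as unit)", A, "admission_mean", "los", unit="days"),
        d("ghpw_los_gt30d", "GHPW stays longer than 30 days", A, "admission_proportion", "long_stay"),
        d("readmission_7d", "Readmission within 7 days of GHPW discharge", A, "admission_proportion", "readm_short"),
        d("readmission_30d", "Readmission within 30 days of GHPW discharge", A, "admission_proportion", "readm_long"),
        d("persistent_community", "≥1 community contact every 90 days over the year", C, "proportion", "persistent_community", among="has_community_contact"),
        d("contact_14d_post_discharge", "CMHC contact within 14 days of GHPW discharge (any professional)", C, "admission_proportion", "contact14_any"),
        d("contact_14d_post_discharge_psychiatric", "Psychiatric visit within 14 days of GHPW discharge", C, "admission_proportion", "contact14_psy"),
        d("homecare_14d_post_discharge", "Home care within 14 days of GHPW discharge", C, "admission_proportion", "home14"),
        d("persistent_drug", "Uninterrupted antipsychotic therapy (among treated starters)", C, "proportion", "persistent_drug", among="has_antipsychotic"),
        d("full_metabolic_monitoring", "Blood glucose + lipid profile both tested (among treated)", S, "proportion", "full_lab", among="has_antipsychotic"),
        d("polytherapy_days_mean", "Days of antipsychotic polytherapy among treated", S, "mean_among_users", "polytherapy_days", among="has_antipsychotic", unit="days"),
        d("smr", "Standardised mortality ratio vs general population", S, "smr"),
    ]


# ---------------------------------------------------------------------------
# feature construction


def build_member_features(
    tables: EventTables,
    members: pd.DataFrame,
    code_config: CodeConfig | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """One row per cohort member with every patient-level feature."""
    codes = code_config or CodeConfig()
    f = members[["patient_id", "region", "cohort", "sex", "age_at_index",
                 "person_years", "died", "full_follow_up"]].copy().reset_index(drop=True)
    f["index_day"] = to_day(members["index_date"])
    pid_index = pd.Series(np.arange(len(f)), index=f["patient_id"].values)
    n = len(f)

    def zeros(dtype=int):
        return np.zeros(n, dtype=dtype)

    counts = {k: zeros() for k in (
        "n_outpatient", "n_psychiatric", "n_structured", "n_psychotherapy",
        "n_psychoeducation", "n_rehabilitation", "n_family", "n_home_visit")}

    # --- contacts in follow-up
    con = tables.contacts
    con = con[con["patient_id"].isin(pid_index.index)] if len(con) else con
    contact_rows = None
    if len(con):
        rows = pid_index.loc[con["patient_id"]].values
        rel = to_day(con["date"]) - f["index_day"].values[rows]
        in_fu = (rel >= 0) & (rel < FOLLOW_UP_DAYS)
        setting = con["setting"].values
        interv = con["intervention"].values
        community = np.isin(setting, COMMUNITY_SETTINGS)
        sel = in_fu & community
        np.add.at(counts["n_outpatient"], rows[sel], 1)
        for col, name in (
            ("n_psychiatric", "psychiatric_visit"),
            ("n_structured", "structured_assessment"),
            ("n_psychotherapy", "psychotherapy"),
            ("n_psychoeducation", "psychoeducation"),
            ("n_rehabilitation", "rehabilitation"),
            ("n_family", "family_intervention"),
        ):
            m = sel & (interv == name)
            np.add.at(counts[col], rows[m], 1)
        m = in_fu & (setting == "home_visit")
        np.add.at(counts["n_home_visit"], rows[m], 1)
        contact_rows = pd.DataFrame({"row": rows, "rel": rel, "community": community,
                                     "psy": interv == "psychiatric_visit",
                                     "home": setting == "home_visit"})

    for k, v in counts.items():
        f[k] = v
    f["n_psychosocial"] = f["n_psychotherapy"] + f["n_psychoeducation"] + f["n_rehabilitation"]
    for flag, src in (
        ("has_outpatient", "n_outpatient"), ("has_home_visit", "n_home_visit"),
        ("has_structured", "n_structured"), ("has_psychosocial", "n_psychosocial"),
        ("has_psychotherapy", "n_psychotherapy"), ("has_psychoeducation", "n_psychoeducation"),
        ("has_family", "n_family"),
    ):
        f[flag] = f[src] > 0

    # --- admissions
    adm = tables.admissions
    adm = adm[adm["patient_id"].isin(pid_index.index)] if len(adm) else adm
    has_ghpw, has_crf = zeros(bool), zeros(bool)
    crf_days = zeros()
    adm_rows = None
    if len(adm):
        rows = pid_index.loc[adm["patient_id"]].values
        a = to_day(adm["admission_date"]) - f["index_day"].values[rows]
        dsc = to_day(adm["discharge_date"]) - f["index_day"].values[rows]
        ward = adm["ward"].values
        in_fu = (a >= 0) & (a < FOLLOW_UP_DAYS)
        g = in_fu & (ward == "GHPW")
        has_ghpw[rows[g]] = True
        c = in_fu & (ward == "CRF")
        has_crf[rows[c]] = True
        np.add.at(crf_days, rows[c], np.maximum(dsc[c] - a[c], 0))
        adm_rows = pd.DataFrame({"row": rows, "adm": a, "dis": dsc, "ward": ward, "in_fu": in_fu})
    f["has_ghpw"], f["has_crf"], f["crf_days"] = has_ghpw, has_crf, crf_days

    # --- antipsychotic supply features
    disp = tables.dispensings
    has_ap = zeros(bool)
    persistent_drug = zeros(bool)
    poly_days = zeros()
    if len(disp):
        is_ap = codes.is_antipsychotic(disp["atc_code"])
        d = disp[is_ap & disp["patient_id"].isin(pid_index.index)].copy()
        if len(d):
            rows = pid_index.loc[d["patient_id"]].values
            d_rel = to_day(d["date"]) - f["index_day"].values[rows]
            in_fu = (d_rel >= 0) & (d_rel < FOLLOW_UP_DAYS)
            d = pd.DataFrame({"row": rows[in_fu], "day": d_rel[in_fu],
                              "atc": d["atc_code"].values[in_fu],
                              "amt": pd.to_numeric(d["total_amount"]).values[in_fu]})
            ddd_map = tables.ddd_reference.set_index("atc_code")["ddd"].to_dict()
            fu = (0, FOLLOW_UP_DAYS)
            for row, grp in d.groupby("row"):
                has_ap[row] = True
                segs_by_atc = {}
                for atc, g in grp.groupby("atc"):
                    segs_by_atc[atc] = ep.supply_segments(
                        g["day"].to_numpy(), g["amt"].to_numpy(), float(ddd_map[atc]))
                all_segs = [s for segs in segs_by_atc.values() for s in segs]
                persistent_drug[row] = ep.is_persistent_drug(all_segs, fu, thresholds.gap_days)
                poly_days[row] = ep.polytherapy_days(segs_by_atc, fu)
    f["has_antipsychotic"] = has_ap
    f["persistent_drug"] = persistent_drug
    f["polytherapy_days"] = poly_days
    f["polytherapy_gt"] = poly_days > thresholds.polytherapy_min_days

    # --- labs (metabolic monitoring) in follow-up
    labs = tables.labs
    glu, lip = zeros(bool), zeros(bool)
    if len(labs):
        l = labs[labs["patient_id"].isin(pid_index.index)]
        if len(l):
            rows = pid_index.loc[l["patient_id"]].values
            rel = to_day(l["date"]) - f["index_day"].values[rows]
            in_fu = (rel >= 0) & (rel < FOLLOW_UP_DAYS)
            panel = l["panel"].values
            glu[rows[in_fu & (panel == "blood_glucose")]] = True
            lip[rows[in_fu & (panel == "lipid_profile")]] = True
    f["full_lab"] = glu & lip

    # --- community persistence (contacts as points + inpatient days as coverage)
    persistent_comm = zeros(bool)
    cdays_by_row: dict = {}
    if contact_rows is not None and len(contact_rows):
        # the 365-day persistence window opens at the first community contact,
        # which may extend past follow-up end; window clipping happens in the rule
        cc = contact_rows[contact_rows["community"] & (contact_rows["rel"] >= 0)]
        cdays_by_row = {r: g["rel"].to_numpy() for r, g in cc.groupby("row")}
    stays_by_row: dict = {}
    if adm_rows is not None and len(adm_rows):
        st = adm_rows[adm_rows["ward"].isin(["GHPW", "CRF"]) & (adm_rows["dis"] > 0)]
        stays_by_row = {r: list(zip(g["adm"].tolist(), (g["dis"] + 1).tolist()))
                        for r, g in st.groupby("row")}
    for row, days in cdays_by_row.items():
        cov = [(int(x), int(x) + 1) for x in days]
        cov.extend(stays_by_row.get(row, []))
        start = int(days.min())
        persistent_comm[row] = ep.is_persistent_community(
            cov, start, FOLLOW_UP_DAYS, thresholds.gap_days)
    f["has_community_contact"] = np.array([r in cdays_by_row for r in range(n)])
    f["persistent_community"] = persistent_comm
    return f


def build_admission_features(
    tables: EventTables,
    members: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """One row per GHPW admission starting within a member's follow-up."""
    cols = ["patient_id", "region", "cohort", "los", "long_stay", "readm_short",
            "readm_long", "contact14_any", "contact14_psy", "home14"]
    adm = tables.admissions
    if not len(adm) or not len(members):
        return pd.DataFrame(columns=cols)
    mem = members[members["full_follow_up"]]
    idx = pd.Series(to_day(mem["index_date"]), index=mem["patient_id"].values)
    meta = mem.set_index("patient_id")[["region", "cohort"]]

    g = adm[(adm["ward"] == "GHPW") & adm["patient_id"].isin(idx.index)].copy()
    if not len(g):
        return pd.DataFrame(columns=cols)
    g["adm_day"] = to_day(g["admission_date"])
    g["dis_day"] = to_day(g["discharge_date"])

    con = tables.contacts
    con = con[con["patient_id"].isin(idx.index)] if len(con) else con
    cmap_any: dict = {}
    cmap_psy: dict = {}
    cmap_home: dict = {}
    if len(con):
        cd = pd.DataFrame({"pid": con["patient_id"].values, "day": to_day(con["date"]),
                           "setting": con["setting"].values, "interv": con["intervention"].values})
        comm = cd[cd["setting"].isin(COMMUNITY_SETTINGS)]
        cmap_any = {p: gg["day"].to_numpy() for p, gg in comm.groupby("pid")}
        psy = comm[comm["interv"] == "psychiatric_visit"]
        cmap_psy = {p: gg["day"].to_numpy() for p, gg in psy.groupby("pid")}
        home = cd[cd["setting"] == "home_visit"]
        cmap_home = {p: gg["day"].to_numpy() for p, gg in home.groupby("pid")}

    out = []
    k = thresholds.post_discharge_days
    empty = np.array([], dtype=int)
    for pid, grp in g.groupby("patient_id"):
        index_day = int(idx.loc[pid])
        in_fu = (grp["adm_day"].values >= index_day) & (grp["adm_day"].values < index_day + FOLLOW_UP_DAYS)
        if not in_fu.any():
            continue
        readm_s = ep.readmission_within(grp["adm_day"].values, grp["dis_day"].values, thresholds.readmission_short)
        readm_l = ep.readmission_within(grp["adm_day"].values, grp["dis_day"].values, thresholds.readmission_long)
        dis = grp["dis_day"].values
        c_any = ep.contact_within_after_discharge(cmap_any.get(pid, empty), dis, k)
        c_psy = ep.contact_within_after_discharge(cmap_psy.get(pid, empty), dis, k)
        c_home = ep.contact_within_after_discharge(cmap_home.get(pid, empty), dis, k)
        los = dis - grp["adm_day"].values
        region, cohort = meta.loc[pid, "region"], meta.loc[pid, "cohort"]
        for i in np.flatnonzero(in_fu):
            out.append((pid, region, cohort, int(los[i]), los[i] > thresholds.long_stay_days,
                        bool(readm_s[i]), bool(readm_l[i]), bool(c_any[i]), bool(c_psy[i]),
                        bool(c_home[i])))
    return pd.DataFrame(out, columns=cols)


# ---------------------------------------------------------------------------
# aggregation


def _proportion(mask: np.ndarray) -> tuple[float, float, int, int]:
    n = int(mask.size)
    if n == 0:
        return np.nan, np.nan, 0, 0
    x = int(mask.sum())
    p = x / n
    return p, float(np.sqrt(p * (1 - p) / n)), x, n


def _mean(values: np.ndarray, py: np.ndarray) -> tuple[float, float, float, float]:
    n = values.size
    if n == 0 or py.sum() == 0:
        return np.nan, np.nan, 0.0, float(py.sum())
    est = float(values.sum() / py.sum())
    rates = values / py
    se = float(np.std(rates, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return est, se, float(values.sum()), float(py.sum())


def _smr_estimate(group: pd.DataFrame, population_rates: pd.DataFrame):
    from .pooling import expected_deaths

    observed = int(group["died"].sum())
    expected = expected_deaths(group, population_rates)
    if expected <= 0:
        return np.nan, np.nan, observed, expected
    return observed / expected, float(np.sqrt(max(observed, 1)) / expected), observed, expected


def compute_indicators(
    tables: EventTables,
    members: pd.DataFrame,
    catalogue: list[IndicatorDefinition] | None = None,
    code_config: CodeConfig | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Estimate every catalogue indicator per (region, cohort).

    Returns a frame with columns region, cohort, indicator_id, domain,
    statistic, numerator, denominator, estimate, se.
    """
    catalogue = catalogue if catalogue is not None else default_catalogue()
    if not len(members):
        return pd.DataFrame(columns=["region", "cohort", "indicator_id", "domain",
                                     "statistic", "numerator", "denominator", "estimate", "se"])
    # members may hold the same patient in both cohorts; features are built
    # per cohort so patient ids stay unique within a pass
    feat_parts, adm_parts = [], []
    for _, mem_c in members.groupby("cohort"):
        feat_parts.append(build_member_features(tables, mem_c, code_config, thresholds))
        adm_parts.append(build_admission_features(tables, mem_c, thresholds))
    feats = pd.concat(feat_parts, ignore_index=True)
    adm_feats = pd.concat(adm_parts, ignore_index=True)

    rows = []
    for (region, cohort), grp in feats.groupby(["region", "cohort"], sort=True):
        full = grp[grp["full_follow_up"]]
        agrp = adm_feats[(adm_feats["region"] == region) & (adm_feats["cohort"] == cohort)] \
            if len(adm_feats) else adm_feats
        for d in catalogue:
            num = den = est = se = np.nan
            if d.statistic == "proportion":
                base = full[full[d.among]] if d.among else full
                est, se, num, den = _proportion(base[d.feature].to_numpy())
            elif d.statistic == "mean_per_py":
                est, se, num, den = _mean(full[d.feature].to_numpy(dtype=float),
                                          full["person_years"].to_numpy(dtype=float))
            elif d.statistic == "mean_among_users":
                base = full[full[d.among]] if d.among else full[full[d.feature] > 0]
                est, se, num, den = _mean(base[d.feature].to_numpy(dtype=float),
                                          base["person_years"].to_numpy(dtype=float))
            elif d.statistic == "admission_proportion":
                est, se, num, den = _proportion(agrp[d.feature].to_numpy(dtype=bool)) \
                    if len(agrp) else (np.nan, np.nan, 0, 0)
            elif d.statistic == "admission_mean":
                vals = agrp[d.feature].to_numpy(dtype=float) if len(agrp) else np.array([])
                est, se, num, den = _mean(vals, np.ones(vals.size))
            elif d.statistic == "smr":
                est, se, num, den = _smr_estimate(grp, tables.population_rates)
            else:
                raise ValueError(f"unknown statistic {d.statistic!r} for indicator {d.id}")
            rows.append((region, cohort, d.id, d.domain, d.statistic, num, den, est, se))
    return pd.DataFrame(rows, columns=["region", "cohort", "indicator_id", "domain",
                                       "statistic", "numerator", "denominator", "estimate", "se"])


# ---------------------------------------------------------------------------
# direct age standardisation


def age_standardised_rate(cases_by_band, population_by_band, standard_weights, per: float = 10_000.0) -> float:
    """Directly age-standardised rate: sum of weights x band rates, scaled.

    All three inputs are Series indexed by age-band label; the standard
    weights are renormalised over the bands present in the population.
    Raises ValueError on band mismatch between cases and population.
    """
    cases = pd.Series(cases_by_band, dtype=float)
    popn = pd.Series(population_by_band, dtype=float)
    w = pd.Series(standard_weights, dtype=float)
    extra = set(cases.index) - set(popn.index)
    if extra:
        raise ValueError(f"case bands missing from population: {sorted(extra)}")
    missing_w = set(popn.index) - set(w.index)
    if missing_w:
        raise ValueError(f"population bands missing from standard weights: {sorted(missing_w)}")
    cases = cases.reindex(popn.index, fill_value=0.0)
    w = w.reindex(popn.index).astype(float)
    w = w / w.sum()
    rates = cases / popn
    return float((w * rates).sum() * per)


def standardised_treatment_rate(
    members: pd.DataFrame,
    patients: pd.DataFrame,
    standard_population: pd.DataFrame,
    age_range: tuple[int, int] = (18, 65),
    reference_date: str = "2015-07-02",
) -> float:
    """Age-standardised treated rate per 10,000 inhabitants in ``age_range``.

    Numerator bands come from the members' age at index; denominator bands
    from the registry's age at ``reference_date`` (mid-recruitment).
    """
    pop_age = np.asarray(
        pd.Series(to_day(patients["birth_date"])).rsub(int(to_day(pd.Series([reference_date]))[0]))
    ) / 365.2425
    pop_age = np.floor(pop_age).astype(int)
    in_range = (pop_age >= age_range[0]) & (pop_age <= age_range[1])
    pop_by_band = pd.Series(age_band(pop_age[in_range])).value_counts()
    mem = members[(members["age_at_index"] >= age_range[0]) & (members["age_at_index"] <= age_range[1])]
    cases_by_band = pd.Series(age_band(mem["age_at_index"].to_numpy())).value_counts()
    weights = standard_population.set_index("age_band")["weight"]
    weights = weights[weights.index.isin(pop_by_band.index)]
    return age_standardised_rate(cases_by_band, pop_by_band, weights)
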