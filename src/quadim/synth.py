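"""Synthetic multi-region HCU data with planted indicator values.

The generator emulates the event streams behind the indicator pipeline —
registry, community contacts, hospital/residential admissions, antipsychotic
dispensings, metabolic lab tests and deaths — such that, for every planted
parameter, the corresponding indicator computed by the full pipeline is an
unbiased estimate of the planted value. The pipeline is then verifiable by
parameter recovery: run it on a simulated dataset and compare estimates to
:func:`planted_truth` within Monte-Carlo error.

Planting is constructive rather than by rejection: persistence and timeliness
flags are drawn first and the event stream is built to satisfy them (refill
chains with gaps below/above the 90-day rule; community contacts scattered
uniformly, then repositioned — never added or removed — to close or open
90-day coverage gaps, so planted contact counts stay exact). Where a patient's
admissions make the drawn community-persistence flag infeasible (a long stay
leaves no 90-day window free), flags are swapped with an admission-free
patient so the planted count is preserved exactly.

Default parameter values are the overall estimates the indicator system is
designed to reproduce for the prevalent cohort (e.g. 27.7 outpatient contacts
per person-year, mean GHPW stay of 31 days, 70% excess mortality).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import yaml

from .episodes import merge_intervals, uncovered_runs
from .model import (
    EventTables,
    age_band,
    default_ddd_reference,
    default_population_rates,
    default_standard_population,
    from_day,
    to_day,
)

__all__ = ["RegionParams", "SimulationParams", "simulate", "planted_truth"]

FOLLOW_UP = 365
GAP = 90
POST_DISCHARGE = 14

_DIAG_CODES = ("F20", "F22", "F25.1", "295.30", "297.1", "298.9")


@dataclasses.dataclass
class RegionParams:
    """Planted per-region parameter set (defaults: overall prevalent-cohort values)."""

    name: str = "region"
    n_inhabitants: int = 50_000
    prevalence_per_10k: float = 39.2      # treated prevalence, ages 18-65
    incidence_per_10k: float = 3.1        # newly taken-in-care, ages 18-40
    mean_outpatient_contacts_py: float = 27.7
    mean_psychiatric_visits_py: float = 4.9
    p_home_visit: float = 0.20
    p_structured_assessment: float = 0.024
    p_psychosocial: float = 0.54
    mean_psychosocial_py: float = 14.7    # sessions per year among users
    p_psychotherapy: float = 0.10
    mean_psychotherapy_py: float = 8.4
    p_psychoeducation: float = 0.10
    mean_psychoeducation_py: float = 5.0
    p_family_intervention: float = 0.36
    mean_family_py: float = 1.5
    p_antipsychotic: float = 0.80
    p_polytherapy_gt30d: float = 0.40     # among antipsychotic-treated
    p_persistent_drug: float = 0.50       # among antipsychotic-treated
    p_persistent_community: float = 0.66
    p_CRF: float = 0.17
    mean_CRF_days: float = 171.0
    p_GHPW: float = 0.10
    mean_LoS_days: float = 31.0
    p_readm_7d: float = 0.10              # per GHPW discharge
    p_readm_30d: float = 0.20
    p_contact_14d_post_discharge: float = 0.60
    p_homecare_14d_post_discharge: float = 0.05
    p_full_lab_monitoring: float = 0.30   # among antipsychotic-treated
    smr_multiplier: float = 1.70

    def validate(self, age_range: tuple[int, int]) -> None:
        probs = {k: v for k, v in dataclasses.asdict(self).items() if k.startswith("p_")}
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {k}={v} outside [0, 1]")
        for k in ("mean_outpatient_contacts_py", "mean_psychiatric_visits_py",
                  "mean_CRF_days", "mean_LoS_days"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{self.name}: {k} must be > 0")
        for k in ("mean_psychosocial_py", "mean_psychotherapy_py",
                  "mean_psychoeducation_py", "mean_family_py"):
            if getattr(self, k) < 1.0:
                raise ValueError(f"{self.name}: {k} must be >= 1 (session means are "
                                 "conditional on at least one session)")
        if self.n_inhabitants < 1000:
            raise ValueError(f"{self.name}: n_inhabitants must be >= 1000")
        if self.p_readm_7d > self.p_readm_30d:
            raise ValueError(f"{self.name}: p_readm_7d > p_readm_30d is impossible "
                             "(7-day readmissions are a subset of 30-day ones)")
        if self.incidence_per_10k > self.prevalence_per_10k:
            raise ValueError(f"{self.name}: incidence cannot exceed prevalence")
        if self.mean_psychiatric_visits_py < 1.0:
            raise ValueError(f"{self.name}: mean_psychiatric_visits_py must be >= 1 "
                             "(the index visit is a psychiatric visit)")
        if self.p_psychosocial > 0:
            if self.p_psychotherapy > self.p_psychosocial or self.p_psychoeducation > self.p_psychosocial:
                raise ValueError(f"{self.name}: psychotherapy/psychoeducation access cannot "
                                 "exceed overall psychosocial access")
            if self._rehab_mean() < 0:
                raise ValueError(f"{self.name}: mean_psychosocial_py too small for the "
                                 "planted psychotherapy/psychoeducation intensities")
        if self._other_contacts_mean() < 0:
            raise ValueError(f"{self.name}: mean_outpatient_contacts_py too small for the "
                             "planted component intensities")
        if self.p_homecare_14d_post_discharge > max(self.p_home_visit, 1e-12) and self.p_GHPW > 0:
            raise ValueError(f"{self.name}: p_homecare_14d_post_discharge cannot exceed p_home_visit")

    def _rehab_mean(self) -> float:
        if self.p_psychosocial == 0:
            return 0.0
        cond_t = self.p_psychotherapy / self.p_psychosocial
        cond_e = self.p_psychoeducation / self.p_psychosocial
        return (self.mean_psychosocial_py - 1.0
                - cond_t * self.mean_psychotherapy_py
                - cond_e * self.mean_psychoeducation_py)

    def _other_contacts_mean(self) -> float:
        return (self.mean_outpatient_contacts_py
                - self.mean_psychiatric_visits_py
                - self.p_psychosocial * self.mean_psychosocial_py
                - self.p_family_intervention * self.mean_family_py
                - self.p_structured_assessment)


@dataclasses.dataclass
class SimulationParams:
    """Global simulation settings: seed, regions, recruitment window, age range."""

    seed: int = 0
    regions: list[RegionParams] = dataclasses.field(default_factory=lambda: [RegionParams()])
    recruitment_start: str = "2015-01-01"
    age_range: tuple[int, int] = (18, 65)
    coverage_start: str = "2008-01-01"
    coverage_end: str = "2019-12-31"

    def validate(self) -> None:
        if not self.regions:
            raise ValueError("at least one region required")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        lo, hi = self.age_range
        if not (18 <= lo <= hi <= 65):
            raise ValueError("age_range must lie within [18, 65]")
        for r in self.regions:
            r.validate(self.age_range)

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        regions = [RegionParams(**r) for r in raw.pop("regions", [])]
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        p = cls(regions=regions or [RegionParams()], **raw)
        p.validate()
        return p


TRUTH_MAP = [
    ("prevalence_rate", "prevalence_per_10k"),
    ("incidence_rate", "incidence_per_10k"),
    ("mean_outpatient_contacts", "mean_outpatient_contacts_py"),
    ("mean_psychiatric_visits", "mean_psychiatric_visits_py"),
    ("access_home_visit", "p_home_visit"),
    ("access_structured_assessment", "p_structured_assessment"),
    ("access_psychosocial", "p_psychosocial"),
    ("mean_psychosocial_sessions", "mean_psychosocial_py"),
    ("access_psychotherapy", "p_psychotherapy"),
    ("mean_psychotherapy_sessions", "mean_psychotherapy_py"),
    ("access_psychoeducation", "p_psychoeducation"),
    ("mean_psychoeducation_sessions", "mean_psychoeducation_py"),
    ("access_family_intervention", "p_family_intervention"),
    ("mean_family_interventions", "mean_family_py"),
    ("access_antipsychotic", "p_antipsychotic"),
    ("polytherapy_gt30d", "p_polytherapy_gt30d"),
    ("persistent_drug", "p_persistent_drug"),
    ("persistent_community", "p_persistent_community"),
    ("access_crf", "p_CRF"),
    ("mean_crf_days", "mean_CRF_days"),
    ("access_ghpw", "p_GHPW"),
    ("mean_ghpw_los", "mean_LoS_days"),
    ("readmission_7d", "p_readm_7d"),
    ("readmission_30d", "p_readm_30d"),
    ("contact_14d_post_discharge", "p_contact_14d_post_discharge"),
    ("homecare_14d_post_discharge", "p_homecare_14d_post_discharge"),
    ("full_metabolic_monitoring", "p_full_lab_monitoring"),
    ("smr", "smr_multiplier"),
]


def planted_truth(params: SimulationParams) -> pd.DataFrame:
    """One row per (region, indicator_id) with the planted true value."""
    params.validate()
    rows = []
    for r in params.regions:
        for ind, attr in TRUTH_MAP:
            rows.append((r.name, ind, float(getattr(r, attr))))
    return pd.DataFrame(rows, columns=["region", "indicator_id", "true_value"])


# ---------------------------------------------------------------------------
# helpers


def _in_windows(day: int, windows: list[tuple[int, int]]) -> bool:
    return any(a <= day < b for a, b in windows)


def _draw_day(rng, forbidden: list[tuple[int, int]], lo: int = 0, hi: int = FOLLOW_UP) -> int:
    for _ in range(60):
        d = int(rng.integers(lo, hi))
        if not _in_windows(d, forbidden):
            return d
    for d in range(lo, hi):  # deterministic fallback for pathological configs
        if not _in_windows(d, forbidden):
            return d
    return int(rng.integers(lo, hi))


def _feasible_gap_start(cov: list[tuple[int, int]], rng) -> int | None:
    """A start day a in [1, 275] with [a, a+90) disjoint from ``cov``, or None."""
    choices: list[tuple[int, int]] = []
    for r0, r1 in uncovered_runs(cov, (1, FOLLOW_UP)):
        hi = min(r1, FOLLOW_UP) - GAP
        if hi >= r0:
            choices.append((r0, hi))
    if not choices:
        return None
    total = sum(hi - lo + 1 for lo, hi in choices)
    t = int(rng.integers(0, total))
    for lo, hi in choices:
        span = hi - lo + 1
        if t < span:
            return lo + t
        t -= span
    return choices[-1][1]


# ---------------------------------------------------------------------------
# per-region generation


def _simulate_region(rp: RegionParams, params: SimulationParams, rng: np.random.Generator):
    lo_age, hi_age = params.age_range
    n = rp.n_inhabitants
    win_start = int(to_day(pd.Series([params.recruitment_start]))[0])
    ref_day = win_start + 182

    sex = np.where(rng.random(n) < 0.5, "M", "F")
    age = rng.integers(lo_age, hi_age + 1, size=n)
    p_prev = rp.prevalence_per_10k / 1e4
    p_inc = rp.incidence_per_10k / 1e4
    case = rng.random(n) < p_prev
    young = (age >= 18) & (age <= 40)
    new = case & young & (rng.random(n) < (p_inc / p_prev if p_prev > 0 else 0.0))

    case_idx = np.flatnonzero(case)
    nc = len(case_idx)
    index_day = np.zeros(n, dtype=np.int64)
    index_day[case_idx] = win_start + rng.integers(0, 365, size=nc)

    anchor = np.where(case, index_day, ref_day)
    f_jitter = rng.integers(10, 351, size=n)
    birth_day = anchor - np.round(age * 365.2425).astype(np.int64) - f_jitter

    pid = np.array([f"{rp.name}-{i:07d}" for i in range(n)], dtype=object)

    # ---- vectorised per-case flags and counts
    rates = default_population_rates(lo_age, hi_age)
    rate_map = {(s, b): r for s, b, r in rates.itertuples(index=False)}
    c_sex = sex[case_idx]
    c_age = age[case_idx]
    c_band = age_band(c_age)
    base_rate = np.array([rate_map[(s, b)] for s, b in zip(c_sex, c_band)])
    death = rng.random(nc) < np.minimum(base_rate * rp.smr_multiplier, 1.0)
    death_rel = rng.integers(1, 365, size=nc)

    def bern(p):
        return rng.random(nc) < p

    def pois1(mean, mask):
        """1 + Poisson(mean - 1) where mask, else 0 (exact conditional mean)."""
        out = np.zeros(nc, dtype=np.int64)
        if mask.any():
            out[mask] = 1 + rng.poisson(max(mean - 1.0, 0.0), size=int(mask.sum()))
        return out

    n_psy = 1 + rng.poisson(rp.mean_psychiatric_visits_py - 1.0, size=nc)  # incl. index visit
    n_other = rng.poisson(max(rp._other_contacts_mean(), 0.0), size=nc)
    psychosocial = bern(rp.p_psychosocial)
    cond = rp.p_psychosocial if rp.p_psychosocial > 0 else 1.0
    ptherapy = psychosocial & bern(rp.p_psychotherapy / cond)
    peduc = psychosocial & bern(rp.p_psychoeducation / cond)
    n_pt = pois1(rp.mean_psychotherapy_py, ptherapy)
    n_pe = pois1(rp.mean_psychoeducation_py, peduc)
    rehab_mean = max(rp._rehab_mean(), 0.0)
    n_re = np.zeros(nc, dtype=np.int64)
    if psychosocial.any():
        n_re[psychosocial] = 1 + rng.poisson(rehab_mean, size=int(psychosocial.sum()))
    structured = bern(rp.p_structured_assessment)
    family = bern(rp.p_family_intervention)
    n_fam = pois1(rp.mean_family_py, family)
    home = bern(rp.p_home_visit)
    n_home = np.zeros(nc, dtype=np.int64)
    if home.any():
        n_home[home] = 1 + rng.poisson(0.5, size=int(home.sum()))

    ghpw = bern(rp.p_GHPW)
    crf = bern(rp.p_CRF)
    antipsy = bern(rp.p_antipsychotic)
    pers_drug = antipsy & bern(rp.p_persistent_drug)
    poly = antipsy & bern(rp.p_polytherapy_gt30d)
    lab_full = antipsy & bern(rp.p_full_lab_monitoring)
    lab_partial = bern(0.5)
    pers_comm = bern(rp.p_persistent_community)

    ddd = default_ddd_reference()
    ap_codes = [c for c in ddd["atc_code"] if c != "N05AN01"]
    ddd_map = ddd.set_index("atc_code")["ddd"].to_dict()

    # ---- phase 1: admissions, per-discharge flags, persistence feasibility
    p7, p30 = rp.p_readm_7d, rp.p_readm_30d
    p_home_cond = (rp.p_homecare_14d_post_discharge / rp.p_home_visit
                   if rp.p_home_visit > 0 else 0.0)
    admissions_by_case: list[list[tuple[int, int, str]]] = []
    c14_by_case: list[list[bool]] = []
    h14_by_case: list[list[bool]] = []
    gap_start = np.full(nc, -1, dtype=np.int64)
    infeasible: list[int] = []
    swap_pool: list[int] = []

    for j in range(nc):
        adms: list[tuple[int, int, str]] = []
        c14: list[bool] = []
        h14: list[bool] = []
        if ghpw[j]:
            start = int(rng.integers(0, 365))
            for _ in range(8):
                los = int(rng.geometric(1.0 / rp.mean_LoS_days))
                end = start + los
                adms.append((start, end, "GHPW"))
                c14.append(bool(rng.random() < rp.p_contact_14d_post_discharge))
                h14.append(bool(home[j]) and bool(rng.random() < p_home_cond))
                u = rng.random()
                if u < p7:
                    start = end + int(rng.integers(1, 8))
                elif u < p30:
                    start = end + int(rng.integers(8, 31))
                else:
                    break
        if crf[j]:
            s = int(rng.integers(0, 365))
            adms.append((s, s + int(rng.geometric(1.0 / rp.mean_CRF_days)), "CRF"))
        admissions_by_case.append(adms)
        c14_by_case.append(c14)
        h14_by_case.append(h14)
        if not pers_comm[j]:
            cov = [(a, e + 1) for a, e, _ in adms]
            ghpw_ends = [e for a, e, w in adms if w == "GHPW"]
            cov += [(e + 1, e + 1 + POST_DISCHARGE) for e, flag in zip(ghpw_ends, c14) if flag]
            g = _feasible_gap_start(cov, rng)
            if g is None:
                infeasible.append(j)
            else:
                gap_start[j] = g
        elif not adms:
            swap_pool.append(j)

    # swap infeasible non-persistent flags with admission-free persistent patients
    for j in infeasible:
        if not swap_pool:
            break  # give up: patient stays (forced) persistent
        k = swap_pool.pop(int(rng.integers(0, len(swap_pool))))
        pers_comm[j] = True
        pers_comm[k] = False
        gap_start[k] = _feasible_gap_start([], rng)

    # ---- phase 2: event assembly
    contacts: list[tuple] = []
    admissions: list[tuple] = []
    dispensings: list[tuple] = []
    labs: list[tuple] = []
    deaths: list[tuple] = []
    patients_cov_end = np.full(n, int(to_day(pd.Series([params.coverage_end]))[0]), dtype=np.int64)
    cov_start_day = int(to_day(pd.Series([params.coverage_start]))[0])

    for j in range(nc):
        i = case_idx[j]
        p = pid[i]
        idx = int(index_day[i])
        adms = admissions_by_case[j]
        ghpw_disch = [e for a, e, w in adms if w == "GHPW"]

        blocked: list[tuple[int, int]] = []     # no CMHC/DC contact may fall here
        required: list[tuple[int, int]] = []    # >=1 CMHC contact needed here
        h_blocked: list[tuple[int, int]] = []
        h_required: list[tuple[int, int]] = []
        for d_end, cflag, hflag in zip(ghpw_disch, c14_by_case[j], h14_by_case[j]):
            w = (d_end + 1, d_end + 1 + POST_DISCHARGE)
            (required if cflag else blocked).append(w)
            (h_required if hflag else h_blocked).append(w)

        forbid = list(blocked)
        gap_win: list[tuple[int, int]] = []
        if not pers_comm[j] and gap_start[j] >= 0:
            gap_win = [(int(gap_start[j]), int(gap_start[j]) + GAP)]
            forbid = forbid + gap_win

        # contact pool: (relative day, setting, intervention); index visit pinned at day 0
        pool: list[list] = [[0, "CMHC_outpatient", "psychiatric_visit", True]]

        def add(cnt, setting, interv):
            cnt = int(cnt)
            if cnt <= 0:
                return
            if forbid:
                for _ in range(cnt):
                    pool.append([_draw_day(rng, forbid), setting, interv, False])
            else:
                for d in rng.integers(0, FOLLOW_UP, size=cnt).tolist():
                    pool.append([int(d), setting, interv, False])
        add(n_psy[j] - 1, "CMHC_outpatient", "psychiatric_visit")
        add(n_other[j], "CMHC_outpatient", "other_professional_contact")
        add(n_pt[j], "CMHC_outpatient", "psychotherapy")
        add(n_pe[j], "CMHC_outpatient", "psychoeducation")
        add(n_re[j], "day_care", "rehabilitation")
        add(n_fam[j], "CMHC_outpatient", "family_intervention")
        if structured[j]:
            add(1, "CMHC_outpatient", "structured_assessment")

        movable = [c for c in pool if not c[3]]
        # satisfy required post-discharge contact windows: reposition a pooled
        # contact when the window lies inside follow-up (keeps planted counts
        # exact), append an extra one when it lies beyond day 365 (invisible
        # to every in-window indicator)
        for w0, w1 in required:
            if any(w0 <= c[0] < w1 for c in pool):
                continue
            target = None
            for d in rng.permutation(np.arange(w0, w1)).tolist():
                if not _in_windows(int(d), forbid):
                    target = int(d)
                    break
            if target is None:
                target = int(rng.integers(w0, w1))
            if target < FOLLOW_UP and movable:
                c = movable.pop(int(rng.integers(0, len(movable))))
                c[0], c[3] = target, True
            else:
                pool.append([target, "CMHC_outpatient", "psychiatric_visit", True])

        adm_cov = [(a, e + 1) for a, e, _ in adms]
        if pers_comm[j]:
            # close any >=90-day coverage gap by repositioning spare contacts
            for _ in range(12):
                cov = adm_cov + [(c[0], c[0] + 1) for c in pool]
                bad = [r for r in uncovered_runs(cov, (0, FOLLOW_UP)) if r[1] - r[0] >= GAP]
                if not bad:
                    break
                r0, r1 = bad[0]
                target = None
                for d in range(r0 + (r1 - r0) // 2, r1):
                    if not _in_windows(d, blocked):
                        target = d
                        break
                if target is None:
                    target = r0 + (r1 - r0) // 2
                if movable:
                    c = movable.pop(int(rng.integers(0, len(movable))))
                    c[0], c[3] = target, True
                else:
                    pool.append([target, "CMHC_outpatient", "other_professional_contact", True])

        # home visits (do not count as community coverage)
        home_days: list[int] = []
        for w0, w1 in h_required:
            d = None
            for cand in rng.permutation(np.arange(w0, w1)).tolist():
                if not _in_windows(int(cand), h_blocked):
                    d = int(cand)
                    break
            home_days.append(d if d is not None else int(rng.integers(w0, w1)))
        extra_home = int(n_home[j]) - len(home_days)
        for _ in range(max(extra_home, 0)):
            home_days.append(_draw_day(rng, h_blocked))

        # dispensings and labs (kept in per-patient lists so death truncation is local)
        p_disp: list[tuple] = []
        p_labs: list[tuple] = []
        if antipsy[j]:
            atc = ap_codes[int(rng.integers(0, len(ap_codes)))]
            unit = float(ddd_map[atc])
            fills: list[tuple[int, int]] = []  # (dispensing day, days of supply)
            if pers_drug[j]:
                day = int(rng.integers(0, 21))
                covered_to = day
                while covered_to < 300:  # refill chain, gaps < 90, through the year
                    dur = int(rng.integers(25, 36))
                    fills.append((day, dur))
                    covered_to = day + dur
                    day = covered_to + int(rng.integers(0, 46))
            else:
                d0 = int(rng.integers(0, 151))
                fills = [(d0, int(rng.integers(40, 91)))]  # ends <= day 240 -> interrupted
            for d, dur in fills:
                p_disp.append((p, idx + d, atc, dur * unit))
            if poly[j]:
                atc2 = atc
                while atc2 == atc:
                    atc2 = ap_codes[int(rng.integers(0, len(ap_codes)))]
                dur2 = 120 if pers_drug[j] else fills[0][1]
                p_disp.append((p, idx + fills[0][0], atc2, dur2 * float(ddd_map[atc2])))

            if lab_full[j]:
                p_labs.append((p, idx + int(rng.integers(0, FOLLOW_UP)), "blood_glucose"))
                p_labs.append((p, idx + int(rng.integers(0, FOLLOW_UP)), "lipid_profile"))
            elif lab_partial[j]:
                panel = "blood_glucose" if rng.random() < 0.5 else "lipid_profile"
                p_labs.append((p, idx + int(rng.integers(0, FOLLOW_UP)), panel))

        # prior history for non-new young cases (lifetime diagnosis exclusion)
        if young[i] and not new[i]:
            hist = win_start - int(rng.integers(30, 701))
            contacts.append((p, hist, "CMHC_outpatient", "psychiatric_visit", "psychiatrist",
                             _DIAG_CODES[int(rng.integers(0, len(_DIAG_CODES)))]))

        # materialise events, truncating at death
        dd = int(death_rel[j]) if death[j] else None
        diag = _DIAG_CODES[int(rng.integers(0, len(_DIAG_CODES)))]
        for c in pool:
            if dd is not None and c[0] > dd:
                continue
            code = diag if (c[0] == 0 and c[2] == "psychiatric_visit") else ""
            contacts.append((p, idx + c[0], c[1], c[2], "mh_professional", code))
            if code:
                diag = ""  # only the index contact carries the diagnosis
        for d in home_days:
            if dd is not None and d > dd:
                continue
            contacts.append((p, idx + d, "home_visit", "other_professional_contact", "nurse", ""))
        for a, e, w in adms:
            if dd is not None and a > dd:
                continue
            e2 = min(e, dd) if dd is not None else e
            admissions.append((p, w, idx + a, idx + e2, "F20"))
        if dd is not None:
            p_disp = [r for r in p_disp if r[1] <= idx + dd]
            p_labs = [r for r in p_labs if r[1] <= idx + dd]
            deaths.append((p, idx + dd))
            patients_cov_end[i] = idx + dd
        dispensings.extend(p_disp)
        labs.extend(p_labs)

    patients = pd.DataFrame({
        "patient_id": pid,
        "region": rp.name,
        "sex": sex,
        "birth_date": from_day(birth_day).values,
        "coverage_start": from_day(np.full(n, cov_start_day)).values,
        "coverage_end": from_day(patients_cov_end).values,
    })
    return patients, contacts, admissions, dispensings, labs, deaths


def simulate(params: SimulationParams) -> EventTables:
    """Generate the full multi-region CSV table suite; deterministic in the seed."""
    params.validate()
    all_pat, all_con, all_adm, all_dis, all_lab, all_dea = [], [], [], [], [], []
    for r_idx, rp in enumerate(params.regions):
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), r_idx]))
        pat, con, adm, dis, lab, dea = _simulate_region(rp, params, rng)
        all_pat.append(pat)
        all_con.extend(con)
        all_adm.extend(adm)
        all_dis.extend(dis)
        all_lab.extend(lab)
        all_dea.extend(dea)

    def frame(rows, cols, date_cols):
        df = pd.DataFrame(rows, columns=cols)
        for c in date_cols:
            df[c] = from_day(df[c]).values if len(df) else pd.Series(dtype="datetime64[ns]")
        return df

    lo, hi = params.age_range
    tables = EventTables(
        patients=pd.concat(all_pat, ignore_index=True),
        contacts=frame(all_con, ["patient_id", "date", "setting", "intervention",
                                 "provider_role", "diagnosis_code"], ["date"]),
        admissions=frame(all_adm, ["patient_id", "ward", "admission_date",
                                   "discharge_date", "diagnosis_code"],
                         ["admission_date", "discharge_date"]),
        dispensings=frame(all_dis, ["patient_id", "date", "atc_code", "total_amount"], ["date"]),
        labs=frame(all_lab, ["patient_id", "date", "panel"], ["date"]),
        deaths=frame(all_dea, ["patient_id", "death_date"], ["death_date"]),
        ddd_reference=default_ddd_reference(),
        population_rates=default_population_rates(18, 65),
        standard_population=default_standard_population(lo, hi),
    )
    return tables
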