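"""Cohort phenotyping tests: direct rules, lookback exclusions, metamorphic
properties and equality with a slow event-by-event reimplementation."""

import math

import numpy as np
import pandas as pd
import pytest

import quadim as q
from quadim.model import (
    default_ddd_reference,
    default_population_rates,
    default_standard_population,
    to_day,
)

WINDOW = ("2015-01-01", "2016-01-01")


def _tables(patients, contacts=None, admissions=None, dispensings=None):
    def df(rows, cols, dates):
        out = pd.DataFrame(rows, columns=cols)
        for c in dates:
            out[c] = pd.to_datetime(out[c]) if len(out) else pd.Series(dtype="datetime64[ns]")
        return out

    return q.EventTables(
        patients=df(patients, ["patient_id", "region", "sex", "birth_date",
                               "coverage_start", "coverage_end"],
                    ["birth_date", "coverage_start", "coverage_end"]),
        contacts=df(contacts or [], ["patient_id", "date", "setting", "intervention",
                                     "provider_role", "diagnosis_code"], ["date"]),
        admissions=df(admissions or [], ["patient_id", "ward", "admission_date",
                                         "discharge_date", "diagnosis_code"],
                      ["admission_date", "discharge_date"]),
        dispensings=df(dispensings or [], ["patient_id", "date", "atc_code", "total_amount"],
                       ["date"]),
        labs=df([], ["patient_id", "date", "panel"], ["date"]),
        deaths=df([], ["patient_id", "death_date"], ["death_date"]),
        ddd_reference=default_ddd_reference(),
        population_rates=default_population_rates(18, 65),
        standard_population=default_standard_population(18, 65),
    )


def _patient(pid, birth, cov_end="2019-12-31"):
    return (pid, "r1", "M", birth, "2005-01-01", cov_end)


def _visit(pid, date, code="F20"):
    return (pid, date, "CMHC_outpatient", "psychiatric_visit", "psychiatrist", code)


class TestSelectPrevalent:
    def test_single_qualifying_contact_sets_index(self):
        t = _tables([_patient("p1", "1985-02-10")], [_visit("p1", "2015-03-01")])
        m = q.select_prevalent(t, WINDOW)
        assert len(m) == 1
        assert m.loc[0, "index_date"] == pd.Timestamp("2015-03-01")
        assert m.loc[0, "follow_up_end"] == pd.Timestamp("2016-02-29")
        assert m.loc[0, "age_at_index"] == 30
        assert m.loc[0, "person_years"] == 1.0

    def test_index_is_earliest_qualifying_event(self):
        t = _tables([_patient("p1", "1985-02-10")],
                    [_visit("p1", "2015-09-01"), _visit("p1", "2015-04-15")])
        m = q.select_prevalent(t, WINDOW)
        assert m.loc[0, "index_date"] == pd.Timestamp("2015-04-15")

    @pytest.mark.parametrize("birth,included", [
        ("1948-09-01", False),   # 66 at contact
        ("1949-09-01", True),    # 65 at contact
        ("1996-09-01", True),    # 18 at contact
        ("1997-09-01", False),   # 17 at contact
    ])
    def test_age_bounds_at_index(self, birth, included):
        t = _tables([_patient("p1", birth)], [_visit("p1", "2015-03-01")])
        assert len(q.select_prevalent(t, WINDOW)) == (1 if included else 0)

    def test_non_spectrum_diagnosis_does_not_qualify(self):
        t = _tables([_patient("p1", "1985-02-10")], [_visit("p1", "2015-03-01", "F32")])
        assert len(q.select_prevalent(t, WINDOW)) == 0

    def test_qualifying_admission_also_selects(self):
        t = _tables([_patient("p1", "1985-02-10")],
                    admissions=[("p1", "GHPW", "2015-05-01", "2015-05-20", "F20")])
        m = q.select_prevalent(t, WINDOW)
        assert len(m) == 1 and m.loc[0, "index_date"] == pd.Timestamp("2015-05-01")

    def test_incomplete_follow_up_excluded_unless_death(self):
        t = _tables([_patient("p1", "1985-02-10", cov_end="2015-09-30")],
                    [_visit("p1", "2015-03-01")])
        assert len(q.select_prevalent(t, WINDOW)) == 0
        # same patient but coverage ends at death during follow-up: retained, censored
        t2 = _tables([_patient("p1", "1985-02-10", cov_end="2015-09-30")],
                     [_visit("p1", "2015-03-01")])
        t2.deaths = pd.DataFrame({"patient_id": ["p1"],
                                  "death_date": pd.to_datetime(["2015-09-30"])})
        m = q.select_prevalent(t2, WINDOW)
        assert len(m) == 1
        assert bool(m.loc[0, "died"]) and not bool(m.loc[0, "full_follow_up"])
        assert 0 < m.loc[0, "person_years"] < 1

    def test_empty_window_is_fatal(self):
        t = _tables([_patient("p1", "1985-02-10")], [_visit("p1", "2015-03-01")])
        with pytest.raises(ValueError, match="window"):
            q.select_prevalent(t, ("2015-01-01", "2015-01-01"))


class TestSelectNew:
    def _base(self, extra_contacts=None, admissions=None, dispensings=None):
        t = _tables([_patient("p1", "1990-02-10")],
                    [_visit("p1", "2015-06-01")] + (extra_contacts or []),
                    admissions, dispensings)
        prev = q.select_prevalent(t, WINDOW)
        return q.select_new(prev, t), prev

    def test_clean_history_included(self):
        new, prev = self._base()
        assert len(prev) == 1 and len(new) == 1
        assert new.loc[0, "cohort"] == "newly_taken_in_care"

    def test_prior_ghpw_admission_in_lookback_excludes(self):
        new, _ = self._base(admissions=[("p1", "GHPW", "2013-12-01", "2013-12-10", "")])
        assert len(new) == 0

    def test_prior_ghpw_before_lookback_does_not_exclude(self):
        new, _ = self._base(admissions=[("p1", "GHPW", "2012-01-01", "2012-01-10", "")])
        assert len(new) == 1

    def test_prior_diagnosis_excludes_at_any_time(self):
        new, _ = self._base(extra_contacts=[_visit("p1", "2009-05-01")])
        assert len(new) == 0

    def test_two_consecutive_dispensings_in_lookback_exclude(self):
        # 300 mg olanzapine = 30 days supply; refill 40 days later -> gap 10 < 90
        new, _ = self._base(dispensings=[("p1", "2014-01-01", "N05AH03", 300.0),
                                         ("p1", "2014-02-10", "N05AH03", 300.0)])
        assert len(new) == 0

    def test_two_interrupted_dispensings_do_not_exclude(self):
        # refill 130 days after supply end -> interrupted, not "consecutive"
        new, _ = self._base(dispensings=[("p1", "2014-01-01", "N05AH03", 300.0),
                                         ("p1", "2014-06-10", "N05AH03", 300.0)])
        assert len(new) == 1

    def test_lithium_dispensings_do_not_exclude(self):
        new, _ = self._base(dispensings=[("p1", "2014-01-01", "N05AN01", 300.0),
                                         ("p1", "2014-01-20", "N05AN01", 300.0)])
        assert len(new) == 1

    def test_age_over_40_not_eligible(self):
        t = _tables([_patient("p1", "1970-02-10")], [_visit("p1", "2015-06-01")])
        prev = q.select_prevalent(t, WINDOW)
        assert len(prev) == 1
        assert len(q.select_new(prev, t)) == 0


# ---------------------------------------------------------------------------
# randomized fixtures vs a slow, day-by-day reimplementation


def _random_tables(rng, n_patients=50):
    patients, contacts, admissions, dispensings = [], [], [], []
    day0 = int(to_day(pd.Series(["2015-01-01"]))[0])
    for i in range(n_patients):
        pid = f"p{i}"
        age = int(rng.integers(15, 70))
        birth = day0 - age * 366 - int(rng.integers(0, 300))
        patients.append((pid, "r1", "M" if rng.random() < 0.5 else "F",
                         str(pd.Timestamp(np.datetime64(birth, "D"))),
                         "2005-01-01",
                         "2019-12-31" if rng.random() < 0.8 else "2015-10-01"))
        for _ in range(int(rng.integers(0, 4))):
            d = day0 + int(rng.integers(-1200, 700))
            code = rng.choice(["F20", "F32", "", "295.30"])
            contacts.append((pid, str(pd.Timestamp(np.datetime64(d, "D"))),
                             "CMHC_outpatient", "psychiatric_visit", "x", code))
        for _ in range(int(rng.integers(0, 2))):
            d = day0 + int(rng.integers(-1200, 700))
            ward = rng.choice(["GHPW", "CRF", "other_hospital"])
            code = rng.choice(["F20", "", "K50"])
            admissions.append((pid, ward, str(pd.Timestamp(np.datetime64(d, "D"))),
                               str(pd.Timestamp(np.datetime64(d + int(rng.integers(0, 40)), "D"))),
                               code))
        for _ in range(int(rng.integers(0, 4))):
            d = day0 - int(rng.integers(0, 1000))
            dispensings.append((pid, str(pd.Timestamp(np.datetime64(d, "D"))),
                                rng.choice(["N05AH03", "N05AN01"]),
                                float(rng.integers(1, 10) * 100)))
    return _tables(patients, contacts, admissions, dispensings)


def _brute_prevalent(tables, w0, w1):
    """Slow per-patient scan re-deriving the prevalent selection rule."""
    out = {}
    codes = q.CodeConfig()
    for _, p in tables.patients.iterrows():
        events = []
        c = tables.contacts[tables.contacts.patient_id == p.patient_id]
        for _, r in c.iterrows():
            if codes.is_diagnosis([r.diagnosis_code])[0]:
                events.append(int(to_day(pd.Series([r["date"]]))[0]))
        a = tables.admissions[tables.admissions.patient_id == p.patient_id]
        for _, r in a.iterrows():
            if r.ward in ("GHPW", "CRF") and codes.is_diagnosis([r.diagnosis_code])[0]:
                events.append(int(to_day(pd.Series([r.admission_date]))[0]))
        events = [e for e in events if w0 <= e < w1]
        if not events:
            continue
        idx = min(events)
        birth = int(to_day(pd.Series([p.birth_date]))[0])
        age = math.floor((idx - birth) / 365.2425)
        if not 18 <= age <= 65:
            continue
        cov_end = int(to_day(pd.Series([p.coverage_end]))[0])
        if cov_end + 1 < idx + 365:  # no death table in this fixture family
            continue
        out[p.patient_id] = idx
    return out


def test_prevalent_selection_matches_brute_force():
    rng = np.random.default_rng(2015)
    w0, w1 = (int(x) for x in to_day(pd.Series(list(WINDOW))))
    for _ in range(8):
        t = _random_tables(rng)
        got = q.select_prevalent(t, WINDOW)
        expected = _brute_prevalent(t, w0, w1)
        assert dict(zip(got.patient_id, to_day(got.index_date))) == expected


def test_new_cohort_metamorphic_properties():
    rng = np.random.default_rng(99)
    t = _random_tables(rng, n_patients=80)
    prev = q.select_prevalent(t, WINDOW)
    new = q.select_new(prev, t)
    young = prev[(prev.age_at_index >= 18) & (prev.age_at_index <= 40)]
    # new is a subset of the young prevalent members
    assert set(new.patient_id) <= set(young.patient_id)

    # removing all pre-index events makes every young prevalent member new
    idx_by_pid = dict(zip(prev.patient_id, to_day(prev.index_date)))
    t2 = t.copy()
    for name, col in (("contacts", "date"), ("admissions", "admission_date"),
                      ("dispensings", "date")):
        df = t2.table(name)
        if not len(df):
            continue
        idx = df.patient_id.map(idx_by_pid)
        keep = idx.isna() | (to_day(df[col]) >= idx.fillna(-10**9))
        setattr(t2, name, df[keep].reset_index(drop=True))
    prev2 = q.select_prevalent(t2, WINDOW)
    new2 = q.select_new(prev2, t2)
    young2 = prev2[(prev2.age_at_index >= 18) & (prev2.age_at_index <= 40)]
    assert set(new2.patient_id) == set(young2.patient_id)

    # adding one pre-index qualifying diagnosis flips exactly that member out
    if len(new2):
        pid = new2.patient_id.iloc[0]
        extra = pd.DataFrame([(pid, pd.Timestamp("2010-06-01"), "CMHC_outpatient",
                               "psychiatric_visit", "x", "F20")],
                             columns=t2.contacts.columns)
        t3 = t2.copy()
        t3.contacts = pd.concat([t2.contacts, extra], ignore_index=True)
        new3 = q.select_new(q.select_prevalent(t3, WINDOW), t3)
        assert set(new2.patient_id) - set(new3.patient_id) == {pid}
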