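"""Shared fixtures: a tiny hand-built table suite and one large seeded
simulation with planted indicator values, used by the recovery suites."""

import numpy as np
import pandas as pd
import pytest

import quadim as q
from quadim.model import default_ddd_reference, default_population_rates, default_standard_population

RECOVERY_SEED = 11


def _dates(*iso):
    return pd.to_datetime(list(iso))


@pytest.fixture()
def tiny_tables():
    """Three patients, five contacts, one admission/dispensing/lab/death."""
    patients = pd.DataFrame({
        "patient_id": ["p1", "p2", "p3"],
        "region": ["nord", "nord", "süd"],
        "sex": ["M", "F", "F"],
        "birth_date": _dates("1980-05-01", "1990-01-15", "1955-07-30"),
        "coverage_start": _dates("2008-01-01", "2008-01-01", "2008-01-01"),
        "coverage_end": _dates("2019-12-31", "2019-12-31", "2019-12-31"),
    })
    contacts = pd.DataFrame({
        "patient_id": ["p1", "p1", "p2", "p2", "p3"],
        "date": _dates("2015-03-01", "2015-05-10", "2015-02-01", "2015-02-20", "2015-06-01"),
        "setting": ["CMHC_outpatient"] * 4 + ["day_care"],
        "intervention": ["psychiatric_visit", "psychotherapy", "psychiatric_visit",
                         "other_professional_contact", "rehabilitation"],
        "provider_role": ["psychiatrist", "psychologist", "psychiatrist", "nurse", "educator"],
        "diagnosis_code": ["F20", "", "295.30", "", "F25.1"],
    })
    admissions = pd.DataFrame({
        "patient_id": ["p1"],
        "ward": ["GHPW"],
        "admission_date": _dates("2015-07-01"),
        "discharge_date": _dates("2015-07-15"),
        "diagnosis_code": ["F20"],
    })
    dispensings = pd.DataFrame({
        "patient_id": ["p2"],
        "date": _dates("2015-03-01"),
        "atc_code": ["N05AH03"],
        "total_amount": [300.0],
    })
    labs = pd.DataFrame({
        "patient_id": ["p2"],
        "date": _dates("2015-04-01"),
        "panel": ["blood_glucose"],
    })
    deaths = pd.DataFrame({
        "patient_id": ["p3"],
        "death_date": _dates("2015-11-20"),
    })
    return q.EventTables(
        patients=patients, contacts=contacts, admissions=admissions,
        dispensings=dispensings, labs=labs, deaths=deaths,
        ddd_reference=default_ddd_reference(),
        population_rates=default_population_rates(18, 65),
        standard_population=default_standard_population(18, 65),
    )


@pytest.fixture(scope="session")
def recovery_params():
    """Four regions, ~20,000 planted cases, indicator values at their defaults."""
    regions = [q.RegionParams(name=f"R{i}", n_inhabitants=125_000,
                              prevalence_per_10k=400.0, incidence_per_10k=80.0)
               for i in range(4)]
    return q.SimulationParams(seed=RECOVERY_SEED, regions=regions)


@pytest.fixture(scope="session")
def recovery_run(recovery_params):
    """Simulated tables + cohorts + indicator estimates + planted truth."""
    tables = q.simulate(recovery_params)
    prevalent = q.select_prevalent(tables)
    new = q.select_new(prevalent, tables)
    members = pd.concat([prevalent, new], ignore_index=True)
    estimates = q.compute_indicators(tables, members)
    truth = q.planted_truth(recovery_params)
    return {"params": recovery_params, "tables": tables, "prevalent": prevalent,
            "new": new, "members": members, "estimates": estimates, "truth": truth}


def pooled_z_scores(estimates: pd.DataFrame, truth: pd.DataFrame, cohort: str) -> pd.DataFrame:
    """Aggregate regional estimates and standardise against the planted truth."""
    e = estimates[estimates["cohort"] == cohort]
    rows = []
    for ind, g in e.groupby("indicator_id"):
        num, den = np.nansum(g["numerator"]), np.nansum(g["denominator"])
        if den == 0:
            continue
        est = num / den
        se = float(np.sqrt(np.nansum(g["se"] ** 2 * g["denominator"] ** 2)) / den)
        rows.append((ind, est, se))
    agg = pd.DataFrame(rows, columns=["indicator_id", "estimate", "se"]).set_index("indicator_id")
    planted = truth[truth["region"] == truth["region"].iloc[0]].set_index("indicator_id")["true_value"]
    agg["planted"] = planted
    agg = agg.dropna(subset=["planted"])
    agg["z"] = (agg["estimate"] - agg["planted"]) / np.maximum(agg["se"], 1e-12)
    return agg
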