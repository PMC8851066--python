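"""Domain model for linked healthcare-utilisation (HCU) event tables.

The package works on a set of per-patient, date-stamped CSV tables emulating
the regional administrative databases used to monitor community mental health
care: a patient registry, mental-health contacts, hospital/residential
admissions, drug dispensings, lab tests and deaths, plus three reference
tables (defined daily doses, general-population mortality rates and a
standard population for direct age standardisation).

Conventions
-----------
* Dates are calendar dates (no times); internally they are converted to
  integer day offsets and every interval is half-open ``[start, end)``.
* Age is computed as ``floor((date - birth_date) / 365.2425)`` days/years,
  a pure day-arithmetic convention applied uniformly by the generator and
  the cohort builder.
* Diagnosis code sets and the antipsychotic ATC definition are configurable;
  the shipped defaults accept both ICD-9-CM (295*, 297*, 298*) and ICD-10
  (F20-F29) dialects and ATC prefix N05A excluding lithium (N05AN01).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CodeConfig",
    "EventTables",
    "ValidationError",
    "read_tables",
    "write_tables",
    "validate_tables",
    "default_ddd_reference",
    "default_population_rates",
    "default_standard_population",
    "age_years",
    "age_band",
    "AGE_BANDS_18_65",
]

DAYS_PER_YEAR = 365.2425

SEXES = ("M", "F")
SETTINGS = ("CMHC_outpatient", "home_visit", "day_care")
INTERVENTIONS = (
    "psychiatric_visit",
    "other_professional_contact",
    "structured_assessment",
    "psychotherapy",
    "psychoeducation",
    "rehabilitation",
    "family_intervention",
)
WARDS = ("GHPW", "CRF", "other_hospital")
LAB_PANELS = ("blood_glucose", "lipid_profile")

# community settings that count as outpatient/day-care contacts
COMMUNITY_SETTINGS = ("CMHC_outpatient", "day_care")

TABLE_FILES = {
    "patients": "patients.csv",
    "contacts": "contacts.csv",
    "admissions": "admissions.csv",
    "dispensings": "dispensings.csv",
    "labs": "labs.csv",
    "deaths": "deaths.csv",
    "ddd_reference": "ddd_reference.csv",
    "population_rates": "population_rates.csv",
    "standard_population": "standard_population.csv",
}

_DATE_COLS = {
    "patients": ["birth_date", "coverage_start", "coverage_end"],
    "contacts": ["date"],
    "admissions": ["admission_date", "discharge_date"],
    "dispensings": ["date"],
    "labs": ["date"],
    "deaths": ["death_date"],
}

COLUMNS = {
    "patients": ["patient_id", "region", "sex", "birth_date", "coverage_start", "coverage_end"],
    "contacts": ["patient_id", "date", "setting", "intervention", "provider_role", "diagnosis_code"],
    "admissions": ["patient_id", "ward", "admission_date", "discharge_date", "diagnosis_code"],
    "dispensings": ["patient_id", "date", "atc_code", "total_amount"],
    "labs": ["patient_id", "date", "panel"],
    "deaths": ["patient_id", "death_date"],
    "ddd_reference": ["atc_code", "ddd"],
    "population_rates": ["sex", "age_band", "rate"],
    "standard_population": ["age_band", "weight"],
}


class ValidationError(ValueError):
    """Raised when an event table violates a schema or linkage invariant."""


# ---------------------------------------------------------------------------
# date and age helpers


def to_day(dates) -> np.ndarray:
    """Calendar dates -> integer days since 1970-01-01 (vectorised)."""
    arr = pd.to_datetime(pd.Series(dates) if not isinstance(dates, pd.Series) else dates)
    return (arr.values.astype("datetime64[D]").astype("int64")).astype(np.int64)


def from_day(days) -> pd.Series:
    """Integer day offsets -> pandas Timestamps."""
    return pd.Series(np.asarray(days, dtype="int64").astype("datetime64[D]"))


def age_years(birth, at) -> np.ndarray:
    """Completed years of age at date ``at`` (floor, day-arithmetic convention)."""
    b = to_day(birth)
    a = to_day(at)
    return np.floor((a - b) / DAYS_PER_YEAR).astype(int)


def age_band(age) -> np.ndarray:
    """5-year age band label ('15-19', '20-24', ...) for integer ages."""
    age = np.asarray(age, dtype=int)
    lo = (age // 5) * 5
    return np.char.add(np.char.add(lo.astype(str), "-"), (lo + 4).astype(str))


def _bands(age_min: int, age_max: int) -> list[str]:
    los = range((age_min // 5) * 5, (age_max // 5) * 5 + 1, 5)
    return [f"{lo}-{lo + 4}" for lo in los]


AGE_BANDS_18_65 = _bands(18, 65)


# ---------------------------------------------------------------------------
# code configuration


@dataclasses.dataclass(frozen=True)
class CodeConfig:
    """Configurable diagnosis / drug code sets.

    ``diagnosis_prefixes`` are string prefixes matched against
    ``diagnosis_code`` (both ICD-9-CM and ICD-10 dialects may be listed
    together); ``antipsychotic_prefixes`` are ATC prefixes, with exact codes
    in ``antipsychotic_exclusions`` removed (lithium by default).
    """

    diagnosis_prefixes: tuple[str, ...] = ("295", "297", "298", "F2")
    antipsychotic_prefixes: tuple[str, ...] = ("N05A",)
    antipsychotic_exclusions: tuple[str, ...] = ("N05AN01",)

    def is_diagnosis(self, codes) -> np.ndarray:
        s = pd.Series(codes, dtype="object").fillna("").astype(str)
        out = np.zeros(len(s), dtype=bool)
        for p in self.diagnosis_prefixes:
            out |= s.str.startswith(p).values
        return out

    def is_antipsychotic(self, atc_codes) -> np.ndarray:
        s = pd.Series(atc_codes, dtype="object").fillna("").astype(str)
        out = np.zeros(len(s), dtype=bool)
        for p in self.antipsychotic_prefixes:
            out |= s.str.startswith(p).values
        for e in self.antipsychotic_exclusions:
            out &= (s != e).values
        return out

    @classmethod
    def from_yaml(cls, path) -> "CodeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("diagnosis_prefixes", "antipsychotic_prefixes", "antipsychotic_exclusions"):
            if key in raw:
                kwargs[key] = tuple(str(x) for x in raw[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# container


@dataclasses.dataclass
class EventTables:
    """The linked set of HCU tables for one or more regions."""

    patients: pd.DataFrame
    contacts: pd.DataFrame
    admissions: pd.DataFrame
    dispensings: pd.DataFrame
    labs: pd.DataFrame
    deaths: pd.DataFrame
    ddd_reference: pd.DataFrame
    population_rates: pd.DataFrame
    standard_population: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLE_FILES}

    def copy(self) -> "EventTables":
        return EventTables(**{name: self.table(name).copy() for name in TABLE_FILES})


def empty_tables() -> EventTables:
    """An EventTables with all-empty, correctly typed tables."""
    frames = {}
    for name, cols in COLUMNS.items():
        df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
        for c in _DATE_COLS.get(name, []):
            df[c] = pd.Series(dtype="datetime64[ns]")
        if name == "dispensings":
            df["total_amount"] = pd.Series(dtype=float)
        if name == "ddd_reference":
            df["ddd"] = pd.Series(dtype=float)
        if name == "population_rates":
            df["rate"] = pd.Series(dtype=float)
        if name == "standard_population":
            df["weight"] = pd.Series(dtype=float)
        frames[name] = df
    return EventTables(**frames)


# ---------------------------------------------------------------------------
# reference table defaults (synthetic stand-ins, clearly labelled)


def default_ddd_reference() -> pd.DataFrame:
    """Synthetic DDD table for a small set of antipsychotics (WHO-style units).

    Amounts in dispensings are expressed in the same unit as the DDD, so only
    the ratio matters for supply-duration arithmetic.
    """
    rows = [
        ("N05AA01", 300.0),  # chlorpromazine, mg
        ("N05AD01", 8.0),    # haloperidol, mg
        ("N05AH02", 300.0),  # clozapine, mg
        ("N05AH03", 10.0),   # olanzapine, mg
        ("N05AH04", 400.0),  # quetiapine, mg
        ("N05AX08", 5.0),    # risperidone, mg
        ("N05AX12", 15.0),   # aripiprazole, mg
        ("N05AN01", 24.0),   # lithium, mmol -- excluded from the antipsychotic set
    ]
    return pd.DataFrame(rows, columns=["atc_code", "ddd"])


def default_population_rates(age_min: int = 18, age_max: int = 65) -> pd.DataFrame:
    """Synthetic general-population annual mortality rates by sex x 5-year band.

    Gompertz-like increase with age, male rates roughly double the female
    ones; magnitudes in the range of a Western European adult population.
    """
    rows = []
    for band in _bands(age_min, age_max):
        lo = int(band.split("-")[0])
        mid = lo + 2.0
        for sex, a in (("M", 4.0e-4), ("F", 2.2e-4)):
            rate = a * float(np.exp(0.068 * (mid - 18.0)))
            rows.append((sex, band, rate))
    return pd.DataFrame(rows, columns=["sex", "age_band", "rate"])


def default_standard_population(age_min: int = 18, age_max: int = 65) -> pd.DataFrame:
    """Uniform standard-population weights over the 5-year bands in range."""
    bands = _bands(age_min, age_max)
    w = 1.0 / len(bands)
    return pd.DataFrame({"age_band": bands, "weight": [w] * len(bands)})


# ---------------------------------------------------------------------------
# validation


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _offending_rows(mask: np.ndarray, limit: int = 5) -> str:
    idx = np.flatnonzero(mask)[:limit]
    return ", ".join(str(i) for i in idx)


def validate_tables(tables: EventTables, code_config: CodeConfig | None = None) -> None:
    """Check every schema, linkage and date invariant; raise ValidationError.

    Errors name the table and the first few offending row indices.
    """
    pat = tables.patients
    for name, cols in COLUMNS.items():
        df = tables.table(name)
        missing = [c for c in cols if c not in df.columns]
        _check(not missing, f"{name}: missing columns {missing}")

    _check(pat["sex"].isin(SEXES).all(), "patients: sex must be M or F")
    # events carry no region column, so linkage requires globally unique ids
    dup = pat.duplicated(subset=["patient_id"])
    _check(not dup.any(), f"patients: duplicate patient_id at rows {_offending_rows(dup.values)}")
    if len(pat):
        b, cs, ce = to_day(pat["birth_date"]), to_day(pat["coverage_start"]), to_day(pat["coverage_end"])
        bad = ~((b < cs) & (cs <= ce))
        _check(not bad.any(), f"patients: birth_date < coverage_start <= coverage_end violated at rows {_offending_rows(bad)}")

    known = set(pat["patient_id"])
    cov = pat.set_index("patient_id")[["coverage_start", "coverage_end"]]

    def _linked(df: pd.DataFrame, name: str) -> None:
        if not len(df):
            return
        unknown = ~df["patient_id"].isin(known)
        if unknown.any():
            raise ValidationError(
                f"{name}: patient_id not in registry at rows {_offending_rows(unknown.values)} "
                f"(e.g. {df.loc[unknown, 'patient_id'].iloc[0]!r})"
            )

    def _in_coverage(df: pd.DataFrame, name: str, col: str) -> None:
        if not len(df):
            return
        j = df.join(cov, on="patient_id")
        d = to_day(j[col])
        bad = (d < to_day(j["coverage_start"])) | (d >= to_day(j["coverage_end"]) + 1)
        _check(not bad.any(), f"{name}: {col} outside patient coverage at rows {_offending_rows(bad)}")

    for name in ("contacts", "admissions", "dispensings", "labs", "deaths"):
        _linked(tables.table(name), name)

    con = tables.contacts
    if len(con):
        _check(con["setting"].isin(SETTINGS).all(), "contacts: unknown setting")
        _check(con["intervention"].isin(INTERVENTIONS).all(), "contacts: unknown intervention")
        _in_coverage(con, "contacts", "date")

    adm = tables.admissions
    if len(adm):
        _check(adm["ward"].isin(WARDS).all(), "admissions: unknown ward")
        a, d = to_day(adm["admission_date"]), to_day(adm["discharge_date"])
        bad = a > d
        _check(not bad.any(), f"admissions: admission_date > discharge_date at rows {_offending_rows(bad)}")
        _in_coverage(adm, "admissions", "admission_date")

    disp = tables.dispensings
    if len(disp):
        amt = pd.to_numeric(disp["total_amount"])
        bad = ~(amt > 0).values
        _check(not bad.any(), f"dispensings: total_amount must be > 0 at rows {_offending_rows(bad)}")
        in_ddd = disp["atc_code"].isin(set(tables.ddd_reference["atc_code"]))
        if not in_ddd.all():
            raise ValidationError(
                "dispensings: atc_code missing from DDD reference at rows "
                f"{_offending_rows((~in_ddd).values)} "
                f"(e.g. {disp.loc[~in_ddd, 'atc_code'].iloc[0]!r})"
            )
        _in_coverage(disp, "dispensings", "date")

    labs = tables.labs
    if len(labs):
        _check(labs["panel"].isin(LAB_PANELS).all(), "labs: unknown panel")
        _in_coverage(labs, "labs", "date")

    dea = tables.deaths
    if len(dea):
        dup = dea.duplicated(subset=["patient_id"])
        _check(not dup.any(), f"deaths: more than one record per patient at rows {_offending_rows(dup.values)}")
        j = dea.join(cov, on="patient_id")
        bad = to_day(j["death_date"]) < to_day(j["coverage_start"])
        _check(not bad.any(), f"deaths: death_date before coverage_start at rows {_offending_rows(bad)}")

    rates = tables.population_rates
    if len(rates):
        _check((pd.to_numeric(rates["rate"]) >= 0).all(), "population_rates: negative rate")
        have = set(map(tuple, rates[["sex", "age_band"]].itertuples(index=False)))
        need = {(s, b) for s in SEXES for b in AGE_BANDS_18_65}
        missing = need - have
        _check(not missing, f"population_rates: missing (sex, band) strata for ages 18-65: {sorted(missing)[:4]}")

    std = tables.standard_population
    if len(std):
        w = pd.to_numeric(std["weight"])
        _check((w >= 0).all(), "standard_population: negative weight")
        _check(w.sum() > 0, "standard_population: weights sum to zero")


# ---------------------------------------------------------------------------
# readers / writers


def read_tables(directory, schema_config: dict | None = None, validate: bool = True) -> EventTables:
    """Read and validate the CSV table suite from ``directory``.

    ``schema_config`` may remap file names per table (``{"patients":
    "registry.csv", ...}``). Dates are parsed from ISO-8601; a malformed date
    raises :class:`ValidationError` naming the table, column and row.
    """
    directory = Path(directory)
    files = dict(TABLE_FILES)
    if schema_config:
        files.update(schema_config)
    frames = {}
    for name, fname in files.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"required table file missing: {path}")
        df = pd.read_csv(path, dtype={"patient_id": str, "diagnosis_code": str, "atc_code": str})
        for col in ("diagnosis_code", "provider_role"):
            if col in df.columns:
                df[col] = df[col].fillna("")
        for col in _DATE_COLS.get(name, []):
            parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.values)[0])
                raise ValidationError(
                    f"{name}: malformed date in column {col!r} at row {row}: {df[col].iloc[row]!r}"
                )
            df[col] = parsed
        frames[name] = df
    tables = EventTables(**frames)
    if validate:
        validate_tables(tables)
    return tables


def write_tables(tables: EventTables, directory) -> None:
    """Write the table suite as CSVs with ISO-8601 dates (UTF-8)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in TABLE_FILES.items():
        df = tables.table(name).copy()
        for col in _DATE_COLS.get(name, []):
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(directory / fname, index=False)
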