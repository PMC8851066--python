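"""End-to-end orchestration: tables -> cohorts -> indicators -> pooling.

The run produces a machine-readable "dashboard" bundle in the output
directory — ``cohorts.csv``, ``indicators.csv``, ``pooled.csv``, ``smr.csv``,
``rates.csv``, a Markdown summary with per-region columns, the pooled column
and the homogeneity/heterogeneity statistics, and ``run.log`` — and is a pure
function of (input tables, configuration, seed); inputs are never mutated.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from pathlib import Path

import pandas as pd
import yaml

from .cohorts import DEFAULT_RECRUITMENT, select_new, select_prevalent
from .indicators import (
    Thresholds,
    compute_indicators,
    default_catalogue,
    standardised_treatment_rate,
)
from .model import CodeConfig, EventTables, read_tables, validate_tables
from .pooling import expected_deaths, pool_and_test, smr

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("quadim")


@dataclasses.dataclass
class RunConfig:
    recruitment_start: str = DEFAULT_RECRUITMENT[0]
    recruitment_end: str = DEFAULT_RECRUITMENT[1]
    lookback_years: int = 2
    age_range_prevalent: tuple[int, int] = (18, 65)
    age_range_new: tuple[int, int] = (18, 40)
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    code_config: CodeConfig = dataclasses.field(default_factory=CodeConfig)
    i2_from: str = "Q"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("recruitment_start", "recruitment_end", "lookback_years", "i2_from"):
            if key in raw:
                kwargs[key] = raw[key]
        if "thresholds" in raw:
            kwargs["thresholds"] = Thresholds(**raw["thresholds"])
        code_keys = {k: tuple(v) for k, v in raw.items()
                     if k in ("diagnosis_prefixes", "antipsychotic_prefixes",
                              "antipsychotic_exclusions")}
        if code_keys:
            kwargs["code_config"] = CodeConfig(**code_keys)
        for key in ("age_range_prevalent", "age_range_new"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)


def build_cohorts(tables: EventTables, config: RunConfig) -> pd.DataFrame:
    prevalent = select_prevalent(
        tables, (config.recruitment_start, config.recruitment_end),
        config.code_config, config.age_range_prevalent)
    new = select_new(prevalent, tables, config.lookback_years,
                     config.code_config, config.age_range_new,
                     config.thresholds.gap_days)
    return pd.concat([prevalent, new], ignore_index=True)


def pool_indicators(estimates: pd.DataFrame, i2_from: str = "Q") -> pd.DataFrame:
    """Pool every (indicator, cohort) across regions into one summary frame."""
    rows = []
    for (ind, cohort), grp in estimates.groupby(["indicator_id", "cohort"], sort=False):
        defined = grp.dropna(subset=["estimate"])
        if defined.empty:
            continue
        r = pool_and_test(grp, i2_from=i2_from)
        rows.append((ind, cohort, r.statistic, r.pooled_estimate, r.Q, r.df,
                     r.p_homogeneity, r.I2, r.anova_F))
    return pd.DataFrame(rows, columns=["indicator_id", "cohort", "statistic", "pooled",
                                       "Q", "df", "p_homogeneity", "I2", "anova_F"])


def _smr_table(members: pd.DataFrame, tables: EventTables) -> pd.DataFrame:
    rows = []
    for cohort, cgrp in members.groupby("cohort"):
        parts = []
        for region, grp in cgrp.groupby("region"):
            o = int(grp["died"].sum())
            e = expected_deaths(grp, tables.population_rates)
            parts.append((region, o, e))
        parts.append(("pooled", sum(o for _, o, _ in parts), sum(e for _, _, e in parts)))
        for region, o, e in parts:
            if e > 0:
                res = smr(o, e)
                rows.append((cohort, region, o, e, res.smr, res.ci95[0], res.ci95[1]))
    return pd.DataFrame(rows, columns=["cohort", "region", "observed", "expected",
                                       "smr", "ci_low", "ci_high"])


def _rates_table(members: pd.DataFrame, tables: EventTables, config: RunConfig) -> pd.DataFrame:
    """Age-standardised treated prevalence / incidence rates per region and overall."""
    rows = []
    pat = tables.patients
    std = tables.standard_population
    specs = [("prevalence_rate", "prevalent", config.age_range_prevalent),
             ("incidence_rate", "newly_taken_in_care", config.age_range_new)]
    mid = str((pd.Timestamp(config.recruitment_start) + pd.Timedelta(days=182)).date())
    for name, cohort, age_range in specs:
        mem = members[members["cohort"] == cohort]
        regions = sorted(pat["region"].unique())
        for region in regions + ["pooled"]:
            m = mem if region == "pooled" else mem[mem["region"] == region]
            p = pat if region == "pooled" else pat[pat["region"] == region]
            try:
                rate = standardised_treatment_rate(m, p, std, age_range, mid)
            except (ValueError, ZeroDivisionError):
                rate = float("nan")
            rows.append((name, region, len(m), rate))
    return pd.DataFrame(rows, columns=["rate", "region", "n_members", "per_10k"])


def _summary_markdown(estimates: pd.DataFrame, pooled: pd.DataFrame) -> str:
    catalogue = {d.id: d for d in default_catalogue()}
    lines = ["# Indicator summary", ""]
    for cohort, cgrp in estimates.groupby("cohort"):
        regions = sorted(cgrp["region"].unique())
        lines.append(f"## Cohort: {cohort}")
        lines.append("")
        header = "| indicator | " + " | ".join(regions) + " | pooled | p-homog. | I2 (%) |"
        lines.append(header)
        lines.append("|" + "---|" * (len(regions) + 4))
        pool_idx = pooled.set_index(["indicator_id", "cohort"]) if len(pooled) else None
        for ind, igrp in cgrp.groupby("indicator_id", sort=False):
            label = catalogue[ind].label if ind in catalogue else ind
            cells = []
            by_region = igrp.set_index("region")["estimate"]
            for r in regions:
                v = by_region.get(r, float("nan"))
                cells.append("—" if pd.isna(v) else f"{v:.3g}")
            if pool_idx is not None and (ind, cohort) in pool_idx.index:
                row = pool_idx.loc[(ind, cohort)]
                cells += [f"{row['pooled']:.3g}",
                          "—" if pd.isna(row["p_homogeneity"]) else f"{row['p_homogeneity']:.3g}",
                          "—" if pd.isna(row["I2"]) else f"{row['I2']:.1f}"]
            else:
                cells += ["—", "—", "—"]
            lines.append(f"| {label} | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(
    tables: EventTables | None = None,
    input_dir=None,
    out_dir=".",
    config: RunConfig | None = None,
) -> dict:
    """Run cohorts -> indicators -> pooling and write the output bundle.

    Either ``tables`` (in memory) or ``input_dir`` (CSV suite) must be given.
    Returns a dict of output DataFrames plus the written file paths.
    """
    config = config or RunConfig()
    if tables is None:
        if input_dir is None:
            raise ValueError("either tables or input_dir is required")
        tables = read_tables(input_dir)
    else:
        validate_tables(tables)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("selecting cohorts (recruitment %s .. %s)",
             config.recruitment_start, config.recruitment_end)
    members = build_cohorts(tables, config)
    log.info("cohort sizes: %s", members.groupby("cohort").size().to_dict())

    estimates = compute_indicators(tables, members, None, config.code_config, config.thresholds)
    pooled = pool_indicators(estimates, config.i2_from)
    smr_table = _smr_table(members, tables)
    rates = _rates_table(members, tables, config)

    members.to_csv(out / "cohorts.csv", index=False)
    estimates.to_csv(out / "indicators.csv", index=False)
    pooled.to_csv(out / "pooled.csv", index=False)
    smr_table.to_csv(out / "smr.csv", index=False)
    rates.to_csv(out / "rates.csv", index=False)
    summary = _summary_markdown(estimates, pooled)
    (out / "summary.md").write_text(summary)
    (out / "run.log").write_text(
        f"quadim run at {_dt.datetime.now().isoformat(timespec='seconds')}\n"
        f"recruitment: {config.recruitment_start}..{config.recruitment_end}\n"
        f"lookback_years: {config.lookback_years}\n"
        f"thresholds: {config.thresholds}\n"
        f"members: {members.groupby('cohort').size().to_dict()}\n"
    )
    return {"members": members, "estimates": estimates, "pooled": pooled,
            "smr": smr_table, "rates": rates, "summary": summary, "out_dir": str(out)}
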