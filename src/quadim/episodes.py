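"""Temporal rules on day grids: drug-supply episodes, persistence, polytherapy,
readmission and post-discharge timeliness.

All functions work on integer day offsets and half-open ``[start, end)``
intervals. The clinically meaningful thresholds (90-day gap for consecutive
prescriptions and community persistence, 7/30-day readmission, 14-day
post-discharge contact) are arguments with those defaults.

Boundary conventions (applied consistently and covered by boundary tests):

* Two supplies are *consecutive* iff the gap from the end of one supply to the
  next dispensing date is **< 90** days; a gap of exactly 90 days starts a new
  episode (an interruption).
* "Within k days" after a discharge means days 1..k inclusive; a same-day
  event (day 0) does not count.
* Community persistence fails iff any uncovered run of **>= 90** consecutive
  days exists inside the 365-day window after the first contact, counting the
  stretch from the last covered day to the end of the window.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "SupplyEpisode",
    "supply_segments",
    "build_supply_episodes",
    "is_persistent_drug",
    "is_persistent_community",
    "polytherapy_days",
    "readmission_within",
    "contact_within_after_discharge",
    "merge_intervals",
    "uncovered_runs",
]

GAP_DAYS = 90


@dataclasses.dataclass(frozen=True)
class SupplyEpisode:
    """A chain of consecutive (<90-day gap) supplies of one substance."""

    patient_id: str
    atc_code: str
    start_day: int
    end_day: int  # exclusive; last supplied day + 1
    n_dispensings: int

    @property
    def duration(self) -> int:
        return self.end_day - self.start_day


def supply_segments(days: np.ndarray, amounts: np.ndarray, ddd: float) -> list[tuple[int, int]]:
    """Covered supply intervals for one patient + substance, with stockpiling.

    Each dispensing covers ``ceil(total_amount / ddd)`` days. A dispensing
    arriving while supply is still running is appended: its coverage starts
    when the previous supply ends. Input need not be sorted.
    """
    order = np.argsort(days, kind="stable")
    days = np.asarray(days)[order]
    amounts = np.asarray(amounts, dtype=float)[order]
    segs: list[tuple[int, int]] = []
    cur_end = None
    for d, amt in zip(days.tolist(), amounts.tolist()):
        dur = math.ceil(amt / ddd)
        start = int(d) if cur_end is None or d >= cur_end else int(cur_end)
        segs.append((start, start + dur))
        cur_end = start + dur
    return segs


def build_supply_episodes(
    dispensings,
    ddd_reference,
    gap_days: int = GAP_DAYS,
) -> list[SupplyEpisode]:
    """Chain each patient's dispensings of each substance into supply episodes.

    ``dispensings`` is a DataFrame with columns ``patient_id, date (or day),
    atc_code, total_amount``; ``ddd_reference`` maps ``atc_code -> ddd``.
    Episodes of the same patient and substance are separated by gaps of at
    least ``gap_days`` days between the end of one supply and the next
    dispensing date.
    """
    import pandas as pd

    from .model import to_day

    df = dispensings
    ddd_map = (
        ddd_reference.set_index("atc_code")["ddd"].to_dict()
        if hasattr(ddd_reference, "set_index")
        else dict(ddd_reference)
    )
    missing = sorted(set(df["atc_code"]) - set(ddd_map))
    if missing:
        raise KeyError(f"ATC codes missing from DDD reference: {missing}")
    day = df["day"].to_numpy() if "day" in df.columns else to_day(df["date"])
    amt = pd.to_numeric(df["total_amount"]).to_numpy(dtype=float)

    episodes: list[SupplyEpisode] = []
    frame = pd.DataFrame({"pid": df["patient_id"].to_numpy(), "atc": df["atc_code"].to_numpy(), "day": day, "amt": amt})
    for (pid, atc), grp in frame.groupby(["pid", "atc"], sort=True):
        ddd = float(ddd_map[atc])
        g = grp.sort_values("day", kind="stable")
        cur_start = cur_end = None
        n = 0
        for d, a in zip(g["day"].tolist(), g["amt"].tolist()):
            dur = math.ceil(a / ddd)
            if cur_end is None:
                cur_start, cur_end, n = d, d + dur, 1
            elif d - cur_end < gap_days:  # consecutive (includes stockpiling d < cur_end)
                start = max(d, cur_end)
                cur_end = start + dur
                n += 1
            else:  # interrupted -> new episode
                episodes.append(SupplyEpisode(pid, atc, int(cur_start), int(cur_end), n))
                cur_start, cur_end, n = d, d + dur, 1
        if cur_end is not None:
            episodes.append(SupplyEpisode(pid, atc, int(cur_start), int(cur_end), n))
    return episodes


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open integer intervals, sorted and disjoint."""
    ivs = sorted((int(a), int(b)) for a, b in intervals if b > a)
    out: list[tuple[int, int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def uncovered_runs(covered, window: tuple[int, int]) -> list[tuple[int, int]]:
    """Maximal uncovered half-open runs inside ``window`` given covered intervals."""
    lo, hi = int(window[0]), int(window[1])
    runs = []
    cur = lo
    for a, b in merge_intervals(covered):
        a, b = max(a, lo), min(b, hi)
        if b <= cur:
            continue
        if a > cur:
            runs.append((cur, min(a, hi)))
        cur = max(cur, b)
        if cur >= hi:
            break
    if cur < hi:
        runs.append((cur, hi))
    return [r for r in runs if r[1] > r[0]]


def is_persistent_drug(
    supply_intervals,
    follow_up: tuple[int, int],
    gap_days: int = GAP_DAYS,
) -> bool:
    """True iff antipsychotic therapy started in follow-up runs uninterrupted.

    ``supply_intervals`` are covered-supply intervals (any substance; the
    union is evaluated, so switching substances is not an interruption).
    An interruption is an uncovered stretch of >= ``gap_days`` days between
    the first supply day and the end of follow-up, including a final
    uncovered stretch before the window end (treatment must be carried
    through the whole year).
    """
    fu_start, fu_end = int(follow_up[0]), int(follow_up[1])
    merged = merge_intervals(supply_intervals)
    starts = [a for a, b in merged if a < fu_end and b > fu_start]
    if not starts:
        return False
    first = max(min(starts), fu_start)
    for a, b in uncovered_runs(merged, (first, fu_end)):
        if b - a >= gap_days:
            return False
    return True


def is_persistent_community(
    covered_intervals,
    start: int,
    window_days: int = 365,
    gap_days: int = GAP_DAYS,
) -> bool:
    """True iff no uncovered run of >= ``gap_days`` days occurs in
    ``[start, start + window_days)``.

    ``covered_intervals`` are the patient's community-coverage intervals:
    CMHC/day-care contacts as 1-day intervals plus inpatient (GHPW/CRF) stay
    days, which count as continuity of care.
    """
    start = int(start)
    for a, b in uncovered_runs(covered_intervals, (start, start + window_days)):
        if b - a >= gap_days:
            return False
    return True


def polytherapy_days(segments_by_atc: dict, follow_up: tuple[int, int]) -> int:
    """Days within follow-up on which >= 2 distinct substances have active supply.

    ``segments_by_atc`` maps an ATC code (level-5 substance) to its covered
    supply intervals.
    """
    fu_start, fu_end = int(follow_up[0]), int(follow_up[1])
    events: list[tuple[int, int]] = []
    for atc, segs in segments_by_atc.items():
        for a, b in merge_intervals(segs):
            a, b = max(a, fu_start), min(b, fu_end)
            if b > a:
                events.append((a, 1))
                events.append((b, -1))
    if not events:
        return 0
    events.sort()
    days = 0
    depth = 0
    prev = None
    for pos, delta in events:
        if prev is not None and depth >= 2:
            days += pos - prev
        depth += delta
        prev = pos
    return days


def readmission_within(admission_days, discharge_days, k: int) -> np.ndarray:
    """Per admission: is there a subsequent admission starting 1..k days after
    its discharge? The statistical unit is the admission, not the patient.

    ``admission_days``/``discharge_days`` are one patient's admission start and
    discharge days (paired, any order). A same-day transfer (gap 0) does not
    count as a readmission.
    """
    adm = np.asarray(admission_days, dtype=int)
    dis = np.asarray(discharge_days, dtype=int)
    order = np.argsort(adm, kind="stable")
    adm_sorted = adm[order]
    out = np.zeros(len(adm), dtype=bool)
    for i, d in enumerate(dis):
        gaps = adm_sorted - d
        out[i] = bool(np.any((gaps >= 1) & (gaps <= k)))
    return out


def contact_within_after_discharge(contact_days, discharge_days, k: int = 14) -> np.ndarray:
    """Per discharge: is there a qualifying contact 1..k days after discharge?

    ``contact_days`` should already be filtered to the qualifying contact type
    (any CMHC professional, psychiatric visits only, or home care only).
    """
    c = np.sort(np.asarray(contact_days, dtype=int))
    out = np.zeros(len(np.atleast_1d(discharge_days)), dtype=bool)
    for i, d in enumerate(np.atleast_1d(discharge_days)):
        lo = np.searchsorted(c, d + 1, side="left")
        hi = np.searchsorted(c, d + k, side="right")
        out[i] = hi > lo
    return out
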