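"""Independent day-grid oracles for the temporal rules.

Every rule is re-derived here on explicit boolean day arrays (730+ days) with
plain loops — no interval arithmetic shared with the implementation — so the
episode engine can be checked against them on random patient histories.
"""

import math

import numpy as np

HORIZON = 1200


def covered_array(intervals, horizon: int = HORIZON) -> np.ndarray:
    arr = np.zeros(horizon, dtype=bool)
    for a, b in intervals:
        a, b = max(int(a), 0), min(int(b), horizon)
        if b > a:
            arr[a:b] = True
    return arr


def supply_days(days, amounts, ddd: float, horizon: int = HORIZON) -> np.ndarray:
    """Day-by-day replay of supply with stockpiling (append after current end)."""
    order = np.argsort(days, kind="stable")
    arr = np.zeros(horizon, dtype=bool)
    cur_end = 0
    for i in order:
        d = int(days[i])
        dur = math.ceil(float(amounts[i]) / ddd)
        start = max(d, cur_end)
        arr[max(start, 0):min(start + dur, horizon)] = True
        cur_end = start + dur
    return arr


def persistent_drug(arr: np.ndarray, fu_start: int, fu_end: int, gap: int = 90) -> bool:
    first = None
    for d in range(fu_start, fu_end):
        if arr[d]:
            first = d
            break
    # supply started before the window also counts if it reaches into it
    if first is not None:
        back = first
        while back > 0 and arr[back - 1]:
            back -= 1
        first = max(back, fu_start)
    if first is None:
        return False
    run = 0
    for d in range(first, fu_end):
        if arr[d]:
            run = 0
        else:
            run += 1
            if run >= gap:
                return False
    return True


def persistent_community(arr: np.ndarray, start: int, window: int = 365, gap: int = 90) -> bool:
    run = 0
    for d in range(start, start + window):
        if d < len(arr) and arr[d]:
            run = 0
        else:
            run += 1
            if run >= gap:
                return False
    return True


def polytherapy_days(arrays: list[np.ndarray], fu_start: int, fu_end: int) -> int:
    total = 0
    for d in range(fu_start, fu_end):
        if sum(1 for a in arrays if a[d]) >= 2:
            total += 1
    return total


def readmission_within(adm, dis, k: int) -> list[bool]:
    out = []
    for i in range(len(adm)):
        hit = False
        for j in range(len(adm)):
            if 1 <= adm[j] - dis[i] <= k:
                hit = True
        out.append(hit)
    return out


def contact_within(contact_days, discharge_days, k: int) -> list[bool]:
    out = []
    for d in discharge_days:
        out.append(any(1 <= c - d <= k for c in contact_days))
    return out
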