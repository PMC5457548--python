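"""Independent brute-force oracles for interval algebra and index selection.

Everything here works on explicit 365-slot boolean day arrays or
exhaustive scans, deliberately sharing no code with the implementation.
"""

from __future__ import annotations

import numpy as np


def day_array(fills: list[tuple[int, int]], window: tuple[int, int]) -> np.ndarray:
    """Boolean coverage array over the closed window from (day, supply) fills."""
    w0, w1 = window
    arr = np.zeros(w1 - w0 + 1, dtype=bool)
    for day, supply in fills:
        for d in range(day, day + supply):
            if w0 <= d <= w1:
                arr[d - w0] = True
    return arr


def oracle_pdc(fills, window) -> float:
    arr = day_array(fills, window)
    return arr.sum() / len(arr)


def _uncovered_runs(arr: np.ndarray) -> list[tuple[int, int, bool]]:
    """(start, length, reaches_end) for each maximal uncovered run."""
    runs = []
    i = 0
    n = len(arr)
    while i < n:
        if not arr[i]:
            j = i
            while j < n and not arr[j]:
                j += 1
            runs.append((i, j - i, j == n))
            i = j
        else:
            i += 1
    return runs


def oracle_persistence(fills, window, threshold: int, count_terminal_gap: bool) -> bool:
    """No uncovered run of >= threshold days after the first covered day."""
    arr = day_array(fills, window)
    covered = np.flatnonzero(arr)
    if len(covered) == 0:
        return not (count_terminal_gap and len(arr) >= threshold)
    first = covered[0]
    for start, length, at_end in _uncovered_runs(arr):
        if start < first:
            continue  # leading gap: therapy not yet started
        if at_end and not count_terminal_gap:
            continue
        if length >= threshold:
            return False
    return True


def oracle_continuous_exposure(fills, index_day, window, gap=90, anchor="supply_end"):
    """Brute-force successor scan of the refill chain."""
    fills = sorted((d, s) for d, s in fills if window[0] <= d <= window[1])
    if not fills:
        return 0, 0
    n = len(fills)
    end = None
    for i, (d, s) in enumerate(fills):
        supply_end = d + s - 1
        ref = supply_end if anchor == "supply_end" else d
        if i + 1 == n or fills[i + 1][0] - ref > gap:
            end = supply_end
            break
    end = min(end, window[1])
    return end - index_day + 1, n


def bridge_array(arr: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill interior uncovered runs of length <= max_gap."""
    out = arr.copy()
    covered = np.flatnonzero(arr)
    if len(covered) == 0:
        return out
    first, last = covered[0], covered[-1]
    for start, length, _ in _uncovered_runs(arr):
        if start > first and start + length - 1 < last + 1 and length <= max_gap:
            if start + length <= last:  # interior run only
                out[start : start + length] = True
    return out


def longest_true_run(arr: np.ndarray) -> int:
    best = cur = 0
    for v in arr:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def oracle_polypharmacy(
    agents: list[tuple[str, str, list[tuple[int, int]]]],
    window,
    ap_classes,
    psych_classes,
    mode: str,
    min_overlap: int = 60,
    bridge_gap: int = 7,
) -> bool:
    arrays = [
        (code, cls, bridge_array(day_array(fills, window), bridge_gap))
        for code, cls, fills in agents
    ]
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            ci, cli, ai = arrays[i]
            cj, clj, aj = arrays[j]
            if ci == cj:
                continue
            if mode == "AP-AP":
                ok = cli in ap_classes and clj in ap_classes
            else:
                ok = (cli in ap_classes and clj in psych_classes) or (
                    clj in ap_classes and cli in psych_classes
                )
            if ok and longest_true_run(ai & aj) >= min_overlap:
                return True
    return False


def oracle_index_day(claim_days: list[int], accrual_day: int, window=90, washout=365):
    """Exhaustive scan over all candidate days for one (patient, agent)."""
    days = sorted(claim_days)
    for d in days:
        if d < accrual_day:
            continue
        if any(d - washout <= c <= d - 1 for c in days):
            continue
        if sum(1 for c in days if d <= c <= d + window) >= 2:
            return d
    return None
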