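"""Breath-by-breath segmentation by flow reversal.

A raw sign change at zero flow would fragment cycles at sensor-noise level,
so reversals are detected with a Schmitt trigger: a phase change is declared
only when flow crosses beyond +/-deadband and the new direction persists for
at least ``min_phase_ms``.  Accepted boundaries are then moved back from the
deadband crossing to the flow zero crossing, estimated by a short local
linear fit, so phase durations are unbiased by the deadband and robust to
single-sample noise flips.

Convention: positive flow = expiration, so a cycle is an inspiration run
(negative flow) followed by an expiration run (positive flow).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .signal_io import SampleSeries

INSP_SIGN = -1  # inspiration is negative flow under the default convention
EXP_SIGN = 1


@dataclass(frozen=True)
class BreathCycle:
    """Index triple delimiting one respiratory cycle.

    ``i_start`` is the first inspiration sample, ``i_rev`` the first
    expiration sample (the inspiration->expiration reversal) and ``i_end``
    the last expiration sample; all inclusive.  For complete cycles
    ``i_start < i_rev <= i_end``.  Incomplete (partial) cycles use sentinels:
    a leading expiration-only partial has ``i_rev == i_start``; a trailing
    inspiration-only partial has ``i_rev == i_end + 1``.
    """

    i_start: int
    i_rev: int
    i_end: int
    complete: bool

    @property
    def has_inspiration(self) -> bool:
        return self.i_rev > self.i_start

    @property
    def has_expiration(self) -> bool:
        return self.i_rev <= self.i_end

    @property
    def n_samples(self) -> int:
        return self.i_end - self.i_start + 1

    def insp_slice(self) -> slice:
        return slice(self.i_start, self.i_rev)

    def exp_slice(self) -> slice:
        return slice(self.i_rev, self.i_end + 1)


def _hysteresis_state(
    flow: np.ndarray, deadband: float, apnea_samples: int
) -> np.ndarray:
    """Per-sample phase state: +1 expiration, -1 inspiration, 0 unassigned.

    Sub-deadband samples inherit the previous state (hysteresis) except when
    a sub-deadband run exceeds ``apnea_samples``, in which case the whole run
    is left unassigned and the state machine resets.
    """
    raw = np.zeros(len(flow), dtype=np.int8)
    raw[flow > deadband] = EXP_SIGN
    raw[flow < -deadband] = INSP_SIGN

    state = np.zeros(len(flow), dtype=np.int8)
    cur = 0
    zero_run_start = None
    for i, s in enumerate(raw):
        if s != 0:
            cur = s
            zero_run_start = None
            state[i] = cur
        else:
            if zero_run_start is None:
                zero_run_start = i
            if i - zero_run_start + 1 > apnea_samples:
                # apneic gap: retroactively unassign the run and reset
                state[zero_run_start : i + 1] = 0
                cur = 0
            else:
                state[i] = cur
    return state


def _runs(state: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (start, end_inclusive, sign) runs of the state vector."""
    runs = []
    start = 0
    for i in range(1, len(state) + 1):
        if i == len(state) or state[i] != state[start]:
            runs.append((start, i - 1, int(state[start])))
            start = i
    return runs


def _debounce(runs: list[tuple[int, int, int]], min_samples: int):
    """Merge non-zero runs shorter than ``min_samples`` into their
    predecessor's sign; a short run with no signed predecessor is noise and
    is unassigned.  Repeat until stable."""
    changed = True
    while changed:
        changed = False
        out: list[tuple[int, int, int]] = []
        for run in runs:
            s, e, sign = run
            if sign != 0 and (e - s + 1) < min_samples:
                if out and out[-1][2] != 0:
                    ps, _, psign = out[-1]
                    out[-1] = (ps, e, psign)
                else:
                    run = (s, e, 0)
                    if out and out[-1][2] == 0:
                        ps, _, _ = out[-1]
                        out[-1] = (ps, e, 0)
                    else:
                        out.append(run)
                changed = True
                continue
            if out and out[-1][2] == sign:
                ps, _, psign = out[-1]
                out[-1] = (ps, e, psign)
                changed = True
            else:
                out.append(run)
        runs = out
    return runs


def _refine_boundaries(
    runs: list[tuple[int, int, int]],
    flow: np.ndarray,
    deadband: float,
    halfwin: int = 5,
):
    """Move each accepted transition from the deadband crossing back to the
    flow zero crossing.

    The crossing is estimated by a least-squares line through the flow
    samples around the transition (up to ``halfwin`` on each side), which
    averages out sensor noise instead of trusting single sign flips.  The new
    boundary is the first sample strictly after the fitted zero, so a sample
    sitting exactly on the crossing stays with the phase being exited.  Two
    guards keep the refinement inside the Schmitt trigger's verdict: samples
    opposing the new phase beyond twice the deadband are never handed to it,
    and samples supporting it beyond twice the deadband are never kept back.
    """
    runs = [list(r) for r in runs]
    for k in range(1, len(runs)):
        prev, cur = runs[k - 1], runs[k]
        if cur[2] == 0 or prev[2] == cur[2]:
            continue
        sign = cur[2]
        b = cur[0]
        # into an unassigned run the whole stretch may be reclaimed; a signed
        # predecessor must keep at least one sample
        floor = prev[0] if prev[2] == 0 else prev[0] + 1
        lo = max(b - halfwin, prev[0])
        hi = min(b + halfwin - 1, cur[1])
        nb = b
        supports_new = flow[lo : hi + 1] * sign > 0  # exact zeros side with old
        if np.all(np.diff(supports_new.astype(np.int8)) >= 0):
            # clean monotone old->new pattern: the bracket is unambiguous
            if supports_new.any():
                nb = lo + int(np.argmax(supports_new))
        else:
            # noise flips present: least-squares zero crossing of the window
            x = np.arange(lo, hi + 1, dtype=np.float64)
            if len(x) >= 3:
                xc = x - x.mean()
                y = flow[lo : hi + 1]
                m = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
                if m * sign > 1e-12:
                    z = x.mean() - (y.mean() / m)
                    if abs(z - b) <= 2 * halfwin:
                        nb = int(np.floor(z)) + 1
        nb = max(floor, min(nb, cur[1]))
        while nb < cur[1] and flow[nb] * sign < -2 * deadband:
            nb += 1
        while nb - 1 >= floor and flow[nb - 1] * sign > 2 * deadband:
            nb -= 1
        if nb != cur[0]:
            cur[0] = nb
            prev[1] = nb - 1
    return [tuple(r) for r in runs if r[1] >= r[0]]


def segment(
    series: SampleSeries,
    deadband: float = 0.5,
    min_phase_ms: float = 150.0,
    apnea_ms: float = 2000.0,
) -> list[BreathCycle]:
    """Partition a record into respiratory cycles.

    Returns maximal non-overlapping cycles in time order.  Leading/trailing
    partial phases are returned with ``complete=False``; records with no
    supra-deadband flow yield an empty list.
    """
    if deadband < 0:
        raise ContractError(f"deadband must be >= 0, got {deadband}")
    if min_phase_ms < series.dt_ms:
        raise ContractError(
            f"min_phase_ms ({min_phase_ms}) must be >= dt_ms ({series.dt_ms})"
        )
    min_samples = max(1, math.ceil(min_phase_ms / series.dt_ms))
    apnea_samples = max(1, math.ceil(apnea_ms / series.dt_ms))

    state = _hysteresis_state(series.flow, deadband, apnea_samples)
    if not np.any(state):
        return []
    runs = [r for r in _runs(state)]
    runs = _debounce(runs, min_samples)
    runs = _refine_boundaries(runs, series.flow, deadband)

    signed = [(s, e, sign) for (s, e, sign) in runs if sign != 0]
    cycles: list[BreathCycle] = []
    k = 0
    while k < len(signed):
        s, e, sign = signed[k]
        if sign == INSP_SIGN:
            paired = (
                k + 1 < len(signed)
                and signed[k + 1][2] == EXP_SIGN
                and signed[k + 1][0] == e + 1  # contiguous, no gap between
            )
            if paired:
                es, ee, _ = signed[k + 1]
                long_enough = (e - s + 1) >= min_samples and (ee - es + 1) >= min_samples
                cycles.append(
                    BreathCycle(i_start=s, i_rev=es, i_end=ee, complete=long_enough)
                )
                k += 2
            else:
                # inspiration with no expiration following (record end / gap)
                cycles.append(BreathCycle(i_start=s, i_rev=e + 1, i_end=e, complete=False))
                k += 1
        else:
            # expiration with no inspiration before it (record start / gap)
            cycles.append(BreathCycle(i_start=s, i_rev=s, i_end=e, complete=False))
            k += 1
    return cycles


def phase_times(cycle: BreathCycle, series: SampleSeries) -> tuple[float, float]:
    """(Ti, Te) in seconds: time difference between the last and first sample
    of each phase.  Missing phases of partial cycles yield ``nan``.
    """
    if cycle.i_end >= len(series) or cycle.i_start < 0:
        raise ContractError(
            f"cycle {cycle.i_start}..{cycle.i_end} outside record of {len(series)}"
        )
    t = series.t
    if cycle.has_inspiration:
        ti = (t[cycle.i_rev - 1] - t[cycle.i_start]) / 1000.0
    else:
        ti = float("nan")
    if cycle.has_expiration:
        te = (t[cycle.i_end] - t[cycle.i_rev]) / 1000.0
    else:
        te = float("nan")
    return float(ti), float(te)


def assigned_sample_count(cycles: list[BreathCycle]) -> int:
    """Total samples covered by the cycles (complete and partial)."""
    return sum(c.n_samples for c in cycles)
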