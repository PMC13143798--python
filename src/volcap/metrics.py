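"""Per-cycle ventilatory parameters: Ti, Te, Vi, Ve, ETCO2, PEF and the
CO2 volume eliminated per breath.

All integrals use the left rectangular rule at the record's own sampling
interval, mirroring the fixed-step integration of the acquisition firmware.
Flow in L/min converts to mL/ms through the factor 1/60.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .segmentation import BreathCycle, phase_times
from .signal_io import SampleSeries

#: L/min -> mL/ms
_LPM_TO_ML_PER_MS = 1.0 / 60.0


@dataclass(frozen=True)
class BreathMetrics:
    """Derived quantities for one respiratory cycle."""

    i_start: int
    i_rev: int
    i_end: int
    complete: bool
    ti_s: float
    te_s: float
    vi_ml: float
    ve_ml: float
    etco2_mmhg: float
    pef_lpm: float
    vco2_ml: float
    patm_mmhg: float


def integrate_volume(
    series: SampleSeries,
    from_idx: int,
    to_idx: int,
    phase_sign: int | None = None,
    sign_tol_lpm: float = 0.5,
) -> float:
    """Volume in mL over the inclusive index span: sum |flow| * dt.

    If ``phase_sign`` (+1 expiration / -1 inspiration) is given, the span is
    checked not to cross a phase boundary: any sample whose flow exceeds
    ``sign_tol_lpm`` in the opposite direction raises :class:`ContractError`.
    """
    if not (0 <= from_idx <= to_idx < len(series)):
        raise ContractError(f"invalid span {from_idx}..{to_idx} for n={len(series)}")
    f = series.flow[from_idx : to_idx + 1]
    if phase_sign is not None:
        opposite = f * phase_sign < -sign_tol_lpm
        if np.any(opposite):
            i = from_idx + int(np.argmax(opposite))
            raise ContractError(
                f"span {from_idx}..{to_idx} crosses a phase boundary at index {i} "
                f"(flow {series.flow[i]:.3f} L/min against phase sign {phase_sign:+d})"
            )
    return float(np.sum(np.abs(f)) * series.dt_ms * _LPM_TO_ML_PER_MS)


def vco2_per_breath(series: SampleSeries, cycle: BreathCycle, patm: float = 760.0) -> float:
    """CO2 volume (mL, at measurement conditions) eliminated in one cycle:
    rectangular-rule sum of flow(t) * pco2(t) / patm * dt over the full cycle.

    Inspiratory terms enter with their (negative) sign; with inspired PCO2
    near zero they are negligible.
    """
    if patm <= 0:
        raise ConfigError(f"patm must be positive, got {patm}")
    sl = slice(cycle.i_start, cycle.i_end + 1)
    f = series.flow[sl]
    p = series.pco2[sl]
    return float(
        np.sum(f * p) / patm * series.dt_ms * _LPM_TO_ML_PER_MS
    )


def _cumulative_expired_ml(series: SampleSeries, cycle: BreathCycle) -> np.ndarray:
    f = series.flow[cycle.exp_slice()]
    return np.cumsum(f) * series.dt_ms * _LPM_TO_ML_PER_MS


def end_tidal_co2(series: SampleSeries, cycle: BreathCycle) -> float:
    """PCO2 at the sample where cumulative expired volume is maximal
    (end of exhalation); ties break to the earliest maximal sample."""
    if not cycle.has_expiration:
        raise ContractError("cycle has no expiration phase")
    cum = _cumulative_expired_ml(series, cycle)
    i = int(np.argmax(cum))  # argmax returns the first maximal index
    return float(series.pco2[cycle.i_rev + i])


def peak_expiratory_flow(series: SampleSeries, cycle: BreathCycle) -> float:
    """Maximum |flow| in L/min over the expiratory span."""
    if not cycle.has_expiration:
        raise ContractError("cycle has no expiration phase")
    return float(np.max(np.abs(series.flow[cycle.exp_slice()])))


def metrics_for_cycle(
    series: SampleSeries, cycle: BreathCycle, patm: float = 760.0
) -> BreathMetrics:
    ti, te = phase_times(cycle, series)
    if cycle.complete:
        vi = integrate_volume(series, cycle.i_start, cycle.i_rev - 1)
        ve = integrate_volume(series, cycle.i_rev, cycle.i_end)
        et = end_tidal_co2(series, cycle)
        pef = peak_expiratory_flow(series, cycle)
        vco2 = vco2_per_breath(series, cycle, patm)
    else:
        vi = ve = et = pef = vco2 = float("nan")
    return BreathMetrics(
        i_start=cycle.i_start,
        i_rev=cycle.i_rev,
        i_end=cycle.i_end,
        complete=cycle.complete,
        ti_s=ti,
        te_s=te,
        vi_ml=vi,
        ve_ml=ve,
        etco2_mmhg=et,
        pef_lpm=pef,
        vco2_ml=vco2,
        patm_mmhg=patm,
    )


def metrics_for_record(
    series: SampleSeries, cycles: list[BreathCycle], patm: float = 760.0
) -> pd.DataFrame:
    """One row per cycle; incomplete or failing cycles are flagged
    (``complete=False``, NaN metrics) rather than aborting the batch."""
    rows = []
    for cycle in cycles:
        try:
            m = metrics_for_cycle(series, cycle, patm)
        except Exception:
            ti, te = phase_times(cycle, series)
            m = BreathMetrics(
                cycle.i_start, cycle.i_rev, cycle.i_end, False,
                ti, te, *([float("nan")] * 5), patm,
            )
        rows.append(asdict(m))
    return pd.DataFrame(rows, columns=list(BreathMetrics.__dataclass_fields__))
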