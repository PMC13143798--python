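"""Volumetric capnogram construction and phase-slope fitting.

A volumetric capnogram plots PCO2 against cumulative expired volume for one
expiration.  Phase III (the alveolar near-plateau) is fitted by ordinary
least squares on the 40-80% expired-volume window by default; the phase II
steep-region fit uses a gradient-based window convention that is this
toolkit's own (marked experimental in CLI output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    ContractError,
    FitError,
    InsufficientDataError,
    InsufficientGradientError,
    InsufficientWindowError,
)
from .segmentation import BreathCycle
from .signal_io import SampleSeries

_LPM_TO_ML_PER_MS = 1.0 / 60.0


@dataclass(frozen=True)
class VolumetricCapnogram:
    """Cumulative expired volume (mL) and PCO2 (mmHg), one point per
    expiratory sample.  ``n_clamped`` counts mid-expiration samples with
    negative flow whose volume increment was clamped to zero."""

    v_ml: np.ndarray
    pco2_mmhg: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.v_ml, dtype=np.float64)
        p = np.asarray(self.pco2_mmhg, dtype=np.float64)
        object.__setattr__(self, "v_ml", v)
        object.__setattr__(self, "pco2_mmhg", p)
        if len(v) != len(p) or len(v) < 3:
            raise ContractError(
                f"capnogram needs >= 3 paired samples, got v={len(v)} p={len(p)}"
            )
        if v[0] < 0 or np.any(np.diff(v) < 0):
            raise ContractError("v_ml must be non-negative and non-decreasing")

    @property
    def vt_ml(self) -> float:
        """Total expired volume (the curve's final/maximal value)."""
        return float(self.v_ml[-1])


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of PCO2 vs expired volume over a volume window."""

    slope_mmhg_per_l: float
    intercept_mmhg: float
    r2: float
    lo_frac: float
    hi_frac: float
    n_points: int
    normalized_slope: float


def build_capnogram(series: SampleSeries, cycle: BreathCycle) -> VolumetricCapnogram:
    """Cumulative rectangular integration of expiratory flow, paired with the
    PCO2 samples.  Negative-flow samples inside the expiration contribute a
    zero increment (monotonicity by construction) and are counted."""
    if not cycle.has_expiration:
        raise ContractError("cycle has no expiration phase")
    f = series.flow[cycle.exp_slice()]
    p = series.pco2[cycle.exp_slice()]
    if len(f) < 3:
        raise ContractError(f"expiration of {len(f)} samples is too short (< 3)")
    inc = np.clip(f, 0.0, None) * series.dt_ms * _LPM_TO_ML_PER_MS
    n_clamped = int(np.sum(f < 0))
    return VolumetricCapnogram(
        v_ml=np.cumsum(inc), pco2_mmhg=p.copy(), n_clamped=n_clamped
    )


def _ols(v_l: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    """Slope (mmHg/L), intercept (mmHg) and r2; r2 of a zero-variance
    response is 0 by convention (with a warning), never NaN."""
    vbar = v_l.mean()
    pbar = p.mean()
    sxx = float(np.sum((v_l - vbar) ** 2))
    if sxx == 0.0:
        raise FitError("zero variance in expired volume over the fit window")
    sxy = float(np.sum((v_l - vbar) * (p - pbar)))
    slope = sxy / sxx
    intercept = pbar - slope * vbar
    sst = float(np.sum((p - pbar) ** 2))
    if sst == 0.0:
        warnings.warn("zero-variance PCO2 in fit window; r2 set to 0", stacklevel=3)
        return slope, intercept, 0.0
    ssr = float(np.sum((p - (intercept + slope * v_l)) ** 2))
    return slope, intercept, 1.0 - ssr / sst


def fit_slope3(
    cap: VolumetricCapnogram, lo_frac: float = 0.40, hi_frac: float = 0.80
) -> SlopeFit:
    """Phase III slope: OLS of PCO2 on expired volume over samples whose
    volume lies in ``[lo_frac*VT, hi_frac*VT]`` (inclusive bounds; the sample
    straddling a bound is included iff its own volume is within bounds)."""
    if not (0.0 < lo_frac < hi_frac < 1.0):
        raise ContractError(f"window fractions must satisfy 0<lo<hi<1, got {lo_frac},{hi_frac}")
    vt = cap.vt_ml
    mask = (cap.v_ml >= lo_frac * vt) & (cap.v_ml <= hi_frac * vt)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientWindowError(
            f"only {n} samples in the {lo_frac:.2f}-{hi_frac:.2f} volume window",
            n_points=n,
        )
    v_l = cap.v_ml[mask] / 1000.0
    p = cap.pco2_mmhg[mask]
    slope, intercept, r2 = _ols(v_l, p)
    pbar = float(p.mean())
    normalized = slope * (vt / 1000.0) / pbar if pbar != 0 else float("nan")
    return SlopeFit(
        slope_mmhg_per_l=slope,
        intercept_mmhg=intercept,
        r2=r2,
        lo_frac=lo_frac,
        hi_frac=hi_frac,
        n_points=n,
        normalized_slope=normalized,
    )


def fit_slope2(
    cap: VolumetricCapnogram, rel_gradient: float = 0.7, min_gradient: float = 1e-6
) -> SlopeFit:
    """Phase II slope (experimental convention, not from the source method):
    OLS on the contiguous window centered on the steepest 3-sample
    central-difference gradient of PCO2 vs volume, expanded on both sides
    while the local gradient stays >= ``rel_gradient`` of the peak (0.7 by
    default: wide enough for a stable OLS fit, tight enough that the fitted
    slope tracks the maximal gradient)."""
    # collapse zero-increment samples so central differences are well defined
    keep = np.concatenate(([True], np.diff(cap.v_ml) > 0))
    v = cap.v_ml[keep] / 1000.0
    p = cap.pco2_mmhg[keep]
    if len(v) < 3:
        raise InsufficientGradientError("too few distinct-volume samples")
    grad = np.gradient(p, v)
    peak = int(np.argmax(grad))
    if grad[peak] <= min_gradient:
        raise InsufficientGradientError(
            f"max gradient {grad[peak]:.3g} mmHg/L below threshold {min_gradient:.3g}"
        )
    lo = peak
    while lo - 1 >= 0 and grad[lo - 1] >= rel_gradient * grad[peak]:
        lo -= 1
    hi = peak
    while hi + 1 < len(v) and grad[hi + 1] >= rel_gradient * grad[peak]:
        hi += 1
    if hi - lo + 1 < 3:
        lo = max(0, lo - 1)
        hi = min(len(v) - 1, hi + 1)
    slope, intercept, r2 = _ols(v[lo : hi + 1], p[lo : hi + 1])
    vt_l = cap.vt_ml / 1000.0
    pbar = float(p[lo : hi + 1].mean())
    return SlopeFit(
        slope_mmhg_per_l=slope,
        intercept_mmhg=intercept,
        r2=r2,
        lo_frac=float(v[lo] / vt_l) if vt_l > 0 else float("nan"),
        hi_frac=float(v[hi] / vt_l) if vt_l > 0 else float("nan"),
        n_points=hi - lo + 1,
        normalized_slope=slope * vt_l / pbar if pbar != 0 else float("nan"),
    )


def slope3_variability(fits) -> dict[str, float]:
    """Across-cycle summary of phase III slopes: mean, sample SD (ddof=1)
    and coefficient of variation in percent."""
    slopes = np.asarray(
        [f.slope_mmhg_per_l if isinstance(f, SlopeFit) else float(f) for f in fits],
        dtype=np.float64,
    )
    if len(slopes) < 2:
        raise InsufficientDataError(
            f"variability needs >= 2 slope fits, got {len(slopes)}"
        )
    mean = float(slopes.mean())
    sd = float(slopes.std(ddof=1))
    cv_pct = float("inf") if mean == 0 else abs(sd / mean) * 100.0
    return {"mean": mean, "sd": sd, "cv_pct": cv_pct, "n": int(len(slopes))}
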