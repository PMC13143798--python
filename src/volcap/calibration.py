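"""Static-bench sensor calibration: linear fit with R², a Fisher-z 95% CI
on R², and the standard OLS 95% prediction band.

The fit orientation is fixed as measured-on-reference (R² is orientation
invariant but the gain is not).  The flow channel's canonical slope
correction factor is 1.438.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ContractError, FitError

#: Canonical multiplicative slope correction applied to the flow channel
#: in the device firmware.
FLOW_CORRECTION_FACTOR = 1.438

#: Bench set points: flow 0-45 L/min in steps of 5, both directions,
#: 5 repetitions each (100 measurements total).
FLOW_LEVELS_LPM = tuple(range(0, 50, 5))
FLOW_REPS = 5

#: Bench set points: 11 CO2 pressures to 100 mmHg, at 5 carrier flows,
#: 3 repetitions each (165 measurements total).
CO2_LEVELS_MMHG = (0, 5, 10, 20, 30, 40, 50, 60, 70, 80, 100)
CO2_CARRIER_FLOWS_LPM = (5, 10, 15, 20, 30)
CO2_REPS = 3


@dataclass(frozen=True)
class StaticTestDesign:
    """Reference set points and the values measured against them.

    ``meta`` carries per-row design labels (direction for flow benches,
    carrier flow for CO2 benches)."""

    reference: np.ndarray
    measured: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=np.float64)
        mea = np.asarray(self.measured, dtype=np.float64)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "measured", mea)
        if len(ref) != len(mea):
            raise ContractError("reference and measured lengths differ")
        if len(ref) < 3:
            raise ContractError("a calibration design needs >= 3 measurements")

    def __len__(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear sensor model measured = gain*reference + offset."""

    gain: float
    offset: float
    r2: float
    ci95_r2: tuple[float, float]
    se_gain: float
    residual_sd: float
    n: int
    x_mean: float
    sxx: float
    correction_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.correction_factor <= 0:
            raise ContractError(
                f"correction_factor must be positive, got {self.correction_factor}"
            )

    def prediction_halfwidth(self, x, level: float = 0.95) -> np.ndarray:
        """Half-width of the prediction interval for a single new observation
        at reference value(s) x (minimal at the design mean)."""
        x = np.asarray(x, dtype=np.float64)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return tcrit * self.residual_sd * np.sqrt(
            1.0 + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )

    def confidence_halfwidth(self, x, level: float = 0.95) -> np.ndarray:
        """Half-width of the confidence interval for the fitted mean at x."""
        x = np.asarray(x, dtype=np.float64)
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.n - 2)
        return tcrit * self.residual_sd * np.sqrt(
            1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )


def _r2_ci_fisher(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    # Fisher z on the correlation, then square; degenerate |r|=1 or tiny n
    # collapses the interval onto r^2.
    if n <= 3 or abs(r) >= 1.0:
        return (r * r, r * r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    r_lo, r_hi = np.tanh(z - half), np.tanh(z + half)
    lo, hi = sorted((float(r_lo) ** 2, float(r_hi) ** 2))
    if r_lo < 0 < r_hi:  # interval straddles zero correlation
        lo = 0.0
    return (lo, hi)


def fit_linear_calibration(
    design: StaticTestDesign, correction_factor: float = 1.0
) -> CalibrationModel:
    """OLS of measured on reference with interval estimates.

    Raises :class:`FitError` if all reference levels coincide.
    """
    x = design.reference
    y = design.measured
    if np.ptp(x) == 0:
        raise FitError("all reference levels identical: rank-deficient design")
    n = len(x)
    res = stats.linregress(x, y)
    xbar = float(x.mean())
    sxx = float(np.sum((x - xbar) ** 2))
    resid = y - (res.intercept + res.slope * x)
    dof = n - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CalibrationModel(
        gain=float(res.slope),
        offset=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        ci95_r2=_r2_ci_fisher(float(res.rvalue), n),
        se_gain=float(res.stderr),
        residual_sd=residual_sd,
        n=n,
        x_mean=xbar,
        sxx=sxx,
        correction_factor=correction_factor,
    )


def apply_calibration(model: CalibrationModel, raw) -> np.ndarray:
    """corrected = correction_factor * (gain * raw + offset).

    With an identity fit and the canonical flow factor this reproduces the
    firmware's slope correction (raw 10.0 -> 14.38)."""
    raw = np.asarray(raw, dtype=np.float64)
    return model.correction_factor * (model.gain * raw + model.offset)


def identity_model(correction_factor: float = 1.0) -> CalibrationModel:
    """A pass-through model carrying only a slope correction factor."""
    return CalibrationModel(
        gain=1.0, offset=0.0, r2=1.0, ci95_r2=(1.0, 1.0), se_gain=0.0,
        residual_sd=0.0, n=2, x_mean=0.0, sxx=1.0,
        correction_factor=correction_factor,
    )


def flow_design_levels() -> np.ndarray:
    """Signed reference grid of the flow bench: 10 levels x 2 directions x
    5 reps = 100 points (expiratory positive, inspiratory negative)."""
    levels = []
    for direction in (1, -1):
        for lv in FLOW_LEVELS_LPM:
            levels.extend([direction * lv] * FLOW_REPS)
    return np.asarray(levels, dtype=np.float64)


def co2_design_levels() -> tuple[np.ndarray, np.ndarray]:
    """(reference PCO2, carrier flow) grids of the CO2 bench:
    11 levels x 5 flows x 3 reps = 165 points."""
    ref, flows = [], []
    for q in CO2_CARRIER_FLOWS_LPM:
        for lv in CO2_LEVELS_MMHG:
            ref.extend([lv] * CO2_REPS)
            flows.extend([q] * CO2_REPS)
    return np.asarray(ref, dtype=np.float64), np.asarray(flows, dtype=np.float64)


def emulate_static_bench(
    true_gain: float,
    noise_sd: float,
    design: str = "flow",
    seed: int | np.random.Generator = 0,
    true_offset: float = 0.0,
) -> StaticTestDesign:
    """Synthetic bench run: measured = true_gain*level + true_offset + noise.

    ``design`` selects the reference grid: ``"flow"`` (100 points) or
    ``"co2"`` (165 points).  Fully reproducible for a given seed.
    """
    if noise_sd < 0:
        raise ContractError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if design == "flow":
        ref = flow_design_levels()
        meta = {"design": "flow"}
    elif design == "co2":
        ref, flows = co2_design_levels()
        meta = {"design": "co2", "carrier_flow_lpm": flows}
    else:
        raise ContractError(f"unknown design {design!r} (expected 'flow' or 'co2')")
    measured = true_gain * ref + true_offset + rng.normal(0.0, noise_sd, size=len(ref))
    return StaticTestDesign(reference=ref, measured=measured, meta=meta)
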