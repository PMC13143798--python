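"""Seeded spontaneous-breathing simulator with per-breath ground truth.

Each breath uses half-sine flow profiles (closed-form volume scaling) and a
single-breath CO2 morphology: a sigmoid upstroke (phase II) joining a phase
III that is linear in *expired volume*, whose endpoint is the breath's
end-tidal value.  Cycle-to-cycle variability is drawn per breath from a
seeded generator, and every drawn parameter is recorded, making the output
usable as an oracle for segmentation, metrics, and capnogram fitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .signal_io import SampleSeries

#: Expired-volume fraction where phase II hands over to the linear phase III.
#: Kept below 0.40 so the default slope III window is purely linear.
KNEE_FRAC = 0.30

#: Time constant (s) of the inspiratory CO2 washout toward 0 mmHg.
INSP_DECAY_TAU_S = 0.08


@dataclass
class SimConfig:
    """Parameters of the simulated breathing pattern.

    CVs are coefficients of variation of the per-breath draws; a fixed seed
    makes the full output bit-for-bit reproducible.  With
    ``snap_times_to_grid`` (default) drawn phase durations are rounded to the
    sampling grid so duration ground truth is exactly representable; switch
    times themselves stay continuous via a sub-sample record start offset.
    """

    n_breaths: int = 20
    vt_ml_mean: float = 500.0
    vt_cv: float = 0.10
    ti_s_mean: float = 1.8
    te_s_mean: float = 2.4
    time_cv: float = 0.05
    etco2_mmhg_mean: float = 34.9
    etco2_sd: float = 0.8
    slope3_mmhg_per_l_mean: float = 10.0
    slope3_cv: float = 0.10
    phase2_sharpness: float = 25.0
    noise_flow_sd_lpm: float = 0.0
    noise_pco2_sd_mmhg: float = 0.0
    dt_ms: int = 10
    seed: int = 0
    snap_times_to_grid: bool = True
    start_offset_ms: float | None = None

    def __post_init__(self) -> None:
        if self.n_breaths < 1:
            raise ConfigError(f"n_breaths must be >= 1, got {self.n_breaths}")
        for name in (
            "vt_ml_mean", "ti_s_mean", "te_s_mean", "etco2_mmhg_mean",
            "slope3_mmhg_per_l_mean", "phase2_sharpness",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("vt_cv", "time_cv", "slope3_cv", "etco2_sd",
                     "noise_flow_sd_lpm", "noise_pco2_sd_mmhg"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.dt_ms <= 0:
            raise ConfigError("dt_ms must be positive")
        dt_s = self.dt_ms / 1000.0
        if self.ti_s_mean < 3 * dt_s or self.te_s_mean < 3 * dt_s:
            raise ConfigError("ti/te must be at least 3 sampling intervals")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BreathShape:
    """Analytic waveform of one breath (times relative to breath start, s).

    Flow is a half-sine per phase scaled so each phase moves ``vt_l`` liters;
    expiration is positive.  PCO2 is a function of expired-volume fraction.
    """

    ti_s: float
    te_s: float
    vt_l: float
    etco2_mmhg: float
    slope3_mmhg_per_l: float
    prev_etco2_mmhg: float = 0.0
    knee_frac: float = KNEE_FRAC
    phase2_sharpness: float = 25.0

    @property
    def duration_s(self) -> float:
        return self.ti_s + self.te_s

    @property
    def peak_insp_lpm(self) -> float:
        return 30.0 * np.pi * self.vt_l / self.ti_s

    @property
    def peak_exp_lpm(self) -> float:
        return 30.0 * np.pi * self.vt_l / self.te_s

    def flow_lpm(self, t_rel) -> np.ndarray:
        t = np.asarray(t_rel, dtype=np.float64)
        out = np.zeros_like(t)
        insp = (t >= 0) & (t < self.ti_s)
        out[insp] = -self.peak_insp_lpm * np.sin(np.pi * t[insp] / self.ti_s)
        ex = (t >= self.ti_s) & (t <= self.duration_s)
        out[ex] = self.peak_exp_lpm * np.sin(np.pi * (t[ex] - self.ti_s) / self.te_s)
        return out

    def v_exp_l(self, t_rel) -> np.ndarray:
        """Cumulative expired volume (L) at time t_rel (0 before reversal)."""
        t = np.asarray(t_rel, dtype=np.float64)
        te_rel = np.clip(t - self.ti_s, 0.0, self.te_s)
        return self.vt_l / 2.0 * (1.0 - np.cos(np.pi * te_rel / self.te_s))

    def pco2_of_volume(self, v_l) -> np.ndarray:
        """Single-breath CO2 curve vs expired volume: sigmoid phase II up to
        the knee, then linear phase III ending exactly at the end-tidal
        value."""
        v = np.asarray(v_l, dtype=np.float64)
        frac = np.clip(v / self.vt_l, 0.0, 1.0)
        p_knee = self.etco2_mmhg - self.slope3_mmhg_per_l * self.vt_l * (
            1.0 - self.knee_frac
        )
        if p_knee <= 0:
            raise ConfigError(
                "inconsistent breath parameters: phase III would start below 0 mmHg"
            )
        out = np.empty_like(frac)
        lin = frac >= self.knee_frac
        out[lin] = self.etco2_mmhg - self.slope3_mmhg_per_l * self.vt_l * (
            1.0 - frac[lin]
        )
        if np.any(~lin):
            k = self.phase2_sharpness
            fm = self.knee_frac / 2.0
            sig = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
            g0 = sig(-k * fm)
            g1 = sig(k * (self.knee_frac - fm))
            g = (sig(k * (frac[~lin] - fm)) - g0) / (g1 - g0)
            out[~lin] = p_knee * g
        return out

    def pco2_mmhg(self, t_rel) -> np.ndarray:
        t = np.asarray(t_rel, dtype=np.float64)
        out = np.empty_like(t)
        insp = t < self.ti_s
        out[insp] = self.prev_etco2_mmhg * np.exp(
            -np.clip(t[insp], 0.0, None) / INSP_DECAY_TAU_S
        )
        out[~insp] = self.pco2_of_volume(self.v_exp_l(t[~insp]))
        return out


TRUTH_COLUMNS = [
    "breath", "t_start_s", "t_rev_s", "t_end_s",
    "vt_ml", "ti_s", "te_s", "etco2_mmhg", "slope3_mmhg_per_l",
]


def _draw_positive(rng, mean: float, sd: float, n: int, floor_frac: float = 0.2):
    """Normal draws clipped below at floor_frac*mean (keeps physiology sane
    at large CVs)."""
    return np.clip(rng.normal(mean, sd, size=n), floor_frac * mean, None)


def simulate(config: SimConfig) -> tuple[SampleSeries, pd.DataFrame]:
    """Generate a record plus its per-breath ground-truth table.

    Returns ``(series, truth)``; ``truth`` has one row per breath with the
    drawn parameters and the continuous phase-switch times.
    """
    rng = np.random.default_rng(config.seed)
    dt_s = config.dt_ms / 1000.0
    n = config.n_breaths

    vt_ml = _draw_positive(rng, config.vt_ml_mean, config.vt_cv * config.vt_ml_mean, n)
    ti = _draw_positive(rng, config.ti_s_mean, config.time_cv * config.ti_s_mean, n)
    te = _draw_positive(rng, config.te_s_mean, config.time_cv * config.te_s_mean, n)
    if config.snap_times_to_grid:
        ti = np.maximum(np.round(ti / dt_s), 3) * dt_s
        te = np.maximum(np.round(te / dt_s), 3) * dt_s
    etco2 = np.clip(rng.normal(config.etco2_mmhg_mean, config.etco2_sd, size=n), 1.0, None)
    s3 = _draw_positive(
        rng, config.slope3_mmhg_per_l_mean,
        config.slope3_cv * config.slope3_mmhg_per_l_mean, n, floor_frac=0.05,
    )

    if config.start_offset_ms is None:
        offset_s = float(rng.uniform(0.0, config.dt_ms)) / 1000.0
    else:
        offset_s = config.start_offset_ms / 1000.0

    starts = offset_s + np.concatenate(([0.0], np.cumsum(ti + te)[:-1]))
    ends = starts + ti + te

    shapes = []
    for b in range(n):
        shapes.append(
            BreathShape(
                ti_s=float(ti[b]),
                te_s=float(te[b]),
                vt_l=float(vt_ml[b] / 1000.0),
                etco2_mmhg=float(etco2[b]),
                slope3_mmhg_per_l=float(s3[b]),
                prev_etco2_mmhg=float(etco2[b - 1]) if b > 0 else 0.0,
                phase2_sharpness=config.phase2_sharpness,
            )
        )

    # all grid points strictly inside the simulated span [0, ends[-1])
    n_samples = int(np.ceil(ends[-1] / dt_s - 1e-12))
    if n_samples < 2:
        raise ConfigError("configuration yields a record shorter than 2 samples")
    t_grid_s = np.arange(n_samples) * dt_s
    flow = np.zeros(n_samples)
    pco2 = np.zeros(n_samples)
    which = np.searchsorted(starts, t_grid_s, side="right") - 1
    for b, shape in enumerate(shapes):
        mask = which == b
        if not np.any(mask):
            continue
        t_rel = t_grid_s[mask] - starts[b]
        flow[mask] = shape.flow_lpm(t_rel)
        pco2[mask] = shape.pco2_mmhg(t_rel)

    if config.noise_flow_sd_lpm > 0:
        flow = flow + rng.normal(0.0, config.noise_flow_sd_lpm, size=n_samples)
    if config.noise_pco2_sd_mmhg > 0:
        pco2 = pco2 + rng.normal(0.0, config.noise_pco2_sd_mmhg, size=n_samples)
        pco2 = np.clip(pco2, 0.0, None)

    series = SampleSeries(
        t=np.arange(n_samples, dtype=np.int64) * config.dt_ms,
        flow=flow,
        pco2=pco2,
        dt_ms=config.dt_ms,
    )
    truth = pd.DataFrame(
        {
            "breath": np.arange(n),
            "t_start_s": starts,
            "t_rev_s": starts + ti,
            "t_end_s": ends,
            "vt_ml": vt_ml,
            "ti_s": ti,
            "te_s": te,
            "etco2_mmhg": etco2,
            "slope3_mmhg_per_l": s3,
        },
        columns=TRUTH_COLUMNS,
    )
    return series, truth


def shapes_from_truth(truth: pd.DataFrame, config: SimConfig) -> list[BreathShape]:
    """Rebuild the analytic per-breath waveforms from a ground-truth table
    (used by fine-grid oracle computations)."""
    shapes = []
    prev = 0.0
    for _, row in truth.iterrows():
        shapes.append(
            BreathShape(
                ti_s=float(row["ti_s"]),
                te_s=float(row["te_s"]),
                vt_l=float(row["vt_ml"]) / 1000.0,
                etco2_mmhg=float(row["etco2_mmhg"]),
                slope3_mmhg_per_l=float(row["slope3_mmhg_per_l"]),
                prev_etco2_mmhg=prev,
                phase2_sharpness=config.phase2_sharpness,
            )
        )
        prev = float(row["etco2_mmhg"])
    return shapes
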