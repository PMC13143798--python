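import numpy as np
import pytest

from volcap.segmentation import BreathCycle
from volcap.signal_io import SampleSeries
from volcap.simulator import SimConfig, simulate


def make_series(flow, pco2=None, dt_ms=10):
    flow = np.asarray(flow, dtype=float)
    if pco2 is None:
        pco2 = np.zeros_like(flow)
    return SampleSeries(
        t=np.arange(len(flow), dtype=np.int64) * dt_ms,
        flow=flow,
        pco2=np.asarray(pco2, dtype=float),
        dt_ms=dt_ms,
    )


def square_breath(n_insp=100, n_exp=100, flow_lpm=30.0, pco2_exp=40.0, dt_ms=10):
    """One square-wave breath: constant inspiratory then expiratory flow,
    zero inspired PCO2, constant expiratory PCO2."""
    flow = np.r_[np.full(n_insp, -flow_lpm), np.full(n_exp, flow_lpm)]
    pco2 = np.r_[np.zeros(n_insp), np.full(n_exp, pco2_exp)]
    series = make_series(flow, pco2, dt_ms)
    cycle = BreathCycle(0, n_insp, n_insp + n_exp - 1, True)
    return series, cycle


@pytest.fixture
def clean_sim():
    """12 noiseless identical breaths at the scale of a resting adult."""
    cfg = SimConfig(
        n_breaths=12, vt_cv=0.0, time_cv=0.0, etco2_sd=0.0, slope3_cv=0.0,
        ti_s_mean=1.8, te_s_mean=2.4, vt_ml_mean=500.0, seed=42,
    )
    series, truth = simulate(cfg)
    return cfg, series, truth


@pytest.fixture
def variable_sim():
    """60 breaths with realistic cycle-to-cycle variability, no noise."""
    cfg = SimConfig(
        n_breaths=60, vt_cv=0.12, time_cv=0.06, etco2_sd=1.0, slope3_cv=0.15,
        seed=7,
    )
    series, truth = simulate(cfg)
    return cfg, series, truth
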