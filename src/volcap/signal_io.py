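"""Core sample record, CSV (de)serialization, and native-stream downsampling.

The universal input of the pipeline is a two-channel record — airflow and
CO2 partial pressure — sampled on an exact uniform millisecond grid.
Timestamps are integers, so the grid invariant is checked exactly with no
floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_COLUMNS
from .errors import ConfigError, FormatError, GridError

#: Readings above this are physically implausible for the instrument class
#: (the CO2 channel is characterized up to 100 mmHg) and are rejected.
PCO2_MAX_MMHG = 150.0

#: Fixed decimal places used when serializing flow / PCO2.
CSV_DECIMALS = 3


@dataclass(frozen=True)
class SampleSeries:
    """Synchronized flow / PCO2 record on a uniform integer-ms grid.

    ``flow`` is signed in L/min with the convention positive = expiration;
    ``pco2`` is in mmHg.  Construction validates all invariants.
    """

    t: np.ndarray
    flow: np.ndarray
    pco2: np.ndarray
    dt_ms: int = 10

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.int64)
        flow = np.asarray(self.flow, dtype=np.float64)
        pco2 = np.asarray(self.pco2, dtype=np.float64)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "flow", flow)
        object.__setattr__(self, "pco2", pco2)
        if not (len(t) == len(flow) == len(pco2)):
            raise FormatError(
                f"channel lengths differ: t={len(t)} flow={len(flow)} pco2={len(pco2)}"
            )
        if len(t) < 2:
            raise FormatError(f"a record needs at least 2 samples, got {len(t)}")
        if self.dt_ms <= 0:
            raise ConfigError(f"dt_ms must be positive, got {self.dt_ms}")
        diffs = np.diff(t)
        bad = np.nonzero(diffs != self.dt_ms)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise GridError(
                f"non-uniform timestamp at index {i}: t[{i}]={t[i]} "
                f"(expected {t[i - 1] + self.dt_ms} for dt_ms={self.dt_ms})"
            )
        if not np.all(np.isfinite(flow)):
            raise FormatError("flow contains non-finite values")
        if not np.all(np.isfinite(pco2)):
            raise FormatError("pco2 contains non-finite values")
        if np.any(pco2 < 0):
            i = int(np.argmax(pco2 < 0))
            raise FormatError(f"negative pco2 at index {i}: {pco2[i]}")
        if np.any(pco2 > PCO2_MAX_MMHG):
            i = int(np.argmax(pco2 > PCO2_MAX_MMHG))
            raise FormatError(
                f"pco2 {pco2[i]} mmHg at index {i} exceeds the plausibility "
                f"limit of {PCO2_MAX_MMHG} mmHg"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration_ms(self) -> int:
        """Total record span covered by the samples (n * dt_ms)."""
        return self.n * self.dt_ms

    def time_s(self) -> np.ndarray:
        return (self.t - self.t[0]) / 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t, "flow_lpm": self.flow, "pco2_mmhg": self.pco2}
        )


@dataclass(frozen=True)
class RawFlowStream:
    """Flow channel at the sensor's native (sub-ms) resolution.

    ``t_native`` is in ms with uniform fractional spacing (0.5 ms for the
    target hardware); the spacing must divide the output grid interval.
    """

    t_native: np.ndarray
    flow_native: np.ndarray
    spacing_ms: float = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_native, dtype=np.float64)
        f = np.asarray(self.flow_native, dtype=np.float64)
        object.__setattr__(self, "t_native", t)
        object.__setattr__(self, "flow_native", f)
        if len(t) != len(f):
            raise FormatError("t_native and flow_native lengths differ")
        if len(t) < 2:
            raise FormatError("native stream needs at least 2 samples")
        diffs = np.diff(t)
        spacing = diffs[0]
        if spacing <= 0 or not np.allclose(diffs, spacing, rtol=0, atol=1e-9):
            raise GridError("native timestamps are not uniformly spaced")
        object.__setattr__(self, "spacing_ms", float(spacing))


def read_series(
    path,
    *,
    columns: dict[str, str] | None = None,
    dt_ms: int | None = None,
    invert_flow: bool = False,
) -> SampleSeries:
    """Read a device CSV into a validated :class:`SampleSeries`.

    Parameters
    ----------
    columns:
        Mapping with keys ``t``, ``flow``, ``pco2`` naming the CSV columns;
        defaults to ``t_ms, flow_lpm, pco2_mmhg``.
    dt_ms:
        Expected grid interval; inferred from the first two rows if omitted.
    invert_flow:
        Negate the flow channel (polarity fix; positive must mean expiration
        downstream).

    Raises
    ------
    FormatError
        Missing column or unparseable field (rows are never silently dropped).
    GridError
        First timestamp off the uniform grid, with its index.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    for key in ("t", "flow", "pco2"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"missing column {cols[key]!r} in {path!r} "
                f"(found: {', '.join(df.columns)})"
            )
    parsed = {}
    for key in ("t", "flow", "pco2"):
        raw = df[cols[key]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            i = int(bad[0])
            raise FormatError(
                f"unparseable value {raw.iloc[i]!r} in column {cols[key]!r}, row {i}"
            )
        parsed[key] = vals.to_numpy(dtype=np.float64)
    t = parsed["t"]
    t_int = np.round(t).astype(np.int64)
    if np.any(np.abs(t - t_int) > 1e-9):
        i = int(np.argmax(np.abs(t - t_int) > 1e-9))
        raise FormatError(f"non-integer timestamp at row {i}: {t[i]}")
    if dt_ms is None:
        if len(t_int) < 2:
            raise FormatError("cannot infer dt_ms from fewer than 2 rows")
        dt_ms = int(t_int[1] - t_int[0])
        if dt_ms <= 0:
            raise GridError("non-uniform timestamp at index 1: non-increasing grid")
    flow = parsed["flow"]
    if invert_flow:
        flow = -flow
    return SampleSeries(t=t_int, flow=flow, pco2=parsed["pco2"], dt_ms=dt_ms)


def write_series(series: SampleSeries, path) -> None:
    """Write a record as CSV: header ``t_ms,flow_lpm,pco2_mmhg``, integer ms,
    3 decimals on both channels, LF line endings, no quoting.

    Re-reading the file reproduces the series exactly at that precision.
    """
    if not path:
        raise OSError("empty output path")
    fmt = f"%.{CSV_DECIMALS}f"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("t_ms,flow_lpm,pco2_mmhg\n")
        for ti, fi, pi in zip(series.t, series.flow, series.pco2):
            fh.write(f"{ti},{fmt % fi},{fmt % pi}\n")


def downsample_flow(raw: RawFlowStream, dt_ms: int = 10) -> np.ndarray:
    """Average the native flow stream onto the output grid.

    Each output sample k is the arithmetic mean of the native samples with
    timestamps in ``[k*dt_ms, (k+1)*dt_ms)`` relative to the stream start.
    A trailing partial window is dropped so every mean covers a full window.
    """
    ratio_f = dt_ms / raw.spacing_ms
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-9 or ratio < 1:
        raise ConfigError(
            f"native spacing {raw.spacing_ms} ms does not divide dt_ms={dt_ms}"
        )
    n_windows = len(raw.flow_native) // ratio
    if n_windows == 0:
        return np.empty(0, dtype=np.float64)
    trimmed = raw.flow_native[: n_windows * ratio]
    return trimmed.reshape(n_windows, ratio).mean(axis=1)
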