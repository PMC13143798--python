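"""Two-sample comparison of per-breath parameter tables.

Parameters from two devices (or device vs ground truth) are compared with an
unpaired two-sided Mann-Whitney U test and summarized as mean +/- sample SD,
one row per parameter.  The exact null distribution is used for small
tie-free samples (n_x * n_y <= 400); otherwise the normal approximation with
tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

#: Parameter columns compared by default (the per-cycle metrics table).
DEFAULT_PARAMETERS = (
    "etco2_mmhg", "ti_s", "te_s", "vi_ml", "ve_ml", "pef_lpm", "vco2_ml",
)

#: Product-of-sizes threshold below which the exact enumeration is used
#: (tie-free data only).
EXACT_THRESHOLD = 400


@dataclass(frozen=True)
class ComparisonRow:
    parameter: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact p by enumeration when ``n_x * n_y <= 400`` and the pooled sample is
    tie-free; normal approximation with tie and continuity corrections
    otherwise.  A fully degenerate pooled sample (zero variance) returns
    ``(n_x * n_y / 2, 1.0)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ContractError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return nx * ny / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if nx * ny <= EXACT_THRESHOLD and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u_x = float(res.statistic)
    # conservation check: U_x + U_y = n_x * n_y
    u_y = nx * ny - u_x
    assert u_y >= 0.0
    return u_x, min(float(res.pvalue), 1.0)


def _complete_values(df: pd.DataFrame, parameter: str) -> np.ndarray:
    vals = df[parameter]
    if "complete" in df.columns:
        vals = vals[df["complete"].astype(bool)]
    return vals.dropna().to_numpy(dtype=np.float64)


def compare_tables(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    parameters=DEFAULT_PARAMETERS,
) -> list[ComparisonRow]:
    """One :class:`ComparisonRow` per requested parameter.

    Only complete cycles enter the comparison; the devices need not have the
    same number of cycles (the test is unpaired).
    """
    rows = []
    for param in parameters:
        for df, label in ((metrics_a, "a"), (metrics_b, "b")):
            if param not in df.columns:
                available = ", ".join(c for c in df.columns if c not in
                                      ("i_start", "i_rev", "i_end", "complete"))
                raise ContractError(
                    f"unknown parameter {param!r} in table {label} "
                    f"(available: {available})"
                )
        a = _complete_values(metrics_a, param)
        b = _complete_values(metrics_b, param)
        u, p = mann_whitney(a, b)
        rows.append(
            ComparisonRow(
                parameter=param,
                n_a=len(a),
                n_b=len(b),
                mean_a=float(a.mean()),
                sd_a=float(a.std(ddof=1)) if len(a) > 1 else 0.0,
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)) if len(b) > 1 else 0.0,
                u_statistic=u,
                p_value=p,
            )
        )
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def _fmt(param: str, mean: float, sd: float) -> str:
    # volumes as integers, pressures/times/flows at one decimal
    if param in ("vi_ml", "ve_ml"):
        return f"{mean:.0f} ± {sd:.0f}"
    return f"{mean:.1f} ± {sd:.1f}"


def render_markdown(rows: list[ComparisonRow], label_a: str = "A", label_b: str = "B") -> str:
    """Mean +/- SD comparison table in Markdown."""
    lines = [
        f"| Parameter | {label_a} (n) | {label_b} (n) | p |",
        "|---|---|---|---|",
    ]
    for r in rows:
        lines.append(
            f"| {r.parameter} | {_fmt(r.parameter, r.mean_a, r.sd_a)} ({r.n_a}) "
            f"| {_fmt(r.parameter, r.mean_b, r.sd_b)} ({r.n_b}) | {r.p_value:.2f} |"
        )
    return "\n".join(lines) + "\n"
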