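"""Heart-rate-variability thresholds from a rolling alpha1 series.

During incremental exercise the short-term DFA exponent falls in a nearly
straight line from its correlated resting range (~1.0 and above) to the
uncorrelated value 0.5 and below.  Two landmarks on that descent serve as
surrogates for the conventional physiologic thresholds:

* HRVT  — the intensity (HR, time, or power) at which alpha1 crosses 0.75,
  a surrogate for the aerobic threshold (VT1/LT1);
* HRVT2 — the crossing of 0.5, the transition into anticorrelated dynamics,
  a surrogate for the anaerobic threshold (VT2/LT2).

Estimation is regression-first: ordinary least squares of alpha1 on the
predictor over the descent band (alpha1 in [0.4, 1.0]), solved for the
target.  When the fit is poor (r² < 0.5) or non-descending, a first-crossing
linear interpolation on the 4-point-smoothed series is used instead, with a
QC flag.  If alpha1 never reaches the target, no value is returned and the
result carries a ``no_crossing`` flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .dfa import moving_average

__all__ = [
    "ThresholdResult",
    "estimate_threshold",
    "estimate_hrvt_pair",
    "load_drift_summary",
]

#: alpha1 band over which the descent is regressed; excludes the correlated
#: pre-ramp plateau (> 1.0) and the anticorrelated floor (< 0.4).
REGRESSION_BAND = (0.4, 1.0)

#: Minimum r-squared for the regression route; below it the first-crossing
#: fallback is used.
MIN_R2 = 0.5

_PREDICTOR_COLS = {"hr": "hr", "time": "t_end", "power": "power"}


@dataclasses.dataclass
class ThresholdResult:
    """One threshold estimate with regression diagnostics and QC flags."""

    target: float
    predictor: str
    value: float | None  # crossing on the predictor axis
    hr: float | None
    time_s: float | None
    power: float | None
    method: str  # "regression" or "first_crossing"
    slope: float | None
    intercept: float | None
    r2: float | None
    n_windows: int
    qc: list[str] = dataclasses.field(default_factory=list)


def _usable(alpha: pd.DataFrame, predictor: str, bounds) -> pd.DataFrame:
    col = _PREDICTOR_COLS.get(predictor)
    if col is None:
        raise ValueError(f"predictor must be one of {sorted(_PREDICTOR_COLS)}")
    df = alpha[alpha["valid"]].copy()
    if bounds is not None:
        lo, hi = bounds
        if lo is not None:
            df = df[df["t_end"] >= lo]
        if hi is not None:
            df = df[df["t_end"] <= hi]
    df = df[np.isfinite(df[col]) & np.isfinite(df["alpha1"])]
    return df.sort_values("t_end")


def _interp_at_time(df: pd.DataFrame, col: str, t_star: float) -> float | None:
    sel = df[np.isfinite(df[col])]
    if len(sel) < 2 or t_star is None:
        return None
    return float(np.interp(t_star, sel["t_end"].to_numpy(), sel[col].to_numpy()))


def _crossings(t: np.ndarray, y: np.ndarray, x: np.ndarray, target: float):
    """All downward crossings of target in y, as (t*, x*) pairs."""
    out = []
    for i in range(len(y) - 1):
        if y[i] >= target > y[i + 1]:
            frac = (y[i] - target) / (y[i] - y[i + 1]) if y[i] != y[i + 1] else 0.0
            out.append(
                (float(t[i] + frac * (t[i + 1] - t[i])), float(x[i] + frac * (x[i + 1] - x[i])))
            )
    return out


def estimate_threshold(
    alpha: pd.DataFrame,
    predictor: str = "hr",
    target: float = 0.75,
    bounds: tuple[float | None, float | None] | None = None,
    band: tuple[float, float] = REGRESSION_BAND,
    min_windows: int = 5,
    smooth_k: int = 4,
) -> ThresholdResult:
    """Estimate the intensity at which alpha1 crosses ``target``.

    ``alpha`` is a rolling-alpha1 frame (see ``alpha1_time_varying``);
    ``predictor`` chooses the axis ("hr", "time" or "power");
    ``bounds`` restricts the analysis to a time range (ramp start/end),
    excluding warm-up and cool-down.
    """
    col = _PREDICTOR_COLS[predictor] if predictor in _PREDICTOR_COLS else None
    df = _usable(alpha, predictor, bounds)
    if len(df) < min_windows:
        raise ValueError(f"need >= {min_windows} usable windows, got {len(df)}")
    qc: list[str] = []
    res = ThresholdResult(
        target=target,
        predictor=predictor,
        value=None,
        hr=None,
        time_s=None,
        power=None,
        method="regression",
        slope=None,
        intercept=None,
        r2=None,
        n_windows=len(df),
        qc=qc,
    )
    if float(df["alpha1"].min()) > target:
        qc.append("no_crossing")
        return res

    smoothed = moving_average(df.assign(valid=True), smooth_k)
    t_arr = smoothed["t_end"].to_numpy(dtype=float)
    a_arr = smoothed["alpha1"].to_numpy(dtype=float)
    x_arr = smoothed[col].to_numpy(dtype=float)
    cross = _crossings(t_arr, a_arr, x_arr, target)
    if len(cross) > 1:
        qc.append("multiple_crossings")

    band_df = df[(df["alpha1"] >= band[0]) & (df["alpha1"] <= band[1])]
    fit = None
    if len(band_df) >= min_windows:
        fit = stats.linregress(band_df[col].to_numpy(), band_df["alpha1"].to_numpy())
        res.slope = float(fit.slope)
        res.intercept = float(fit.intercept)
        res.r2 = float(fit.rvalue**2)

    use_regression = (
        fit is not None
        and np.isfinite(fit.slope)
        and fit.slope < 0
        and fit.rvalue**2 >= MIN_R2
    )
    if use_regression:
        res.method = "regression"
        res.value = float((target - fit.intercept) / fit.slope)
        t_star = cross[0][0] if cross else None
    else:
        res.method = "first_crossing"
        if fit is not None:
            qc.append("poor_fit" if fit.slope < 0 else "non_monotone")
        if not cross:
            if "no_crossing" not in qc:
                qc.append("no_crossing")
            return res
        t_star, x_star = cross[0]
        res.value = x_star

    res.time_s = t_star
    if t_star is not None:
        res.hr = _interp_at_time(df, "hr", t_star)
        res.power = _interp_at_time(df, "power", t_star)
    if predictor == "hr":
        res.hr = res.value
    elif predictor == "time":
        res.time_s = res.value
    elif predictor == "power":
        res.power = res.value
    return res


def estimate_hrvt_pair(
    alpha: pd.DataFrame,
    predictor: str = "hr",
    targets: tuple[float, float] = (0.75, 0.5),
    bounds: tuple[float | None, float | None] | None = None,
    **kwargs,
) -> tuple[ThresholdResult, ThresholdResult]:
    """Estimate HRVT (alpha1 = 0.75) and HRVT2 (alpha1 = 0.5) together.

    HRVT2 lies at a higher intensity than HRVT; if the HR estimates violate
    that ordering both results are flagged ``inconsistent``.
    """
    first = estimate_threshold(alpha, predictor, targets[0], bounds, **kwargs)
    second = estimate_threshold(alpha, predictor, targets[1], bounds, **kwargs)
    if first.hr is not None and second.hr is not None and second.hr < first.hr:
        first.qc.append("inconsistent")
        second.qc.append("inconsistent")
    return first, second


def load_drift_summary(
    alpha: pd.DataFrame,
    bounds: tuple[float | None, float | None] | None = None,
    min_windows: int = 10,
) -> dict:
    """Drift of alpha1 over a bounded segment, for durability/fatigue inspection.

    Returns the slope of alpha1 against time (units: per hour) with the mean
    alpha1, HR and power over the segment.  A sustained negative slope at a
    fixed external load indicates deteriorating autonomic status.
    """
    df = _usable(alpha, "time", bounds)
    if len(df) < min_windows:
        raise ValueError(f"need >= {min_windows} valid windows, got {len(df)}")
    t_h = df["t_end"].to_numpy() / 3600.0
    a = df["alpha1"].to_numpy()
    if np.allclose(a, a[0]):
        slope = 0.0
    else:
        slope = float(stats.linregress(t_h, a).slope)
    return {
        "slope_per_h": slope,
        "mean_alpha1": float(df["alpha1"].mean()),
        "mean_hr": float(df["hr"].mean()),
        "mean_power": float(df["power"].mean()) if np.isfinite(df["power"]).any() else None,
        "n_windows": int(len(df)),
    }
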