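"""Reading and writing RR-interval recordings and analysis outputs.

The central container is :class:`RRSeries`: an ordered sequence of beat-to-beat
(RR) intervals in milliseconds with a derived time base.  The time stamp of
each beat is the *end* of its interval, so a recording starting at t = 0 has
its first beat at ``rr[0] / 1000`` seconds and the total duration equals
``sum(rr) / 1000`` exactly.

Two plain-text dialects are supported, matching what consumer heart-rate
straps and HRV apps export:

* one interval per line (ms or s), ``#`` comments and blank lines ignored;
* CSV with a header row and configurable column names, optionally carrying a
  1-Hz external-load channel (cycling power, running speed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("fractalhrv")

__all__ = [
    "RRSeries",
    "read_rr_text",
    "read_rr_csv",
    "write_rr_text",
    "instantaneous_hr",
    "write_alpha_csv",
    "read_alpha_csv",
    "write_threshold_json",
]

#: Physiologically plausible RR range, ms.  Intervals outside are accepted on
#: read (gating is the preprocess module's job) but logged.
PHYSIO_RR_MS = (200.0, 2500.0)

#: Column order of the rolling-alpha1 CSV schema.
ALPHA_COLUMNS = ["window_end_s", "alpha1", "hr_bpm", "power_w", "artifact_pct", "valid"]


@dataclasses.dataclass
class RRSeries:
    """An RR-interval recording.

    Parameters
    ----------
    rr
        Intervals in ms, all positive, length >= 2.
    channels
        Optional aligned external-load channels, e.g. ``{"power": series}``
        where the pandas Series is indexed by time in seconds (nominally 1 Hz).
    meta
        Free-form source description.
    corrected
        Optional boolean mask, aligned with ``rr``, marking intervals that were
        replaced/interpolated by artifact correction.
    """

    rr: np.ndarray
    channels: dict[str, pd.Series] = dataclasses.field(default_factory=dict)
    meta: dict = dataclasses.field(default_factory=dict)
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1 or self.rr.size < 2:
            raise ValueError("RRSeries needs a 1-d sequence of at least 2 intervals")
        if not np.all(self.rr > 0):
            raise ValueError("all RR intervals must be positive")
        if self.corrected is not None:
            self.corrected = np.asarray(self.corrected, dtype=bool)
            if self.corrected.shape != self.rr.shape:
                raise ValueError("corrected mask must align with rr")
        lo, hi = PHYSIO_RR_MS
        n_out = int(np.count_nonzero((self.rr < lo) | (self.rr > hi)))
        if n_out:
            logger.info("%d of %d intervals outside [%g, %g] ms", n_out, self.rr.size, lo, hi)

    @property
    def t(self) -> np.ndarray:
        """Beat times in seconds (end of each interval, starting from 0)."""
        return np.cumsum(self.rr) / 1000.0

    @property
    def n_beats(self) -> int:
        return int(self.rr.size)

    @property
    def duration_s(self) -> float:
        return float(np.sum(self.rr) / 1000.0)

    def copy(self) -> "RRSeries":
        return RRSeries(
            rr=self.rr.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            meta=dict(self.meta),
            corrected=None if self.corrected is None else self.corrected.copy(),
        )


def read_rr_text(path: str | Path, unit: str = "ms") -> RRSeries:
    """Read a one-interval-per-line RR export.

    Blank lines and lines starting with ``#`` are ignored.  ``unit`` is the
    unit of the stored numbers (``"ms"`` or ``"s"``); intervals are converted
    to ms internally.
    """
    if unit not in ("ms", "s"):
        raise ValueError(f"unit must be 'ms' or 's', got {unit!r}")
    scale = 1.0 if unit == "ms" else 1000.0
    values: list[float] = []
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                v = float(line)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: not a number: {line!r}") from None
            if v <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive interval {v}")
            values.append(v * scale)
    return RRSeries(rr=np.asarray(values), meta={"source": str(path), "unit": unit})


def write_rr_text(series: RRSeries, path: str | Path) -> None:
    """Write intervals in ms, one per line (the dialect `read_rr_text` reads)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for v in series.rr:
            fh.write(f"{v:.10g}\n")


def read_rr_csv(
    path: str | Path,
    rr_col: str = "rr",
    time_col: str | None = None,
    power_col: str | None = None,
    unit: str = "ms",
) -> RRSeries:
    """Read a CSV RR export with a header row.

    The RR column is mandatory.  If a timestamp column is given it is checked
    for consistency with the cumulative-RR time base (1% of total duration);
    on disagreement a warning is logged and cumulative RR wins.  A power
    column, if present, is attached as a 1-Hz channel indexed by the
    timestamp column (or cumulative time when absent).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if rr_col not in df.columns:
        raise KeyError(f"{path}: required RR column {rr_col!r} not in {list(df.columns)}")
    scale = {"ms": 1.0, "s": 1000.0}.get(unit)
    if scale is None:
        raise ValueError(f"unit must be 'ms' or 's', got {unit!r}")
    rr = df[rr_col].to_numpy(dtype=float) * scale
    if np.any(~np.isfinite(rr)) or np.any(rr <= 0):
        raise ValueError(f"{path}: RR column contains non-positive or missing values")
    series = RRSeries(rr=rr, meta={"source": str(path)})
    if time_col is not None and time_col in df.columns:
        ts = df[time_col].to_numpy(dtype=float)
        ts = ts - ts[0] + rr[0] / 1000.0
        drift = float(np.max(np.abs(ts - series.t)))
        if drift > 0.01 * series.duration_s:
            logger.warning(
                "%s: timestamp column deviates from cumulative RR by up to %.2f s; "
                "using cumulative RR",
                path,
                drift,
            )
    if power_col is not None:
        if power_col not in df.columns:
            raise KeyError(f"{path}: power column {power_col!r} not found")
        t_idx = (
            df[time_col].to_numpy(dtype=float) if time_col and time_col in df.columns else series.t
        )
        series.channels["power"] = pd.Series(
            df[power_col].to_numpy(dtype=float), index=np.asarray(t_idx, dtype=float), name="power"
        )
    return series


def instantaneous_hr(
    series: RRSeries, window_s: float, at: np.ndarray | None = None
) -> pd.DataFrame:
    """Windowed heart rate in bpm: HR(t) = 60000 / mean(rr in (t - window_s, t]).

    ``at`` gives the evaluation times (defaults to every beat time).  Times
    whose window contains no beat get NaN.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = series.t
    times = t if at is None else np.asarray(at, dtype=float)
    hr = np.full(times.shape, np.nan)
    for i, te in enumerate(times):
        lo = np.searchsorted(t, te - window_s, side="right")
        hi = np.searchsorted(t, te, side="right")
        if hi > lo:
            hr[i] = 60000.0 / float(np.mean(series.rr[lo:hi]))
    return pd.DataFrame({"t_s": times, "hr_bpm": hr})


def write_alpha_csv(alpha: pd.DataFrame, path: str | Path) -> None:
    """Write a rolling-alpha1 table (see `fractalhrv.dfa.alpha1_time_varying`).

    Columns: window_end_s, alpha1 (3 decimals), hr_bpm (1 decimal), power_w,
    artifact_pct, valid.  An empty table writes the header only and logs a
    warning.
    """
    out = pd.DataFrame(index=alpha.index)
    out["window_end_s"] = alpha["t_end"].round(3)
    out["alpha1"] = alpha["alpha1"].round(3)
    out["hr_bpm"] = alpha["hr"].round(1)
    out["power_w"] = alpha["power"].round(1) if "power" in alpha else np.nan
    out["artifact_pct"] = alpha["artifact_pct"].round(2)
    out["valid"] = alpha["valid"].astype(bool)
    if out.empty:
        logger.warning("writing empty alpha series to %s", path)
        out = pd.DataFrame(columns=ALPHA_COLUMNS)
    out.to_csv(path, index=False)


def read_alpha_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by `write_alpha_csv` back into the internal schema."""
    df = pd.read_csv(path)
    missing = set(ALPHA_COLUMNS) - set(df.columns)
    if missing:
        raise KeyError(f"{path}: missing alpha CSV columns {sorted(missing)}")
    return pd.DataFrame(
        {
            "t_end": df["window_end_s"].astype(float),
            "alpha1": df["alpha1"].astype(float),
            "hr": df["hr_bpm"].astype(float),
            "power": df["power_w"].astype(float),
            "artifact_pct": df["artifact_pct"].astype(float),
            "n_beats": df.get("n_beats", pd.Series(np.nan, index=df.index)),
            "valid": df["valid"].astype(bool),
        }
    )


def write_threshold_json(results: Mapping | object, path: str | Path) -> None:
    """Serialize one or several threshold estimates to JSON.

    Accepts a single ThresholdResult-like dataclass or a mapping of them
    (e.g. ``{"0.75": res1, "0.5": res2}``).
    """

    def _as_dict(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, Mapping):
            return {str(k): _as_dict(v) for k, v in obj.items()}
        return obj

    payload = _as_dict(results)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
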