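"""Synthetic fractal RR-interval series with known scaling exponents.

Fractional Gaussian noise (fGn) with Hurst exponent H is the canonical test
process for short-term DFA: the DFA exponent of fGn equals H, so series
generated here carry a known ground truth for estimator validation.  Exact
fGn (H < 1) is synthesized by circulant embedding (Davies–Harte); the
"more-than-1/f" regimes seen in resting HRV (alpha up to ~1.2) are reached by
spectral shaping with power spectrum ∝ f^-(2H-1), which has the same DFA
exponent and extends the usable range to H < 1.5.

An incremental exercise ramp is emulated as piecewise-stationary segments —
each with its own target exponent, mean RR and RR variability — joined by
30-s cross-fades.  Along a ramp the mean RR falls (HR rises), the exponent
declines from a correlated resting value through 0.75 and 0.5 into the
anticorrelated range, and the RR variability amplitude shrinks (vagal
withdrawal).  The generator records the planted trajectory and the true heart
rate at which the exponent crosses 0.75 and 0.5, giving every downstream
threshold estimator an oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import RRSeries

__all__ = [
    "Segment",
    "RampSpec",
    "RampTruth",
    "generate_fgn",
    "generate_exercise_ramp",
    "builtin_scenarios",
]

#: Duration of the linear cross-fade joining adjacent ramp segments, s.
DEFAULT_FADE_S = 30.0


@dataclasses.dataclass(frozen=True)
class Segment:
    """One stationary stretch of a simulated recording."""

    length_s: float
    H: float  # target scaling exponent
    mean_rr_ms: float
    rr_sd_ms: float


@dataclasses.dataclass(frozen=True)
class RampSpec:
    """A synthetic incremental-exercise specification."""

    name: str
    segments: tuple[Segment, ...]
    fade_s: float = DEFAULT_FADE_S
    jitter_ms: float = 0.0  # iid measurement noise added to every interval
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("at least one segment required")
        for s in self.segments:
            if not (0 < s.H < 1.5):
                raise ValueError(f"target H must be in (0, 1.5), got {s.H}")
            if s.length_s <= 0 or s.mean_rr_ms <= 0 or s.rr_sd_ms < 0:
                raise ValueError("segment lengths/means must be positive, sd non-negative")
        means = [s.mean_rr_ms for s in self.segments]
        if any(b > a + 1e-9 for a, b in zip(means, means[1:])):
            raise ValueError("mean RR must be non-increasing across a ramp")

    @property
    def duration_s(self) -> float:
        return float(sum(s.length_s for s in self.segments))


@dataclasses.dataclass
class RampTruth:
    """Planted ground truth sampled at 1 Hz, plus threshold crossings."""

    t: np.ndarray
    alpha: np.ndarray  # target exponent trajectory
    mean_rr: np.ndarray  # ms
    hr: np.ndarray  # bpm, 60000 / mean_rr
    hr_at_hrvt: float | None  # true HR where alpha crosses 0.75
    hr_at_hrvt2: float | None  # true HR where alpha crosses 0.5
    t_at_hrvt: float | None
    t_at_hrvt2: float | None

    def hr_at_alpha(self, target: float) -> float | None:
        """True HR at the first downward crossing of ``target``."""
        t_star = _first_downward_crossing(self.t, self.alpha, target)
        if t_star is None:
            return None
        return float(np.interp(t_star, self.t, self.hr))


def generate_fgn(n: int, H: float, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian series with DFA exponent H.

    H < 1: exact fractional Gaussian noise by circulant embedding
    (Davies–Harte); its lag-1 autocorrelation obeys the closed form
    ``rho(1) = 2^(2H-1) - 1``.  1 <= H < 1.5: spectral synthesis with power
    spectrum ∝ f^-(2H-1) (1/f-type noise at H = 1).
    """
    if not (0 < H < 1.5):
        raise ValueError(f"H must be in (0, 1.5), got {H}")
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if H < 1.0:
        # population moments are exact (gamma(0) = 1); per-sample restandardization
        # would re-center by the sample mean and bias the autocovariance structure
        return _fgn_davies_harte(n, H, rng)
    x = _spectral_noise(n, 2.0 * H - 1.0, rng)  # exact zero mean (no DC component)
    sd = x.std()
    return x / sd if sd > 0 else x


def _fgn_davies_harte(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    lam = np.where(lam < 0, 0.0, lam)  # clip tiny negative eigenvalues
    m = row.size
    w = np.zeros(m, dtype=complex)
    half = m // 2
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[half] = np.sqrt(lam[half] / m) * rng.standard_normal()
    j = np.arange(1, half)
    a = rng.standard_normal(half - 1)
    b = rng.standard_normal(half - 1)
    w[j] = np.sqrt(lam[j] / (2 * m)) * (a + 1j * b)
    w[m - j] = np.conj(w[j])
    return np.fft.fft(w).real[:n]


def _spectral_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = z[-1].real
    return np.fft.irfft(amp * z, n)


def _faded_trajectory(spec: RampSpec, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise-constant per-segment values with linear cross-fades at boundaries."""
    bounds = np.cumsum([s.length_s for s in spec.segments])[:-1]
    seg_idx = np.searchsorted(bounds, t, side="right")
    out = values[seg_idx].astype(float)
    half = spec.fade_s / 2.0
    for bi, b in enumerate(bounds):
        in_fade = (t > b - half) & (t < b + half)
        if np.any(in_fade):
            w = (t[in_fade] - (b - half)) / spec.fade_s
            out[in_fade] = (1 - w) * values[bi] + w * values[bi + 1]
    return out


def _first_downward_crossing(t: np.ndarray, y: np.ndarray, target: float) -> float | None:
    above = y >= target
    for i in range(len(y) - 1):
        if above[i] and not above[i + 1]:
            y0, y1 = y[i], y[i + 1]
            frac = (y0 - target) / (y0 - y1) if y1 != y0 else 0.0
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def generate_exercise_ramp(
    spec: RampSpec, seed: int | np.random.Generator | None = None
) -> tuple[RRSeries, RampTruth]:
    """Synthesize an RR recording from a ramp specification.

    Each segment contributes a unit fGn stream with its target exponent;
    beats are generated sequentially with the interval set to
    ``mean_rr(t) + sd(t) * x`` where mean and sd follow the cross-faded
    trajectories.  Inside a fade the two adjacent streams are mixed with
    variance-normalized linear weights, so the effective exponent sweeps
    between the neighboring targets.  Determinism: the same seed reproduces
    the series bit for bit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else spec.seed
    )
    segs = spec.segments
    n_seg = len(segs)
    streams = []
    for s in segs:
        # generous stream length: segment plus both fades at the fastest local rate
        worst_rr = 0.7 * min(s.mean_rr_ms, 2500.0)
        length = int(np.ceil((s.length_s + 2 * spec.fade_s) * 1000.0 / worst_rr)) + 64
        streams.append(generate_fgn(max(length, 16), s.H, rng))
    cursors = [0] * n_seg

    bounds = np.cumsum([s.length_s for s in segs])[:-1]
    half = spec.fade_s / 2.0
    mean_v = np.array([s.mean_rr_ms for s in segs])
    sd_v = np.array([s.rr_sd_ms for s in segs])

    def _next_sample(si: int) -> float:
        stream = streams[si]
        c = cursors[si]
        if c >= stream.size:  # extremely unlikely; extend deterministically
            streams[si] = np.concatenate([stream, generate_fgn(stream.size, segs[si].H, rng)])
            stream = streams[si]
        cursors[si] += 1
        return float(stream[c])

    rr_out: list[float] = []
    t_now = 0.0
    T = spec.duration_s
    while t_now < T:
        si = int(np.searchsorted(bounds, t_now, side="right"))
        # fade weights against the neighboring segment, if inside a fade
        w_next = 0.0
        if si < n_seg - 1 and t_now > bounds[si] - half:
            w_next = (t_now - (bounds[si] - half)) / spec.fade_s
        elif si > 0 and t_now < bounds[si - 1] + half:
            # early part of the fade that started in the previous segment
            w_prev = 1.0 - (t_now - (bounds[si - 1] - half)) / spec.fade_s
            x = w_prev * _next_sample(si - 1) + (1 - w_prev) * _next_sample(si)
            x /= np.hypot(w_prev, 1 - w_prev)
            mean = (1 - w_prev) * mean_v[si] + w_prev * mean_v[si - 1]
            sd = (1 - w_prev) * sd_v[si] + w_prev * sd_v[si - 1]
            rr = _emit(mean, sd, x, spec, rng)
            rr_out.append(rr)
            t_now += rr / 1000.0
            continue
        if w_next > 0:
            x = (1 - w_next) * _next_sample(si) + w_next * _next_sample(si + 1)
            x /= np.hypot(1 - w_next, w_next)
            mean = (1 - w_next) * mean_v[si] + w_next * mean_v[si + 1]
            sd = (1 - w_next) * sd_v[si] + w_next * sd_v[si + 1]
        else:
            x = _next_sample(si)
            mean, sd = mean_v[si], sd_v[si]
        rr = _emit(mean, sd, x, spec, rng)
        rr_out.append(rr)
        t_now += rr / 1000.0

    t_grid = np.arange(0.0, T + 1.0)
    alpha_traj = _faded_trajectory(spec, np.array([s.H for s in segs]), t_grid)
    rr_traj = _faded_trajectory(spec, mean_v, t_grid)
    hr_traj = 60000.0 / rr_traj
    t075 = _first_downward_crossing(t_grid, alpha_traj, 0.75)
    t05 = _first_downward_crossing(t_grid, alpha_traj, 0.5)
    truth = RampTruth(
        t=t_grid,
        alpha=alpha_traj,
        mean_rr=rr_traj,
        hr=hr_traj,
        hr_at_hrvt=None if t075 is None else float(np.interp(t075, t_grid, hr_traj)),
        hr_at_hrvt2=None if t05 is None else float(np.interp(t05, t_grid, hr_traj)),
        t_at_hrvt=t075,
        t_at_hrvt2=t05,
    )
    series = RRSeries(rr=np.asarray(rr_out), meta={"scenario": spec.name, "synthetic": True})
    return series, truth


def _emit(mean: float, sd: float, x: float, spec: RampSpec, rng: np.random.Generator) -> float:
    rr = mean + sd * x
    if spec.jitter_ms > 0:
        rr += spec.jitter_ms * rng.standard_normal()
    return float(np.clip(rr, 250.0, 3000.0))


def builtin_scenarios() -> dict[str, RampSpec]:
    """Named simulation scenarios used across tests and experiments.

    * ``clean_ramp`` — 20-min incremental ramp, exponent 1.1 -> 0.3, mean RR
      850 -> 330 ms, RR variability shrinking 40 -> 3 ms; plants crossings of
      0.75 and 0.5.
    * ``noisy_ramp`` — same trajectory with 4 ms iid measurement jitter.
    * ``steady_low`` — 15 min of low-intensity, well-correlated variability
      (exponent 1.05); never reaches 0.75.
    * ``anticorrelated_floor`` — 10 min steady at exponent 0.3, as at severe
      intensity.
    * ``full_range_ramp`` — steady correlated start (1.15), ramp, steady
      anticorrelated finish (0.25); guarantees control windows both above
      1.0 and below 0.5 for bias experiments.
    """
    n = 10
    hs = np.linspace(1.1, 0.3, n)
    rrs = np.linspace(850.0, 330.0, n)
    sds = np.geomspace(40.0, 3.0, n)
    ramp_segments = tuple(
        Segment(120.0, float(h), float(m), float(s)) for h, m, s in zip(hs, rrs, sds)
    )
    mid_h = np.linspace(1.05, 0.35, 8)
    mid_rr = np.linspace(800.0, 380.0, 8)
    mid_sd = np.geomspace(35.0, 4.0, 8)
    full_range = (
        (Segment(240.0, 1.15, 850.0, 40.0),)
        + tuple(Segment(120.0, float(h), float(m), float(s)) for h, m, s in zip(mid_h, mid_rr, mid_sd))
        + (Segment(240.0, 0.25, 340.0, 3.0),)
    )
    return {
        "clean_ramp": RampSpec(name="clean_ramp", segments=ramp_segments),
        "noisy_ramp": RampSpec(name="noisy_ramp", segments=ramp_segments, jitter_ms=4.0),
        "steady_low": RampSpec(
            name="steady_low", segments=(Segment(900.0, 1.05, 850.0, 40.0),)
        ),
        "anticorrelated_floor": RampSpec(
            name="anticorrelated_floor", segments=(Segment(600.0, 0.3, 350.0, 5.0),)
        ),
        "full_range_ramp": RampSpec(name="full_range_ramp", segments=full_range),
    }
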