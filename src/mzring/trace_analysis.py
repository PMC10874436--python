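"""Per-cell calcium fluorescence trace analysis.

Traces are expressed as 100 x dF/F0 (percent change about the temporal
mean of the raw trace). A slowly drifting baseline is estimated by
asymmetric least squares (ALS) — penalised smoothing in which points above
the running baseline are strongly down-weighted so that brief positive
transients do not pull the fit up — and subtracted. Spikes are then called
on the detrended trace: a moving-average smoothed copy supplies candidate
local maxima, small candidates are filtered out, and amplitude, peak time
and full width at half maximum (FWHM) are measured on the unsmoothed
detrended trace.

Default detection settings follow common practice for Cal520-type
recordings sampled every 3 s: ALS with asymmetry 0.001, roughness penalty
10^4, 10 iterations, convergence threshold 0.02; peak search with a
20-frame smoothing window, 5-point local-maximum test and a height filter
at 10 % of the trace maximum. An additional noise-adaptive floor
(``noise_floor_sigma`` times a robust noise estimate) suppresses spurious
local maxima of the smoothed noise; set it to 0 to disable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

DEFAULT_FRAME_INTERVAL_S = 3.0


@dataclass
class FluorescenceTrace:
    """A single cell's 100 x dF/F0 time series on a uniform frame grid."""

    times: np.ndarray
    values: np.ndarray
    cell_id: str = ""
    region: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if not (dt > 0).all():
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")
        if not np.isfinite(self.values).all():
            raise ValueError("trace values must be finite")

    @property
    def frame_interval(self) -> float:
        if self.times.size < 2:
            return DEFAULT_FRAME_INTERVAL_S
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0] + self.frame_interval)


@dataclass
class SpikeCall:
    """One detected calcium transient."""

    peak_time: float
    amplitude: float
    fwhm: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")


@dataclass
class TraceStats:
    """Firing statistics for one trace (or a pool of traces)."""

    frequency: float        # spikes per second, in mHz
    mean_amplitude: float | None
    n_spikes: int
    duration: float         # s


# ---------------------------------------------------------------------------
# normalisation and baseline
# ---------------------------------------------------------------------------

def compute_dff(raw: np.ndarray, times: np.ndarray | None = None,
                frame_interval: float = DEFAULT_FRAME_INTERVAL_S,
                cell_id: str = "", region: str = "unknown") -> FluorescenceTrace:
    """100 x (F - F0)/F0 with F0 the temporal mean of the raw trace.

    Invariant to multiplicative rescaling of the raw intensities.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ValueError("raw trace must be finite")
    f0 = raw.mean()
    if f0 <= 0:
        raise ValueError(f"F0 must be > 0, got {f0}")
    if times is None:
        times = np.arange(raw.size) * frame_interval
    values = 100.0 * (raw - f0) / f0
    return FluorescenceTrace(times=times, values=values,
                             cell_id=cell_id, region=region)


def als_baseline(values: np.ndarray, asym: float = 0.001, smooth: float = 4.0,
                 iterations: int = 10, threshold: float = 0.02) -> np.ndarray:
    """Asymmetric least squares baseline of a trace.

    Minimises  sum_i w_i (y_i - z_i)^2 + 10**smooth * sum |d2 z|^2  with
    w_i = asym for points above the current baseline and 1 - asym below,
    re-estimating the weights each iteration. Iteration stops after
    ``iterations`` rounds or when the fraction of weights that changed
    falls below ``threshold``.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError(f"trace too short for baseline estimation (n={n})")
    lam = 10.0 ** smooth
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = y.copy()
    for _ in range(iterations):
        W = sparse.diags(w)
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, asym, 1.0 - asym)
        changed = np.mean(w_new != w)
        w = w_new
        if changed < threshold:
            break
    return z


def subtract_baseline(trace: FluorescenceTrace, **als_kwargs) -> FluorescenceTrace:
    """Return the trace with its ALS baseline removed."""
    base = als_baseline(trace.values, **als_kwargs)
    return FluorescenceTrace(times=trace.times, values=trace.values - base,
                             cell_id=trace.cell_id, region=trace.region)


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the ends are averaged over real data only
    pad = window // 2
    padded = np.pad(values, pad, mode="reflect")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + values.size]
    return out


def _half_height_crossing(values: np.ndarray, peak: int, half: float,
                          direction: int) -> float | None:
    """Fractional index where the trace first crosses ``half``, walking from
    the peak in ``direction`` (+1 right / -1 left); None if it never does."""
    i = peak
    while 0 <= i + direction < values.size:
        j = i + direction
        if values[j] <= half:
            # linear interpolation between i and j
            if values[i] == values[j]:
                return float(j)
            frac = (values[i] - half) / (values[i] - values[j])
            return i + direction * frac
        i = j
    return None


def detect_spikes(detrended: FluorescenceTrace, smooth_window: int = 20,
                  local_points: int = 5, height_frac: float = 0.10,
                  noise_floor_sigma: float = 3.5) -> list[SpikeCall]:
    """Call transients on a baseline-corrected trace.

    Candidate peaks are local maxima of a moving-average smoothed copy
    that are the maximum of their ``local_points``-frame neighbourhood
    (ties broken toward the earlier frame). Two smoothing scales are
    scanned — the coarse ``smooth_window`` average for noise suppression
    and the fine ``local_points`` average so that transients closer
    together than the coarse window are still resolved — and each scale is
    gated by a noise floor of ``noise_floor_sigma`` times a
    median-absolute-deviation noise estimate scaled to that amount of
    averaging. Candidates are refined to the highest unsmoothed sample
    within half their smoothing window and deduplicated; amplitude is the
    unsmoothed detrended value at the refined peak, the FWHM is measured on
    the unsmoothed trace by linear interpolation at half height, and calls
    below ``height_frac`` of the trace maximum are discarded.
    """
    y = detrended.values
    n = y.size
    if n == 0:
        return []
    # centre on the median so a residual offset left by the asymmetric
    # baseline (which hugs the lower noise envelope) does not inflate heights
    y = y - np.median(y)
    if not (y > 0).any():
        return []
    dt = detrended.frame_interval
    half_nb = max(1, local_points // 2)
    # noise scale from first differences: transients are much slower than
    # frame-to-frame noise, so they barely inflate this estimate
    d = np.diff(y)
    sigma = np.median(np.abs(d - np.median(d))) / (0.6745 * np.sqrt(2.0))

    # Candidate peaks at two smoothing scales: the coarse window suppresses
    # noise; the fine (local_points) window resolves transients closer than
    # the coarse window. Each scale is gated by a noise floor matched to how
    # much averaging it applies.
    candidates: list[tuple[int, int]] = []   # (index, refine radius)
    for win in sorted({smooth_window, local_points}):
        smoothed = _moving_average(y, win)
        floor = noise_floor_sigma * sigma / np.sqrt(max(win, 1))
        refine = max(1, win // 2)
        for i in range(n):
            lo, hi = max(0, i - half_nb), min(n, i + half_nb + 1)
            window = smoothed[lo:hi]
            if smoothed[i] < window.max():
                continue
            if int(np.argmax(window)) + lo != i:   # earlier-frame tie break
                continue
            if smoothed[i] <= 0 or smoothed[i] < floor:
                continue
            candidates.append((i, refine))

    # Localise each candidate on the fine-smoothed trace (stable under
    # noise), then take the unsmoothed maximum in its immediate
    # neighbourhood; a wide unsmoothed argmax would let noise samples on a
    # transient's tail capture the peak.
    fine = _moving_average(y, local_points)
    peaks: set[int] = set()
    for c, refine in candidates:
        lo, hi = max(0, c - refine), min(n, c + refine + 1)
        p1 = lo + int(np.argmax(fine[lo:hi]))
        lo, hi = max(0, p1 - half_nb), min(n, p1 + half_nb + 1)
        peaks.add(lo + int(np.argmax(y[lo:hi])))

    # Greedy acceptance, tallest first. A lower peak within the exclusion
    # radius of an accepted one is a shoulder of the same transient; a later
    # peak that does not clearly exceed the decaying tail predicted from an
    # accepted call (plus the noise floor) is a noise bump riding on that
    # tail, not a separate spike.
    excl = max(half_nb, (smooth_window + 2) // 3)
    fine_floor = noise_floor_sigma * sigma / np.sqrt(max(local_points, 1))
    max_height = y.max()
    calls: list[SpikeCall] = []
    accepted: list[tuple[int, float, float]] = []   # (index, amp, fwhm)
    for peak in sorted(peaks, key=lambda p: -y[p]):
        if any(abs(peak - a) <= excl for a, _, _ in accepted):
            continue
        tail_veto = False
        for a, a_amp, tail_fwhm in accepted:
            delta_s = (peak - a) * dt
            if 0 < delta_s <= 4.0 * tail_fwhm:
                tail = a_amp * 2.0 ** (-delta_s / tail_fwhm)
                if y[peak] < 2.0 * tail + fine_floor:
                    tail_veto = True
                    break
        if tail_veto:
            continue
        amp = y[peak]
        if amp < height_frac * max_height or amp <= 0:
            continue
        half = amp / 2.0
        left = _half_height_crossing(y, peak, half, -1)
        right = _half_height_crossing(y, peak, half, +1)
        if left is None and right is None:
            continue
        if left is None:
            left = peak - (right - peak)
        if right is None:
            right = peak + (peak - left)
        fwhm = (right - left) * dt
        if fwhm <= 0:
            continue
        # Predicted-tail scale for the veto: a sharp-rise/slow-decay
        # transient carries nearly all its width to the right and its
        # measured FWHM underestimates the decay, so stretch the scale;
        # symmetric transients decay faster than exponential and need none.
        right_hw, left_hw = right - peak, peak - left
        tail_fwhm = fwhm * (1.3 if right_hw > 1.5 * left_hw else 1.0)
        accepted.append((peak, amp, tail_fwhm))
        calls.append(SpikeCall(peak_time=float(detrended.times[peak]),
                               amplitude=float(amp), fwhm=float(fwhm)))
    calls.sort(key=lambda s: s.peak_time)
    return calls


def trace_stats(spikes: list[SpikeCall], duration: float) -> TraceStats:
    """Firing frequency (mHz) and mean amplitude over a recording."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = len(spikes)
    freq = 1000.0 * n / duration
    mean_amp = float(np.mean([s.amplitude for s in spikes])) if n else None
    return TraceStats(frequency=freq, mean_amplitude=mean_amp,
                      n_spikes=n, duration=duration)
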