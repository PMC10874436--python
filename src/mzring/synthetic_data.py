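"""Seeded synthetic-data generators with ground truth.

The generators emulate the observable features of calcium imaging of the
pre-streak chick marginal zone: spontaneous per-cell spike trains at a few
mHz with ~15 s FWHM transients; spatially graded initiation of short
firing "tracks" that hop between neighbouring cells of an annular marginal
zone in random directions; and rendered image stacks with Gaussian spots
on a noisy background. Every generator is driven by a single integer seed
and returns the matching ground truth, so each analysis stage can be
benchmarked on data whose answer is known.

Defaults mirror the recording conditions the analyses were designed for:
200 frames at 3 s (10 min), ~5 mHz firing, 15 s FWHM transients, and an
annular marginal zone ~120 um wide at a ~1.5 mm radius with ~12 um cell
spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from mzring.trace_analysis import FluorescenceTrace


@dataclass
class SyntheticConfig:
    """Settings shared by all generators. Same seed, same output — always."""

    seed: int = 0
    n_cells: int = 100
    duration_s: float = 600.0
    frame_interval_s: float = 3.0
    # trace generator
    spike_rate_mhz: float = 5.0
    spike_amplitude_mean: float = 50.0
    spike_amplitude_sd: float = 10.0
    spike_fwhm_s: float = 15.0
    spike_shape: Literal["expdecay", "gaussian"] = "expdecay"
    noise_sd: float = 5.0
    min_isi_s: float | None = None
    drift_amplitude: float = 0.0
    drift_period_s: float = 600.0
    # annulus geometry (um)
    inner_radius_um: float = 1500.0
    outer_radius_um: float = 1620.0
    cell_spacing_um: float = 12.0
    arc_span_deg: float = 180.0
    # event-field generator
    track_init_rate: tuple[float, float] = (0.004, 0.0004)  # per cell per frame,
                                                            # ramp from arc start
    track_step_um: float = 30.0
    track_step_frames: int = 1
    track_mean_length: float = 5.0
    direction_rule: Literal["uniform-random"] = "uniform-random"

    def __post_init__(self) -> None:
        if self.spike_rate_mhz < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be >= 0")
        if any(r < 0 for r in self.track_init_rate):
            raise ValueError("track initiation rates must be >= 0")
        if self.track_step_um <= 0:
            raise ValueError("track_step_um must be > 0")
        if self.track_step_um < self.cell_spacing_um:
            raise ValueError(
                "geometry too sparse: track_step_um below the cell spacing "
                "leaves no neighbour to step to"
            )
        if self.frame_interval_s <= 0 or self.duration_s <= 0:
            raise ValueError("duration and frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))


@dataclass
class GroundTruth:
    """The generating truth behind one synthetic data set."""

    true_spikes: dict[str, list[dict]] = field(default_factory=dict)
    true_tracks: list[dict] = field(default_factory=list)
    true_region_counts: dict[str, int] = field(default_factory=dict)
    true_histogram_params: dict | None = None


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def _lognormal_amp(rng: np.random.Generator, config: SyntheticConfig) -> float:
    """Positive, right-skewed spike amplitude with the configured mean/sd."""
    mean, sd = config.spike_amplitude_mean, config.spike_amplitude_sd
    if mean <= 0:
        return 0.0
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return float(rng.lognormal(math.log(mean) - s2 / 2.0, math.sqrt(s2)))


def _transient(t: np.ndarray, t0: float, amp: float, fwhm: float,
               shape: str) -> np.ndarray:
    if shape == "gaussian":
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return amp * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    # fast rise, exponential decay; FWHM of this shape is tau * ln 2
    tau = fwhm / math.log(2.0)
    out = np.zeros_like(t)
    m = t >= t0
    out[m] = amp * np.exp(-(t[m] - t0) / tau)
    return out


def make_traces(config: SyntheticConfig) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Per-cell spike trains rendered as noisy 100 x dF/F0 traces.

    Spike times are Poisson at ``spike_rate_mhz`` (optionally with a
    refractory gap ``min_isi_s``); each spike adds a transient of the
    configured shape and FWHM with a log-normally distributed amplitude of
    the configured mean and sd; Gaussian noise and an optional
    photobleaching-like exponential baseline drift (initial height
    ``drift_amplitude``, time constant ``drift_period_s``) are added on top.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    times = np.arange(n_frames) * config.frame_interval_s
    rate = config.spike_rate_mhz / 1000.0  # spikes per second
    # leave a margin so every true transient is actually sampled
    t_max = config.duration_s - 2.0 * config.frame_interval_s
    traces: list[FluorescenceTrace] = []
    truth = GroundTruth()
    for c in range(config.n_cells):
        cell_id = f"cell{c:03d}"
        spike_times = []
        t = 0.0
        while rate > 0:
            gap = rng.exponential(1.0 / rate)
            if config.min_isi_s is not None:
                gap = max(gap, config.min_isi_s)
            t += gap
            if t > t_max:
                break
            spike_times.append(t)
        values = np.zeros(n_frames)
        spikes = []
        for t0 in spike_times:
            amp = _lognormal_amp(rng, config)
            values += _transient(times, t0, amp, config.spike_fwhm_s,
                                 config.spike_shape)
            spikes.append({"time": t0, "amplitude": amp,
                           "fwhm": config.spike_fwhm_s})
        if config.drift_amplitude:
            # photobleaching-style monotone baseline decay
            values += config.drift_amplitude * np.exp(-times / config.drift_period_s)
        if config.noise_sd:
            values += rng.normal(0.0, config.noise_sd, n_frames)
        traces.append(FluorescenceTrace(times=times, values=values,
                                        cell_id=cell_id, region="pMZ"))
        truth.true_spikes[cell_id] = spikes
    return traces, truth


# ---------------------------------------------------------------------------
# spatial firing-event fields
# ---------------------------------------------------------------------------

def _annulus_cells(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Cell positions (x, y in um) along the mid-annulus arc, plus the arc
    coordinate u in [0, 1] of each cell measured from the arc start."""
    r = 0.5 * (config.inner_radius_um + config.outer_radius_um)
    span = math.radians(config.arc_span_deg)
    n = max(2, int(round(r * span / config.cell_spacing_um)))
    theta = span * (np.arange(n) + 0.5) / n
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    u = (np.arange(n) + 0.5) / n
    return np.column_stack([x, y]), u


def make_event_field(config: SyntheticConfig) -> tuple[list[dict], GroundTruth]:
    """Propagating firing tracks on the annular marginal zone.

    Cells sit along the mid-annulus arc at the configured spacing. Each
    frame, cell ``i`` initiates a new track with probability ramping
    linearly along the arc between the two ``track_init_rate`` endpoints.
    A track emits one event per visited cell and hops every
    ``track_step_frames`` frames to a uniformly chosen neighbouring cell
    within ``track_step_um``; its number of events is geometric with mean
    ``track_mean_length`` (minimum 2). Events are returned as dicts with
    frame, time, x, y, intensity and the ground-truth track id.
    """
    rng = np.random.default_rng(config.seed + 1)
    pos, u = _annulus_cells(config)
    n_cells = pos.shape[0]
    lo, hi = config.track_init_rate
    p_init = lo + (hi - lo) * u
    # neighbour lists within the step radius
    neighbours: list[np.ndarray] = []
    for i in range(n_cells):
        d = np.linalg.norm(pos - pos[i], axis=1)
        nb = np.flatnonzero((d > 0) & (d <= config.track_step_um))
        neighbours.append(nb)
    if min(len(nb) for nb in neighbours) == 0:
        raise ValueError("geometry too sparse for the requested step length")

    events: list[dict] = []
    truth = GroundTruth()
    track_id = 0
    n_frames = config.n_frames
    for f0 in range(n_frames):
        fires = np.flatnonzero(rng.random(n_cells) < p_init)
        for cell in fires:
            length = 2 + rng.geometric(1.0 / max(config.track_mean_length - 1, 1.0))
            track_events = []
            here = int(cell)
            frame = f0
            for _ in range(length):
                if frame >= n_frames:
                    break
                amp = _lognormal_amp(rng, config)
                ev = {
                    "frame": frame,
                    "time": frame * config.frame_interval_s,
                    "x": float(pos[here, 0]), "y": float(pos[here, 1]),
                    "intensity": float(amp), "track_id": track_id,
                }
                track_events.append(ev)
                events.append(ev)
                here = int(rng.choice(neighbours[here]))
                frame += config.track_step_frames
            if track_events:
                truth.true_tracks.append({
                    "track_id": track_id,
                    "events": track_events,
                    "init_cell": int(cell),
                    "init_u": float(u[cell]),
                })
                track_id += 1
    events.sort(key=lambda e: (e["frame"], e["x"], e["y"]))
    return events, truth


def make_sparse_track_field(config: SyntheticConfig, n_tracks: int = 20,
                            track_length: int = 5,
                            min_separation_um: float = 120.0
                            ) -> tuple[list[dict], GroundTruth]:
    """A solvable tracking scenario: tracks confined to disjoint arc slots.

    Each track is restricted to its own arc slot, with slots spaced so that
    events of different tracks are always farther apart than
    ``min_separation_um`` — linking at a 90 um cutoff must then recover the
    ground truth exactly.
    """
    rng = np.random.default_rng(config.seed + 2)
    pos, u = _annulus_cells(config)
    n_cells = pos.shape[0]
    slot = n_cells // n_tracks
    # whole walks are confined to their slot minus this margin, so tracks in
    # neighbouring slots stay at least min_separation_um apart
    margin_cells = int(math.ceil(
        min_separation_um / 2.0 / config.cell_spacing_um))
    if slot < 2 * margin_cells + 2:
        raise ValueError(
            f"geometry too sparse: {n_tracks} tracks of length {track_length} "
            f"cannot be separated by {min_separation_um} um on this arc"
        )
    neighbours: list[np.ndarray] = []
    for i in range(n_cells):
        d = np.linalg.norm(pos - pos[i], axis=1)
        nb = np.flatnonzero((d > 0) & (d <= config.track_step_um))
        neighbours.append(nb)

    events: list[dict] = []
    truth = GroundTruth()
    n_frames = config.n_frames
    for k in range(n_tracks):
        lo_cell = k * slot + margin_cells
        hi_cell = (k + 1) * slot - margin_cells
        here = int(rng.integers(lo_cell, hi_cell))
        usable = range(lo_cell, hi_cell)
        frame = int(rng.integers(0, max(1, n_frames - track_length
                                        * config.track_step_frames)))
        track_events = []
        for _ in range(track_length):
            amp = _lognormal_amp(rng, config)
            ev = {"frame": frame, "time": frame * config.frame_interval_s,
                  "x": float(pos[here, 0]), "y": float(pos[here, 1]),
                  "intensity": float(amp), "track_id": k}
            track_events.append(ev)
            events.append(ev)
            options = [nb for nb in neighbours[here]
                       if nb in usable]
            here = int(rng.choice(options)) if options else here
            frame += config.track_step_frames
        truth.true_tracks.append({"track_id": k, "events": track_events,
                                  "init_cell": None, "init_u": float(u[here])})
    events.sort(key=lambda e: (e["frame"], e["x"], e["y"]))
    return events, truth


# ---------------------------------------------------------------------------
# rendered image stacks
# ---------------------------------------------------------------------------

def render_movie(events: list[dict], psf_sigma_um: float,
                 image_size: tuple[int, int], config: SyntheticConfig,
                 pixel_size_um: float = 4.0, background: float = 10.0,
                 background_sd: float = 1.0,
                 origin_um: tuple[float, float] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render events as Gaussian blobs over a noisy background.

    Returns ``(stack, average)`` where ``stack`` has one page per frame.
    Event coordinates (um) are mapped to pixels via ``pixel_size_um`` after
    shifting by ``origin_um`` (default: chosen so all events fit).
    """
    rng = np.random.default_rng(config.seed + 3)
    h, w = image_size
    n_frames = config.n_frames
    if origin_um is None:
        if events:
            xs = [e["x"] for e in events]
            ys = [e["y"] for e in events]
            origin_um = (min(xs) - 5 * psf_sigma_um, min(ys) - 5 * psf_sigma_um)
        else:
            origin_um = (0.0, 0.0)
    stack = rng.normal(background, background_sd,
                       size=(n_frames, h, w)).astype(np.float32)
    yy, xx = np.mgrid[0:h, 0:w]
    s_px = psf_sigma_um / pixel_size_um
    for e in events:
        if not 0 <= e["frame"] < n_frames:
            raise ValueError(f"event frame {e['frame']} outside the movie")
        cx = (e["x"] - origin_um[0]) / pixel_size_um
        cy = (e["y"] - origin_um[1]) / pixel_size_um
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("event outside image bounds")
        blob = e["intensity"] * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * s_px ** 2))
        stack[e["frame"]] += blob.astype(np.float32)
    return stack, stack.mean(axis=0)


# ---------------------------------------------------------------------------
# masks and intensity fields for sector-histogram tests
# ---------------------------------------------------------------------------

def make_annulus_mask(shape: tuple[int, int], center: tuple[float, float],
                      r_inner: float, r_outer: float) -> np.ndarray:
    """Boolean annulus mask in pixel units."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(yy - center[0], xx - center[1])
    return (r >= r_inner) & (r <= r_outer)


def make_lognormal_image(shape: tuple[int, int], mask: np.ndarray,
                         mu: float, sigma: float, seed: int = 0,
                         background: float = 0.0) -> np.ndarray:
    """Image whose masked pixels are log-normal(mu, sigma) draws."""
    rng = np.random.default_rng(seed)
    img = np.full(shape, background, dtype=float)
    img[mask] = rng.lognormal(mu, sigma, int(mask.sum()))
    return img
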