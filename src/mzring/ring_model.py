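"""Deterministic ring model of marginal-zone polarity.

The pre-streak chick marginal zone is represented as a one-dimensional ring
of ``n_cells`` cells (default 100) with periodic boundary conditions. Each
cell ``i`` carries three continuous variables — the streak-inhibiting
morphogen BMP4 (``B_i``), the streak-inducing ligand cVG1/GDF3 (``V_i``) and
a lumped "calcium activity" (``C_i``) — plus an irreversible binary streak
identity ``A_i``. The governing equations are

    dB_i/dt = k_B * P(C_i; alpha) - (gamma0 + gamma_C*C_i + gamma_V*V_i) * B_i
    dC_i/dt = k_C * A_i + D/dx**2 * (C_{i+1} + C_{i-1} - 2*C_i) - lambda * C_i
    dV_i/dt = k_V * Q(B_i; beta_V) - mu * V_i

where ``P`` is an increasing threshold function of calcium activity (BMP4
production requires a very low level of activity), ``Q`` a decreasing
threshold function of BMP4 (cVG1 is induced where BMP4 has fallen below
``beta_V``), and ``A_i`` latches to 1 the first time ``B_i`` drops to the
lower threshold ``beta_C`` (< ``beta_V``). Threshold functions are either
sharp Heaviside steps, with the boundary included in the "on" branch
(``H(0) = 1``), or smooth Hill functions with coefficient ``hill_n``.

Streak cells act as calcium sources; activity spreads rapidly to the
neighbouring cells through gap junctions (the discrete diffusion term) and
decays first-order. The resulting posterior-high activity gradient both
degrades BMP4 posteriorly and sustains its production anteriorly, locking in
a single posterior streak. Cutting out the posterior arc (the
``anterior_half`` scenario) removes every source, activity collapses, BMP4
decays everywhere, and a slightly oblique cut biases which edge of the
fragment reaches the commitment threshold first.

Integration is forward Euler with a small fixed step (default 1e-4 h);
t = 0 denotes the cut event, so intact-phase times are negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

logger = logging.getLogger("mzring")

PRODUCTION_MODES = ("heaviside", "hill")


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Rate constants, thresholds and discretisation settings.

    Units: concentrations and activities are arbitrary; time in hours;
    space in cell lengths. The defaults form the package's named reference
    set, calibrated so that (a) the initial gradient keeps BMP4 above
    ``beta_V`` anteriorly and below it posteriorly, and (b) the intact ring
    forms exactly one posterior streak while an obliquely cut anterior half
    repolarises to a single streak on its posterior-leaning edge. Users
    reproducing published timings should override these with the originally
    published values.
    """

    k_B: float = 0.6        # BMP4 production rate (conc/h)
    alpha: float = 3e-4     # calcium-activity threshold gating BMP4 production
    gamma0: float = 0.08    # basal BMP4 decay rate (1/h)
    gamma_C: float = 0.25   # calcium-dependent BMP4 decay (per activity per h)
    gamma_V: float = 0.6    # cVG1-dependent BMP4 decay (per conc per h)
    k_C: float = 12.0       # calcium-activity production in streak cells (activity/h)
    D: float = 4800.0       # calcium transmission coefficient (cell^2/h)
    dx: float = 1.0         # cell spacing (cell lengths)
    lambda_: float = 2.0    # calcium-activity decay rate (1/h)
    k_V: float = 1.0        # cVG1 production rate (conc/h)
    mu: float = 2.0         # cVG1 decay rate (1/h)
    beta_C: float = 0.4     # BMP4 threshold for streak commitment (conc)
    beta_V: float = 1.3     # BMP4 threshold for cVG1 induction (conc)
    n_cells: int = 100
    dt: float = 1e-4        # Euler step (h)
    production_mode: Literal["heaviside", "hill"] = "heaviside"
    hill_n: int = 4

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rates = {
            "k_B": self.k_B, "alpha": self.alpha, "gamma0": self.gamma0,
            "gamma_C": self.gamma_C, "gamma_V": self.gamma_V, "k_C": self.k_C,
            "D": self.D, "lambda_": self.lambda_, "k_V": self.k_V,
            "mu": self.mu, "beta_C": self.beta_C, "beta_V": self.beta_V,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.beta_V <= self.beta_C:
            raise ValueError(
                f"beta_V > beta_C is required (beta_V={self.beta_V}, "
                f"beta_C={self.beta_C})"
            )
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.dx <= 0:
            raise ValueError(f"dx must be > 0, got {self.dx}")
        if self.n_cells < 3:
            raise ValueError(f"n_cells must be >= 3, got {self.n_cells}")
        if self.D > 0 and self.dt > self.dx ** 2 / (2.0 * self.D):
            raise ValueError(
                f"explicit-scheme stability requires dt <= dx^2/(2 D) = "
                f"{self.dx ** 2 / (2.0 * self.D):.3g}, got dt={self.dt}"
            )
        if self.production_mode not in PRODUCTION_MODES:
            raise ValueError(f"production_mode must be one of {PRODUCTION_MODES}")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")


@dataclass
class RingState:
    """Instantaneous per-cell state of the ring (or cut segment).

    ``cells`` holds the original ring indices of the members, so edge cells
    remain identifiable after a cut. ``A`` is the latched streak identity;
    it never reverts from 1 to 0 within a simulation.
    """

    t: float
    B: np.ndarray
    C: np.ndarray
    V: np.ndarray
    A: np.ndarray
    topology: Literal["periodic", "segment"] = "periodic"
    cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.A = np.asarray(self.A, dtype=np.int8)
        n = self.B.size
        if not (self.C.size == self.V.size == self.A.size == n):
            raise ValueError("B, C, V, A must all have the same length")
        if self.cells is None:
            self.cells = np.arange(n)

    @property
    def n(self) -> int:
        return self.B.size

    def copy(self) -> "RingState":
        return RingState(
            t=self.t, B=self.B.copy(), C=self.C.copy(), V=self.V.copy(),
            A=self.A.copy(), topology=self.topology, cells=self.cells.copy(),
        )


@dataclass
class ScenarioConfig:
    """Which experiment to simulate and how to record it.

    The cut arc is given by inclusive ring indices running through the
    posterior pole (e.g. 90..9 removes cells 90..99 and 0..9);
    ``obliquity_offset`` shifts the whole arc by that many cells towards
    lower indices, leaving the lower-index edge of the remaining fragment
    more posterior (the "right side leaning posteriorly" bias). t = 0 is the
    cut; the intact phase occupies negative times.
    """

    scenario: Literal["intact", "anterior_half"] = "intact"
    pre_cut_duration: float = 5.0
    post_cut_duration: float = 14.0
    cut_left_index: int = 90
    cut_right_index: int = 9
    obliquity_offset: int = 2
    record_interval: float = 0.05

    def __post_init__(self) -> None:
        if self.scenario not in ("intact", "anterior_half"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.pre_cut_duration <= 0:
            raise ValueError("pre_cut_duration must be > 0")
        if self.scenario == "anterior_half":
            if self.post_cut_duration <= 0:
                raise ValueError("post_cut_duration must be > 0")
            if self.obliquity_offset == 0:
                raise ValueError(
                    "anterior_half requires a nonzero obliquity_offset"
                )
        if self.record_interval <= 0:
            raise ValueError("record_interval must be > 0")

    def resolved_cut_arc(self, n_cells: int) -> tuple[int, int]:
        """Cut arc endpoints after applying the obliquity offset (inclusive)."""
        left = (self.cut_left_index - self.obliquity_offset) % n_cells
        right = (self.cut_right_index - self.obliquity_offset) % n_cells
        return left, right


@dataclass
class SimulationRecord:
    """Snapshots, per-cell commitment times and summary streak arcs."""

    snapshots: list[RingState] = field(default_factory=list)
    events: dict[int, float] = field(default_factory=dict)
    streak_segments: list[dict] = field(default_factory=list)
    clamped_negatives: int = 0

    @property
    def final(self) -> RingState:
        if not self.snapshots:
            raise ValueError("record has no snapshots")
        return self.snapshots[-1]


# ---------------------------------------------------------------------------
# initial condition
# ---------------------------------------------------------------------------

def arc_distance_from_posterior(n_cells: int) -> np.ndarray:
    """Arc distance of each cell centre from the posterior pole, in cells.

    The posterior pole lies at the midpoint between cells ``n-1`` and ``0``;
    the anterior pole at the midpoint between cells ``n/2 - 1`` and ``n/2``.
    Cell centres therefore sit at half-integer distances: cells 0 and n-1 at
    0.5, cells n/2-1 and n/2 at n/2 - 0.5.
    """
    i = np.arange(n_cells)
    d = np.minimum(i + 0.5, n_cells - i - 0.5)
    return d


def init_intact_state(params: ModelParams) -> RingState:
    """Initial condition: shallow linear BMP4 gradient, nothing else.

    BMP4 runs linearly from 1.1 at the posterior pole flanks to 2.2 at the
    anterior flanks; cVG1, calcium activity and streak identity all start
    at zero.
    """
    n = params.n_cells
    d = arc_distance_from_posterior(n)
    d_min, d_max = d.min(), d.max()
    B = 1.1 + 1.1 * (d - d_min) / (d_max - d_min)
    zeros = np.zeros(n)
    return RingState(t=0.0, B=B, C=zeros.copy(), V=zeros.copy(),
                     A=np.zeros(n, dtype=np.int8))


# ---------------------------------------------------------------------------
# right-hand sides
# ---------------------------------------------------------------------------

def _production_up(C: np.ndarray, alpha: float, params: ModelParams) -> np.ndarray:
    """Increasing threshold function P(C; alpha); H(C - alpha) with H(0)=1."""
    if params.production_mode == "heaviside":
        return (C - alpha >= 0.0).astype(float)
    Cn = np.power(C, params.hill_n)
    return Cn / (alpha ** params.hill_n + Cn)


def _production_down(B: np.ndarray, beta: float, params: ModelParams) -> np.ndarray:
    """Decreasing threshold function Q(B; beta); H(beta - B) with H(0)=1."""
    if params.production_mode == "heaviside":
        return (beta - B >= 0.0).astype(float)
    bn = beta ** params.hill_n
    return bn / (bn + np.power(B, params.hill_n))


def laplacian(C: np.ndarray, topology: str) -> np.ndarray:
    """Discrete Laplacian C_{i+1} + C_{i-1} - 2 C_i.

    Periodic wrap on the intact ring; reflecting (no-flux) ghost cells at
    the two edges of a cut segment, since gap-junctional transmission
    cannot cross the wound.
    """
    lap = np.empty_like(C)
    lap[1:-1] = C[2:] + C[:-2] - 2.0 * C[1:-1]
    if topology == "periodic":
        lap[0] = C[1] + C[-1] - 2.0 * C[0]
        lap[-1] = C[0] + C[-2] - 2.0 * C[-1]
    else:
        lap[0] = C[1] - C[0]
        lap[-1] = C[-2] - C[-1]
    return lap


def dB_dt(state: RingState, params: ModelParams) -> np.ndarray:
    """BMP4 rate: activity-gated production minus basal/activity/cVG1 decay."""
    prod = params.k_B * _production_up(state.C, params.alpha, params)
    decay = (params.gamma0 + params.gamma_C * state.C
             + params.gamma_V * state.V) * state.B
    return prod - decay

def dC_dt(state: RingState, params: ModelParams) -> np.ndarray:
    """Calcium-activity rate: streak-cell source, transmission, decay."""
    return (params.k_C * state.A
            + (params.D / params.dx ** 2) * laplacian(state.C, state.topology)
            - params.lambda_ * state.C)

def dV_dt(state: RingState, params: ModelParams) -> np.ndarray:
    """cVG1 rate: production where BMP4 is below beta_V, first-order decay."""
    prod = params.k_V * _production_down(state.B, params.beta_V, params)
    return prod - params.mu * state.V


def update_latch(state: RingState, params: ModelParams) -> RingState:
    """Set streak identity wherever BMP4 has reached beta_C; never unset."""
    state.A |= (state.B <= params.beta_C)
    return state


def euler_step(state: RingState, params: ModelParams,
               clamp_counter: list[int] | None = None) -> RingState:
    """Advance the state by one forward-Euler step, in place.

    Negative concentrations produced by discretisation undershoot are
    clamped to zero (and counted in ``clamp_counter[0]`` when given).
    Non-finite values abort with diagnostics.
    """
    dB = dB_dt(state, params)
    dC = dC_dt(state, params)
    dV = dV_dt(state, params)
    state.B += params.dt * dB
    state.C += params.dt * dC
    state.V += params.dt * dV
    neg = 0
    for arr in (state.B, state.C, state.V):
        m = arr < 0.0
        if m.any():
            neg += int(m.sum())
            arr[m] = 0.0
    if neg and clamp_counter is not None:
        clamp_counter[0] += neg
    if not (np.isfinite(state.B).all() and np.isfinite(state.C).all()
            and np.isfinite(state.V).all()):
        raise FloatingPointError(
            f"non-finite state at t={state.t + params.dt:.6f} h "
            f"(max |B|={np.abs(state.B).max():.3g}, "
            f"|C|={np.abs(state.C).max():.3g}, "
            f"|V|={np.abs(state.V).max():.3g})"
        )
    update_latch(state, params)
    state.t += params.dt
    return state


# ---------------------------------------------------------------------------
# the cut
# ---------------------------------------------------------------------------

def apply_anterior_half_cut(state: RingState, config: ScenarioConfig) -> RingState:
    """Excise the posterior arc, leaving an open anterior fragment.

    The removed arc (inclusive, wrapping through the posterior pole) must
    contain every committed cell. The remaining cells form a segment with
    no-flux edges; with a positive obliquity offset the first (lower-index)
    edge cell sits closer to the posterior pole and carries less BMP4. The
    cut defines t = 0.
    """
    if state.topology != "periodic":
        raise ValueError("cut can only be applied to an intact ring")
    n = state.n
    left, right = config.resolved_cut_arc(n)
    if left <= right:
        removed = np.arange(left, right + 1)
    else:
        removed = np.concatenate([np.arange(left, n), np.arange(0, right + 1)])
    removed_set = set(removed.tolist())
    committed = np.flatnonzero(state.A == 1)
    outside = [int(c) for c in committed if int(c) not in removed_set]
    if outside:
        raise ValueError(
            f"cut arc {left}..{right} does not cover streak cells {outside}"
        )
    # order the segment from the edge just after the removed arc
    start = (right + 1) % n
    keep = np.array(
        [(start + k) % n for k in range(n) if (start + k) % n not in removed_set]
    )
    return RingState(
        t=0.0,
        B=state.B[keep].copy(), C=state.C[keep].copy(),
        V=state.V[keep].copy(), A=state.A[keep].copy(),
        topology="segment", cells=state.cells[keep].copy(),
    )


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

def simulate(config: ScenarioConfig, params: ModelParams) -> SimulationRecord:
    """Run a full scenario, recording snapshots and commitment events.

    The intact phase runs on t in [-pre_cut_duration, 0]; the
    ``anterior_half`` scenario then applies the cut and continues on
    [0, post_cut_duration]. Snapshots are stored every ``record_interval``
    hours (plus phase endpoints); events map original cell index to the
    first time its streak latch switched on. Fully deterministic.
    """
    record = SimulationRecord()
    clamp = [0]
    state = init_intact_state(params)
    state.t = -config.pre_cut_duration

    def run_phase(state: RingState, t_end: float) -> RingState:
        n_steps = int(round((t_end - state.t) / params.dt))
        rec_every = max(1, int(round(config.record_interval / params.dt)))
        record.snapshots.append(state.copy())
        prev_A = state.A.copy()
        for step in range(1, n_steps + 1):
            euler_step(state, params, clamp)
            new = state.A & ~prev_A
            if new.any():
                for c in state.cells[new.astype(bool)]:
                    record.events.setdefault(int(c), state.t)
                prev_A = state.A.copy()
            if step % rec_every == 0 or step == n_steps:
                record.snapshots.append(state.copy())
        return state

    state = run_phase(state, 0.0)
    if config.scenario == "anterior_half":
        state = apply_anterior_half_cut(state, config)
        state = run_phase(state, config.post_cut_duration)
    record.clamped_negatives = clamp[0]
    if clamp[0]:
        logger.warning("clamped %d negative values to zero", clamp[0])
    record.streak_segments = detect_streak_segments(record)
    return record


def detect_streak_segments(record: SimulationRecord) -> list[dict]:
    """Maximal contiguous streak arcs in the final snapshot.

    Returns one dict per arc with the member cells (original ring indices,
    in ring order), span in cells, and onset time (earliest commitment among
    members, if recorded). On a periodic ring an arc may wrap across the
    index seam.
    """
    final = record.final
    A = final.A.astype(bool)
    n = A.size
    if not A.any():
        return []
    if A.all():
        members = list(final.cells)
        runs = [list(range(n))]
    else:
        runs = []
        current: list[int] = []
        for i in range(n):
            if A[i]:
                current.append(i)
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
        # wrap-around merge on the periodic ring
        if (final.topology == "periodic" and len(runs) > 1
                and runs[0][0] == 0 and runs[-1][-1] == n - 1):
            runs[0] = runs.pop() + runs[0]
    segments = []
    for run in runs:
        members = [int(final.cells[i]) for i in run]
        onsets = [record.events[c] for c in members if c in record.events]
        segments.append({
            "cells": members,
            "span": len(members),
            "onset": min(onsets) if onsets else None,
        })
    segments.sort(key=lambda s: -s["span"])
    return segments


# ---------------------------------------------------------------------------
# transmission-speed arithmetic
# ---------------------------------------------------------------------------

def transmission_speed_bound(diameter_cells: float = 240.0,
                             window_h: float = 5.0) -> dict:
    """Lower bound on signal speed along the marginal zone.

    A pre-streak blastoderm (area pellucida plus marginal zone) about
    ``diameter_cells`` cell lengths across has a marginal-zone
    half-circumference of pi * d / 2 — roughly 380 cell lengths. A
    positional signal that traverses it within ``window_h`` hours must
    therefore travel at >= ~380 / (window_h * 60) cells per minute
    (about 1.27 cells/min for the defaults).

    Returns the exact half-circumference, its round figure (nearest ten
    cells), and the minimum speed implied by the round figure.
    """
    half = math.pi * diameter_cells / 2.0
    half_round = round(half, -1)
    speed = half_round / (window_h * 60.0)
    return {
        "half_circumference_cells": half,
        "half_circumference_rounded": half_round,
        "min_speed_cells_per_min": speed,
    }
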