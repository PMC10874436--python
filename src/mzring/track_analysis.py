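"""Linking calcium firing events into intercellular tracks and
quantifying their geometry.

Firing events (frame, time, x, y, intensity) are linked frame-to-frame by
solving a linear assignment problem (LAP) with squared-distance costs and a
hard distance cutoff (default 90 um), as in LAP/TrackMate-style particle
tracking. Track fragments whose end and start fall within the cutoff and
within a small frame gap are then merged (gap closing), and an unmatched
event next to an already-linked source may start a branch track (splitting).
Tracks are summarised by duration (last minus first event time) and by the
quadrant of their net displacement direction; temporal-average images of
activity are summarised per marginal-zone sector by histogram analysis with
a log-normal fit.

Coordinates are treated as plain Cartesian micrometres; callers working in
image convention (y down) should flip y before computing angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, linear_sum_assignment
from scipy.stats import lognorm

QUADRANT_LABELS = ("Q1", "Q2", "Q3", "Q4")   # [0,90), [90,180), [180,270), [270,360)


@dataclass
class FiringEvent:
    """A single firing detection."""

    frame: int
    time: float
    x: float
    y: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class Track:
    """A time-ordered chain of linked firing events."""

    events: list[FiringEvent]
    track_id: int = -1
    parent_id: int | None = None   # source track when this is a split branch

    def __post_init__(self) -> None:
        frames = [e.frame for e in self.events]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("event frames must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def is_singleton(self) -> bool:
        return len(self.events) < 2

    @property
    def start(self) -> np.ndarray:
        return self.events[0].pos

    @property
    def end(self) -> np.ndarray:
        return self.events[-1].pos


def track_duration(track: Track) -> float:
    """Lifetime of a track in seconds (last event time minus first)."""
    if track.is_singleton:
        raise ValueError("duration is undefined for singleton tracks")
    return track.events[-1].time - track.events[0].time


def track_angle(track: Track) -> float | None:
    """Net displacement direction in degrees in [0, 360); None if the
    start and end positions coincide."""
    d = track.end - track.start
    if d[0] == 0.0 and d[1] == 0.0:
        return None
    return float(np.degrees(np.arctan2(d[1], d[0])) % 360.0)


def angle_class(track: Track) -> str | None:
    """Quadrant of the net displacement: Q1 [0,90) ... Q4 [270,360).

    Boundary angles belong to the higher quadrant's lower edge (half-open
    bins), so 0 deg is Q1 and 90 deg is Q2. Zero-displacement tracks return
    None and are counted separately by callers.
    """
    angle = track_angle(track)
    if angle is None:
        return None
    return QUADRANT_LABELS[int(angle // 90.0) % 4]


# ---------------------------------------------------------------------------
# LAP linking
# ---------------------------------------------------------------------------

def _assign_pairs(sources: list[FiringEvent], targets: list[FiringEvent],
                  max_dist: float) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two event sets.

    Squared-distance costs with the standard LAP birth/death augmentation:
    every source (target) can instead link to a dummy at the cutoff cost,
    so no pair farther apart than ``max_dist`` is ever linked.
    """
    n, m = len(sources), len(targets)
    if n == 0 or m == 0:
        return []
    sp = np.array([[e.x, e.y] for e in sources])
    tp = np.array([[e.x, e.y] for e in targets])
    d2 = ((sp[:, None, :] - tp[None, :, :]) ** 2).sum(axis=2)
    cutoff2 = max_dist ** 2
    big = 4.0 * cutoff2 + 1.0
    cost = np.full((n + m, m + n), big)
    cost[:n, :m] = np.where(d2 <= cutoff2, d2, big)
    alt = 1.05 * cutoff2
    cost[np.arange(n) + 0, np.arange(n) + m] = alt        # source death
    cost[np.arange(m) + n, np.arange(m) + 0] = alt        # target birth
    cost[n:, m:] = 0.0                                    # dummy-dummy
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < n and c < m and d2[r, c] <= cutoff2]


def link_events(events: list[FiringEvent], max_link: float = 90.0,
                gap_frames: int = 2, gap_distance: float = 90.0,
                split_distance: float | None = 90.0) -> list[Track]:
    """Link firing events into tracks.

    Frame-to-frame links are solved per consecutive frame pair as a
    minimum-cost assignment with a ``max_link`` cutoff. Fragments whose end
    and start are within ``gap_distance`` and separated by 2..``gap_frames``
    frames are merged (gap closing). When ``split_distance`` is set, an
    event left unmatched in a frame but lying within that distance of an
    already-linked source in the previous frame starts a new branch track
    whose ``parent_id`` records the source track; every event still belongs
    to exactly one track. Events that remain alone form singleton tracks.
    """
    if not events:
        return []
    order = sorted(range(len(events)), key=lambda i: events[i].frame)
    by_frame: dict[int, list[int]] = {}
    for i in order:
        by_frame.setdefault(events[i].frame, []).append(i)
    frames = sorted(by_frame)

    # frame-to-frame assignment
    next_link: dict[int, int] = {}
    prev_link: dict[int, int] = {}
    for f0, f1 in zip(frames, frames[1:]):
        if f1 - f0 != 1:
            continue
        src = [events[i] for i in by_frame[f0]]
        tgt = [events[i] for i in by_frame[f1]]
        for r, c in _assign_pairs(src, tgt, max_link):
            i, j = by_frame[f0][r], by_frame[f1][c]
            next_link[i] = j
            prev_link[j] = i

    # assemble fragments
    fragments: list[list[int]] = []
    for i in order:
        if i in prev_link:
            continue
        chain = [i]
        while chain[-1] in next_link:
            chain.append(next_link[chain[-1]])
        fragments.append(chain)

    # gap closing between fragment ends and starts (optimal assignment on
    # squared distance among admissible end/start pairs)
    ends = [frag[-1] for frag in fragments]
    starts = [frag[0] for frag in fragments]
    admissible: list[tuple[int, int, float]] = []
    for a, e_i in enumerate(ends):
        for b, s_j in enumerate(starts):
            if a == b:
                continue
            df = events[s_j].frame - events[e_i].frame
            if not 2 <= df <= max(2, gap_frames):
                continue
            dist = float(np.hypot(events[s_j].x - events[e_i].x,
                                  events[s_j].y - events[e_i].y))
            if dist <= gap_distance:
                admissible.append((a, b, dist))
    merged_into: dict[int, int] = {}
    if admissible:
        a_idx = sorted({a for a, _, _ in admissible})
        b_idx = sorted({b for _, b, _ in admissible})
        big = 4.0 * gap_distance ** 2 + 1.0
        cost = np.full((len(a_idx), len(b_idx)), big)
        for a, b, dist in admissible:
            cost[a_idx.index(a), b_idx.index(b)] = dist ** 2
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < big:
                merged_into[b_idx[c]] = a_idx[r]

    def root(b: int) -> int:
        while b in merged_into:
            b = merged_into[b]
        return b

    chains: dict[int, list[int]] = {}
    for b in sorted(range(len(fragments)),
                    key=lambda b: events[fragments[b][0]].frame):
        chains.setdefault(root(b), []).extend(fragments[b])

    tracks: list[Track] = []
    event_track: dict[int, int] = {}
    for chain in chains.values():
        chain.sort(key=lambda i: events[i].frame)
        tid = len(tracks)
        for i in chain:
            event_track[i] = tid
        tracks.append(Track(events=[events[i] for i in chain], track_id=tid))

    # splitting: a singleton that sits within split_distance of a linked
    # source one frame earlier becomes a branch of that source's track
    if split_distance is not None:
        for t in tracks:
            if not t.is_singleton:
                continue
            e = t.events[0]
            best = None
            for i, src in enumerate(events):
                if src.frame != e.frame - 1 or i not in next_link:
                    continue
                dist = float(np.hypot(e.x - src.x, e.y - src.y))
                if dist <= split_distance and (best is None or dist < best[0]):
                    best = (dist, event_track[i])
            if best is not None:
                t.parent_id = best[1]
    return tracks


def quadrant_counts(tracks: list[Track]) -> dict[str, int]:
    """Number of classified tracks per displacement quadrant.

    Singletons and zero-displacement tracks are tallied under
    ``unclassified``.
    """
    counts = {q: 0 for q in QUADRANT_LABELS}
    counts["unclassified"] = 0
    for t in tracks:
        if t.is_singleton:
            counts["unclassified"] += 1
            continue
        q = angle_class(t)
        if q is None:
            counts["unclassified"] += 1
        else:
            counts[q] += 1
    return counts


# ---------------------------------------------------------------------------
# sector histogram analysis
# ---------------------------------------------------------------------------

@dataclass
class SectorHistogram:
    """Histogram analysis of one marginal-zone sector of an average image."""

    sector: str
    bin_edges: np.ndarray
    counts: np.ndarray
    lognormal_params: dict | None    # {"mu", "sigma", "scale"} or None if no fit
    above_threshold_count: int
    peak_centre: float | None
    fit_error: str | None = None


def _lognormal_curve(x: np.ndarray, area: float, mu: float, sigma: float) -> np.ndarray:
    return area * lognorm.pdf(x, s=sigma, scale=np.exp(mu))


def sector_histogram(avg_image: np.ndarray, mz_mask: np.ndarray,
                     n_sectors: int = 4, threshold: float = 6.0,
                     n_bins: int = 64, start_angle_deg: float = 0.0,
                     center: tuple[float, float] | None = None
                     ) -> list[SectorHistogram]:
    """Per-sector intensity histograms of an average image with log-normal fits.

    The masked marginal-zone annulus (or arc) is divided into ``n_sectors``
    equal angular sectors about its centroid, starting from
    ``start_angle_deg`` (sector s1 first — by convention nearest the cut
    edge). Each sector's pixel intensities are histogrammed, a log-normal
    curve is fitted to the histogram by least squares, pixels above
    ``threshold`` are counted, and the fitted mode (peak centre,
    exp(mu - sigma^2)) is reported. A failed fit is reported per sector
    rather than raised.
    """
    if avg_image.shape != mz_mask.shape:
        raise ValueError("image and mask shapes differ")
    mask = mz_mask.astype(bool)
    if not mask.any():
        raise ValueError("empty marginal-zone mask")
    yy, xx = np.nonzero(mask)
    if center is None:
        center = (float(yy.mean()), float(xx.mean()))
    theta = np.degrees(np.arctan2(yy - center[0], xx - center[1]))
    theta = (theta - start_angle_deg) % 360.0
    span = 360.0
    present = np.sort(theta)
    # if the mask is an arc, measure its angular extent instead
    if present.size:
        gaps = np.diff(np.concatenate([present, present[:1] + 360.0]))
        widest = np.argmax(gaps)
        if gaps[widest] > 30.0:   # arc, not a full ring
            start = present[(widest + 1) % present.size]
            theta = (theta - start) % 360.0
            span = 360.0 - gaps[widest]
    results: list[SectorHistogram] = []
    for s in range(n_sectors):
        lo, hi = span * s / n_sectors, span * (s + 1) / n_sectors
        sel = (theta >= lo) & (theta < hi) if s < n_sectors - 1 else \
              (theta >= lo) & (theta <= hi)
        pix = avg_image[yy[sel], xx[sel]].astype(float)
        name = f"s{s + 1}"
        if pix.size == 0:
            raise ValueError(f"sector {name} contains no pixels")
        counts, edges = np.histogram(pix, bins=n_bins)
        centres = 0.5 * (edges[:-1] + edges[1:])
        params = None
        peak = None
        err = None
        positive = pix[pix > 0]
        if positive.size >= 10 and np.ptp(positive) > 0:
            mu0 = float(np.log(np.median(positive)))
            sig0 = max(float(np.std(np.log(positive))), 1e-3)
            try:
                popt, _ = curve_fit(
                    _lognormal_curve, centres, counts,
                    p0=[pix.size * (edges[1] - edges[0]), mu0, sig0],
                    maxfev=5000)
                area, mu, sigma = popt
                sigma = abs(float(sigma))
                params = {"area": float(area), "mu": float(mu), "sigma": sigma}
                peak = float(np.exp(mu - sigma ** 2))
                if not (edges[0] <= peak <= edges[-1]):
                    peak = float(np.clip(peak, edges[0], edges[-1]))
            except (RuntimeError, ValueError) as e:
                err = str(e)
        else:
            err = "degenerate sector intensities"
        results.append(SectorHistogram(
            sector=name, bin_edges=edges, counts=counts,
            lognormal_params=params,
            above_threshold_count=int((pix > threshold).sum()),
            peak_centre=peak, fit_error=err))
    return results


# ---------------------------------------------------------------------------
# active-cell counting
# ---------------------------------------------------------------------------

def count_active_cells(events: list[FiringEvent],
                       region_masks: dict[str, np.ndarray],
                       pixel_size_um: float = 1.0,
                       cluster_radius_um: float = 13.0,
                       origin_um: tuple[float, float] = (0.0, 0.0)
                       ) -> dict[str, int]:
    """Distinct firing cells per region.

    Events are assigned to regions through boolean masks (pixel space,
    ``pixel_size_um`` per pixel; masks must not overlap), then clustered by
    single linkage at ``cluster_radius_um`` — one blob diameter — so that
    repeated firing of the same cell counts once.
    """
    names = list(region_masks)
    shapes = {region_masks[n].shape for n in names}
    if len(shapes) > 1:
        raise ValueError("region masks must share one shape")
    total = None
    for n in names:
        m = region_masks[n].astype(bool)
        if total is None:
            total = m.astype(int)
        else:
            total = total + m.astype(int)
    if total is not None and (total > 1).any():
        raise ValueError("region masks overlap")

    counts = {n: 0 for n in names}
    by_region: dict[str, list[np.ndarray]] = {n: [] for n in names}
    for e in events:
        col = int((e.x - origin_um[0]) / pixel_size_um)
        row = int((e.y - origin_um[1]) / pixel_size_um)
        for n in names:
            m = region_masks[n]
            if 0 <= row < m.shape[0] and 0 <= col < m.shape[1] and m[row, col]:
                by_region[n].append(e.pos)
                break
    for n in names:
        pts = by_region[n]
        if not pts:
            continue
        pts = np.array(pts)
        # single-linkage union-find at the cluster radius
        parent = list(range(len(pts)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pts)):
            d = np.linalg.norm(pts[i + 1:] - pts[i], axis=1)
            for j in np.flatnonzero(d <= cluster_radius_um) + i + 1:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[rj] = ri
        counts[n] = len({find(i) for i in range(len(pts))})
    return counts
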