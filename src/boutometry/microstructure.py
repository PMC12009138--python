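"""Feeding-microstructure analysis of lick trains.

The consummatory unit here is the *bout*: a run of licks uninterrupted
by an inter-lick interval (ILI) exceeding a threshold.  The threshold
is derived from behavior rather than fixed a priori: the food zone (FZ)
is the region within one body length of the spout (the 95th percentile
of the mouth-to-tail-base distance), food-zone times (FZT) are the
dwell intervals inside it, and the bout-defining ILI threshold is the
lower decile of FZT durations — the idea being that a bout ends when
the animal leaves the food zone.

All percentiles and quantiles use the nearest-rank (inclusive) method,
which is exact on small samples and free of interpolation ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .session_io import LickSession, SessionConfig, ValidationError

BOUT_COLUMNS = [
    "start_s",
    "end_s",
    "duration_s",
    "n_licks",
    "block_index",
    "block_label",
    "spans_block",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PoseTrack:
    """Pose key points over time: mouth and tail-base plus the fixed spout.

    Coordinates are in cm; ``frame_times_s`` are strictly increasing at
    the nominal pose frame rate (30 frames/s by default).
    """

    frame_times_s: np.ndarray
    mouth_xy: np.ndarray  # (n, 2)
    tailbase_xy: np.ndarray  # (n, 2)
    spout_xy: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.mouth_xy = np.asarray(self.mouth_xy, dtype=float)
        self.tailbase_xy = np.asarray(self.tailbase_xy, dtype=float)
        self.spout_xy = np.asarray(self.spout_xy, dtype=float)
        n = self.frame_times_s.size
        if self.mouth_xy.shape != (n, 2) or self.tailbase_xy.shape != (n, 2):
            raise ValidationError("pose coordinate arrays must be (n_frames, 2)")
        if n > 1 and np.any(np.diff(self.frame_times_s) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        for arr in (self.frame_times_s, self.mouth_xy, self.tailbase_xy, self.spout_xy):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("pose coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times_s.size)

    def body_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.mouth_xy - self.tailbase_xy, axis=1)

    def mouth_spout_distances(self) -> np.ndarray:
        return np.linalg.norm(self.mouth_xy - self.spout_xy[None, :], axis=1)


@dataclass
class FZInterval:
    """One food-zone dwell interval, half-open ``[enter_s, exit_s)``."""

    enter_s: float
    exit_s: float
    at_edge: bool = False

    @property
    def duration_s(self) -> float:
        return self.exit_s - self.enter_s


@dataclass
class FoodZoneParams:
    """Food-zone geometry and the bout threshold derived from it."""

    radius_cm: float
    percentile_q: float = 0.95
    fzt_intervals: list[FZInterval] = field(default_factory=list)
    ili_threshold_s: float | None = None
    threshold_q: float = 0.10

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValidationError("radius_cm must be > 0")
        if self.ili_threshold_s is not None and self.ili_threshold_s <= 0:
            raise ValidationError("ili_threshold_s must be > 0")
        for iv in self.fzt_intervals:
            if iv.exit_s <= iv.enter_s:
                raise ValidationError("every FZT interval must have exit > enter")


@dataclass
class BoutTable:
    """Per-bout segmentation results plus session-level scalars.

    ``frame`` has one row per bout with columns ``start_s, end_s,
    duration_s, n_licks, block_index, block_label, spans_block``.
    Duration is last-lick minus first-lick time.  ``block_index`` is -1
    until blocks are assigned.
    """

    frame: pd.DataFrame
    ili_threshold_s: float | None = None
    fundamental_lick_interval_s: float | None = None
    n_discarded_licks: int = 0

    def __post_init__(self) -> None:
        if list(self.frame.columns) != BOUT_COLUMNS:
            self.frame = self.frame.reindex(columns=BOUT_COLUMNS)
        if len(self.frame):
            if (self.frame["duration_s"] < -1e-12).any():
                raise ValidationError("bout durations must be >= 0")
            starts = self.frame["start_s"].to_numpy()
            ends = self.frame["end_s"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError("bouts must be disjoint and ordered")

    @property
    def n_bouts(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# food zone and threshold
# ---------------------------------------------------------------------------


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Nearest-rank (inclusive) q-quantile: the ceil(q*n)-th order statistic."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot take a quantile of an empty sample")
    if not 0 < q <= 1:
        raise ValidationError("q must lie in (0, 1]")
    rank = max(1, math.ceil(q * values.size))
    return float(np.sort(values)[rank - 1])


def food_zone_radius(pose: PoseTrack, q: float = 0.95) -> float:
    """Food-zone radius: q-th percentile of mouth-to-tail-base distances."""
    if pose.n_frames == 0:
        raise ValidationError("empty pose track")
    return nearest_rank_quantile(pose.body_lengths(), q)


def food_zone_times(pose: PoseTrack, radius_cm: float) -> list[FZInterval]:
    """Dwell intervals with the mouth inside the food zone.

    A dwell is a maximal run of consecutive frames with mouth-to-spout
    distance strictly below ``radius_cm``, converted to a half-open time
    interval ending at the first out-of-zone frame.  Runs touching the
    track edges are kept and flagged; the final frame's exit time is
    extrapolated by the median inter-frame interval.
    """
    if radius_cm <= 0:
        raise ValidationError("radius_cm must be > 0")
    inside = pose.mouth_spout_distances() < radius_cm
    t = pose.frame_times_s
    n = inside.size
    if n == 0:
        return []
    dt = float(np.median(np.diff(t))) if n > 1 else 1.0 / 30.0
    intervals: list[FZInterval] = []
    i = 0
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and inside[j + 1]:
            j += 1
        exit_s = t[j + 1] if j + 1 < n else t[-1] + dt
        intervals.append(
            FZInterval(float(t[i]), float(exit_s), at_edge=(i == 0 or j == n - 1))
        )
        i = j + 1
    return intervals


def derive_food_zone_params(
    pose: PoseTrack,
    percentile_q: float = 0.95,
    threshold_q: float = 0.10,
) -> FoodZoneParams:
    """Run the full food-zone workflow: radius, dwell intervals, threshold."""
    radius = food_zone_radius(pose, percentile_q)
    fzt = food_zone_times(pose, radius)
    threshold = (
        ili_threshold([iv.duration_s for iv in fzt], threshold_q) if fzt else None
    )
    return FoodZoneParams(
        radius_cm=radius,
        percentile_q=percentile_q,
        fzt_intervals=fzt,
        ili_threshold_s=threshold,
        threshold_q=threshold_q,
    )


def ili_threshold(fzt_durations: Sequence[float], q: float = 0.10) -> float:
    """Bout-defining ILI threshold: nearest-rank q-quantile of FZT durations."""
    durations = np.asarray(fzt_durations, dtype=float)
    if durations.size == 0:
        raise ValidationError("no FZT durations supplied")
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    return nearest_rank_quantile(durations, q)


# ---------------------------------------------------------------------------
# bout segmentation
# ---------------------------------------------------------------------------


def segment_bouts(
    session: LickSession,
    ili_threshold_s: float,
    min_licks: int = 2,
) -> BoutTable:
    """Split a lick train into bouts at ILIs strictly greater than threshold.

    An ILI exactly equal to the threshold continues the bout.  Runs with
    fewer than ``min_licks`` licks are dropped from the table but
    counted in the discarded-lick tally (single-lick runs have zero
    duration, which makes every duration-based metric degenerate; the
    default therefore requires 2 licks and is configurable down to 1).
    """
    if ili_threshold_s <= 0:
        raise ValidationError("ili_threshold_s must be > 0")
    if min_licks < 1:
        raise ValidationError("min_licks must be >= 1")
    times = session.lick_times_s
    rows = []
    discarded = 0
    if times.size:
        breaks = np.flatnonzero(np.diff(times) > ili_threshold_s)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [times.size - 1]])
        for a, b in zip(starts, ends):
            n = int(b - a + 1)
            if n < min_licks:
                discarded += n
                continue
            rows.append(
                {
                    "start_s": float(times[a]),
                    "end_s": float(times[b]),
                    "duration_s": float(times[b] - times[a]),
                    "n_licks": n,
                    "block_index": -1,
                    "block_label": "",
                    "spans_block": False,
                }
            )
    frame = pd.DataFrame(rows, columns=BOUT_COLUMNS)
    if not rows:
        frame = frame.astype(
            {"start_s": float, "end_s": float, "duration_s": float, "n_licks": int,
             "block_index": int, "block_label": str, "spans_block": bool}
        )
    return BoutTable(frame=frame, ili_threshold_s=float(ili_threshold_s),
                     n_discarded_licks=discarded)


def fundamental_lick_interval(
    session: LickSession,
    bin_width_s: float = 0.01,
    max_ili_s: float = 1.0,
) -> float:
    """Mode of the ILI distribution: the fundamental lick-oscillator interval.

    The histogram uses 10-ms bins on (0, ``max_ili_s``]; the returned
    value is the center of the maximal-count bin, with ties broken
    toward the smallest bin center.
    """
    if session.n_licks < 2:
        raise ValidationError("at least 2 licks are required to compute ILIs")
    ilis = session.interlick_intervals()
    ilis = ilis[(ilis > 0) & (ilis <= max_ili_s)]
    if ilis.size == 0:
        raise ValidationError(f"no ILIs in (0, {max_ili_s}] s")
    edges = np.arange(0.0, max_ili_s + bin_width_s / 2, bin_width_s)
    counts, _ = np.histogram(ilis, bins=edges)
    # np.argmax returns the first (smallest-center) maximal bin
    best = int(np.argmax(counts))
    return float(edges[best] + bin_width_s / 2)


# ---------------------------------------------------------------------------
# block bookkeeping
# ---------------------------------------------------------------------------


def _schedule_arrays(schedule) -> tuple[np.ndarray, np.ndarray, list[str]]:
    blocks = [tuple(b) for b in schedule]
    blocks = [(float(s), float(e), str(lab)) for s, e, lab in blocks]
    starts = np.array([b[0] for b in blocks])
    ends = np.array([b[1] for b in blocks])
    labels = [b[2] for b in blocks]
    return starts, ends, labels


def _block_index_of(
    times: np.ndarray, starts: np.ndarray, ends: np.ndarray, closing: bool = False
) -> np.ndarray:
    """Block index per time under the half-open [start, end) convention.

    With ``closing=True`` (used for bout *end* times) a time exactly on
    a block boundary belongs to the block it closes, so a bout truncated
    at a boundary does not count as spanning.
    """
    idx = np.searchsorted(starts, times, side="right") - 1
    if closing:
        on_boundary = (idx > 0) & (times == starts[np.clip(idx, 0, len(starts) - 1)])
        idx = idx - on_boundary
    limit = ends[np.clip(idx, 0, len(ends) - 1)]
    if closing:
        bad = (idx < 0) | (times > limit)
    else:
        bad = (idx < 0) | (times >= limit)
    if np.any(bad):
        t = float(np.asarray(times)[bad][0])
        raise ValidationError(f"time {t} falls outside the block schedule")
    return idx


def assign_blocks(bouts: BoutTable, schedule) -> BoutTable:
    """Label each bout with the block containing its start time.

    ``spans_block`` is set when start and end fall in different blocks;
    block-conditioned analyses exclude spanning bouts, but they are
    retained here for all other statistics.
    """
    starts, ends, labels = _schedule_arrays(schedule)
    frame = bouts.frame.copy()
    if len(frame):
        bi = _block_index_of(frame["start_s"].to_numpy(), starts, ends)
        be = _block_index_of(frame["end_s"].to_numpy(), starts, ends, closing=True)
        frame["block_index"] = bi
        frame["block_label"] = [labels[i] for i in bi]
        frame["spans_block"] = bi != be
    return replace(bouts, frame=frame)


def licks_per_block(session: LickSession, schedule) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-block lick counts and per-condition mean licks per block.

    Blocks in which the animal never licked are excluded from the
    condition means (a condition with no licked blocks is reported as
    NaN, not zero).
    """
    starts, ends, labels = _schedule_arrays(schedule)
    counts = []
    for s, e in zip(starts, ends):
        lo = np.searchsorted(session.lick_times_s, s, side="left")
        hi = np.searchsorted(session.lick_times_s, e, side="left")
        counts.append(int(hi - lo))
    frame = pd.DataFrame(
        {"block_index": np.arange(len(labels)), "block_label": labels, "n_licks": counts}
    )
    means: dict[str, float] = {}
    for label in dict.fromkeys(labels):
        sub = frame[(frame["block_label"] == label) & (frame["n_licks"] > 0)]
        means[label] = float(sub["n_licks"].mean()) if len(sub) else float("nan")
    return frame, means


@dataclass
class LickRateProfile:
    """Bout-aligned binned lick counts; NaN marks bins after bout end."""

    counts: np.ndarray  # (n_bouts, n_bins), NaN after each bout's end
    bin_s: float
    mean_profile: np.ndarray  # per-bin mean across bouts, ignoring NaN

    @property
    def n_bouts(self) -> int:
        return self.counts.shape[0]


def bout_lick_rate_profile(
    bouts: BoutTable,
    session: LickSession,
    bin_s: float = 1.0,
    horizon_s: float = 20.0,
) -> LickRateProfile:
    """Lick counts in bout-aligned 1-s bins over the first ``horizon_s``.

    Bouts are aligned at their start; bin *k* covers
    ``[start + k*bin_s, start + (k+1)*bin_s)`` and is marked missing
    (NaN) once ``k*bin_s`` reaches the bout duration.  The mean profile
    averages across bouts per bin, ignoring missing values.
    """
    if bin_s <= 0 or horizon_s < bin_s:
        raise ValidationError("need bin_s > 0 and horizon_s >= bin_s")
    n_bins = int(round(horizon_s / bin_s))
    n_bouts = bouts.n_bouts
    counts = np.full((n_bouts, n_bins), np.nan)
    times = session.lick_times_s
    for i, row in enumerate(bouts.frame.itertuples(index=False)):
        rel = times[(times >= row.start_s) & (times <= row.end_s)] - row.start_s
        n_valid = min(n_bins, max(1, math.ceil(row.duration_s / bin_s - 1e-12)))
        hist, _ = np.histogram(rel, bins=np.arange(0, (n_valid + 1) * bin_s, bin_s))
        counts[i, :n_valid] = hist[:n_valid]
    if n_bouts:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(counts, axis=0)
    else:
        mean = np.full(n_bins, np.nan)
    return LickRateProfile(counts=counts, bin_s=bin_s, mean_profile=mean)


# ---------------------------------------------------------------------------
# intake
# ---------------------------------------------------------------------------


def energy_intake(
    config: SessionConfig,
    n_licks: int | None = None,
    volume_ml: float | None = None,
    dilution: float = 1.0,
) -> float:
    """Caloric intake in kcal from either a lick count or a volume.

    Every ``licks_per_delivery`` licks trigger one pump delivery of
    ``volume_per_delivery_ul``; intake is volume times the caloric
    density of the (possibly diluted) liquid diet.
    """
    if not 0 < dilution <= 1:
        raise ValidationError("dilution must lie in (0, 1]")
    if (n_licks is None) == (volume_ml is None):
        raise ValidationError("supply exactly one of n_licks or volume_ml")
    if n_licks is not None:
        if n_licks < 0:
            raise ValidationError("n_licks must be nonnegative")
        deliveries = n_licks // config.licks_per_delivery
        volume_ml = deliveries * config.volume_per_delivery_ul / 1000.0
    if volume_ml < 0:
        raise ValidationError("volume must be nonnegative")
    return float(volume_ml * dilution * config.caloric_density_kcal_per_ml)


def delivered_volume_ul(config: SessionConfig, n_licks: int) -> float:
    """Volume dispensed (µL) for a lick count under the delivery rule."""
    if n_licks < 0:
        raise ValidationError("n_licks must be nonnegative")
    return float((n_licks // config.licks_per_delivery) * config.volume_per_delivery_ul)
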