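"""Synthetic self-paced consumption sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* **Licks** — bout onsets follow a homogeneous Poisson process during
  the session; each bout's duration is Gamma-distributed with a mean
  scaled by the palatability label of its block (bouts are truncated at
  block boundaries, since the delivered food changes there), and licks
  within a bout form a renewal process around the ~8 Hz murine lick
  rhythm (mean inter-lick interval 0.125 s).
* **Pose** — the mouth sits at the spout throughout each true bout and
  wanders the arena in a reflected random walk between bouts; tail-base
  trails the mouth by one (jittered) body length.
* **Photometry** — two channels with channel-specific exponential
  bleaching, a shared low-pass motion artifact (entering the 470 nm
  channel additively and the 415 nm channel with a coupling gain, so a
  linear channel regression can remove it), white measurement noise,
  and bout-locked transients: per-lick unit impulses convolved with a
  difference-of-exponentials kernel, scaled by a per-condition
  amplitude.  Negative amplitudes model the negative responses seen in
  low-palatability blocks under hedonic contrast.

Every stochastic step draws from a generator seeded by ``params.seed``;
identical seeds yield bit-identical bundles.  The ground truth
(:class:`SimTruth`) carries the injected bout intervals, labels,
artifact and noise-free drive so that recovery tests can compare
pipeline estimates against what was injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .closedloop import BlockSchedule, LaserLog, StimProtocol, build_schedule
from .closedloop import contingent_inhib_log, contingent_stim_log
from .microstructure import BOUT_COLUMNS, BoutTable, PoseTrack
from .photometry import PhotometryTrace
from .session_io import LickSession, SessionConfig, ValidationError


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    ``bout_duration_mean_s`` and ``transient_amplitude`` are keyed by
    condition label and must cover every label in the session's block
    schedule.  ``transient_amplitude`` is the fractional 470 nm
    modulation at the single-lick kernel peak; it may be negative.
    """

    bout_rate_per_min: float = 1.0
    bout_duration_mean_s: Mapping[str, float] = field(
        default_factory=lambda: {"high": 10.0, "low": 5.0}
    )
    bout_duration_shape: float = 2.0
    intra_bout_ili_mean_s: float = 0.125
    intra_bout_ili_cv: float = 0.1
    transient_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.004, "low": 0.002}
    )
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.0
    bleach_tau_470_s: float = 2400.0
    bleach_tau_415_s: float = 4000.0
    motion_sd: float = 0.002
    motion_coupling_415: float = 1.0
    motion_multiplicative: bool = False
    motion_lowpass_s: float = 0.5
    noise_sd: float = 0.005
    baseline_F: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bout_rate_per_min < 0:
            raise ValidationError("bout_rate_per_min must be >= 0")
        if any(m <= 0 for m in self.bout_duration_mean_s.values()):
            raise ValidationError("bout duration means must be > 0")
        if self.intra_bout_ili_mean_s <= 0:
            raise ValidationError("intra_bout_ili_mean_s must be > 0")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= 0:
            raise ValidationError("kernel constants must be > 0")
        if self.kernel_rise_s >= self.kernel_decay_s:
            raise ValidationError("kernel_rise_s must be < kernel_decay_s")
        if self.bleach_tau_470_s <= 0 or self.bleach_tau_415_s <= 0:
            raise ValidationError("bleach taus must be > 0")


@dataclass
class SimTruth:
    """Ground truth paired with a synthetic session."""

    bout_intervals: np.ndarray  # (n_bouts, 2) intended [start, end]
    bout_labels: list[str]
    bout_lick_counts: np.ndarray
    merged: np.ndarray  # flag: bout produced by merging overlapping draws
    params: SimParams
    config: SessionConfig
    motion: np.ndarray | None = None  # artifact on the 470 time base
    calcium_drive: np.ndarray | None = None  # noise-free fractional drive

    @property
    def n_bouts(self) -> int:
        return int(self.bout_intervals.shape[0])

    def bout_table(self) -> BoutTable:
        """The true bouts as a :class:`BoutTable` (duration = lick span)."""
        rows = []
        for (s, e), label, n in zip(
            self.bout_intervals, self.bout_labels, self.bout_lick_counts
        ):
            rows.append(
                {
                    "start_s": float(s),
                    "end_s": float(e),
                    "duration_s": float(e - s),
                    "n_licks": int(n),
                    "block_index": -1,
                    "block_label": label,
                    "spans_block": False,
                }
            )
        return BoutTable(frame=pd.DataFrame(rows, columns=BOUT_COLUMNS))


@dataclass(frozen=True)
class ArenaGeometry:
    """Behavioral chamber geometry for pose simulation (cm)."""

    width_cm: float = 29.0
    height_cm: float = 29.0
    spout_xy: tuple[float, float] = (0.0, 14.5)
    body_length_cm: float = 8.0
    body_length_jitter_cm: float = 0.3
    speed_sd_cm_s: float = 4.0
    speed_tau_s: float = 1.0
    mouth_jitter_cm: float = 0.3

    def __post_init__(self) -> None:
        if min(self.width_cm, self.height_cm) <= self.body_length_cm:
            raise ValidationError("arena must be larger than one body length")


@dataclass
class SessionBundle:
    """One complete synthetic session."""

    session: LickSession
    truth: SimTruth
    schedule: BlockSchedule
    pose: PoseTrack | None = None
    trace: PhotometryTrace | None = None
    laser_log: LaserLog | None = None


# ---------------------------------------------------------------------------
# licks
# ---------------------------------------------------------------------------


def default_schedule(config: SessionConfig) -> BlockSchedule:
    return build_schedule(
        config.session_length_s,
        config.block_length_s,
        first_label=config.block_labels[0],
        labels=config.block_labels,
    )


def simulate_licks(
    config: SessionConfig,
    params: SimParams,
    schedule: BlockSchedule | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LickSession, SimTruth]:
    """Draw a bout-structured lick train.

    Bout onsets are Poisson at ``bout_rate_per_min``; each bout's
    intended duration is Gamma(shape, mean scaled by its block's
    palatability label), truncated at the block boundary and session
    end.  Intra-bout licks are a Gamma renewal process with the stated
    mean and CV.  Overlapping bout draws are merged and flagged.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if schedule is None:
        schedule = default_schedule(config)
    for block in schedule:
        if block.label not in params.bout_duration_mean_s:
            raise ValidationError(
                f"no bout_duration_mean_s entry for label {block.label!r}"
            )
    L = config.session_length_s
    rate = params.bout_rate_per_min / 60.0
    onsets: list[float] = []
    t = 0.0
    while rate > 0:
        t += rng.exponential(1.0 / rate)
        if t >= L:
            break
        onsets.append(t)

    shape = params.bout_duration_shape
    intervals: list[list[float]] = []
    labels: list[str] = []
    merged_flags: list[bool] = []
    for onset in onsets:
        i = schedule.index_at(onset)
        block = schedule.blocks[i]
        mean = params.bout_duration_mean_s[block.label]
        dur = rng.gamma(shape, mean / shape)
        end = min(onset + dur, block.end_s, L)
        if intervals and onset <= intervals[-1][1]:
            # overlapping draw: merge into the previous bout and flag it
            intervals[-1][1] = max(intervals[-1][1], end)
            merged_flags[-1] = True
            continue
        intervals.append([onset, end])
        labels.append(block.label)
        merged_flags.append(False)

    cv = params.intra_bout_ili_cv
    ili_shape = 1.0 / (cv * cv) if cv > 0 else None
    lick_times: list[float] = []
    lick_labels: list[str] = []
    counts: list[int] = []
    eps = 1e-9
    for (start, end), label in zip(intervals, labels):
        t = start
        n = 0
        while t <= end and t < L - eps:
            lick_times.append(t)
            lick_labels.append(label)
            n += 1
            if ili_shape is None:
                ili = params.intra_bout_ili_mean_s
            else:
                ili = rng.gamma(ili_shape, params.intra_bout_ili_mean_s / ili_shape)
            t += max(ili, eps)
        counts.append(n)

    session = LickSession(
        np.asarray(lick_times), np.asarray(lick_labels, dtype=object), config
    )
    truth = SimTruth(
        bout_intervals=np.asarray(intervals, dtype=float).reshape(-1, 2),
        bout_labels=labels,
        bout_lick_counts=np.asarray(counts, dtype=int),
        merged=np.asarray(merged_flags, dtype=bool),
        params=params,
        config=config,
    )
    return session, truth


# ---------------------------------------------------------------------------
# pose
# ---------------------------------------------------------------------------


def simulate_pose(
    session: LickSession,
    truth: SimTruth,
    geometry: ArenaGeometry = ArenaGeometry(),
    rng: np.random.Generator | None = None,
) -> PoseTrack:
    """Pose track consistent with the true bouts.

    During a true bout the mouth jitters tightly around the spout;
    between bouts it moves with a persistent (Ornstein-Uhlenbeck)
    velocity — smooth excursions rather than frame-by-frame jitter, so
    food-zone crossings produce dwell times on a behavioral timescale.
    The tail-base trails the mouth by one body length (jittered per
    frame) in a slowly wandering direction.
    """
    if rng is None:
        rng = np.random.default_rng(truth.params.seed + 1)
    cfg = session.config
    n = int(math.floor(cfg.session_length_s * cfg.pose_rate_hz))
    dt = 1.0 / cfg.pose_rate_hz
    t = np.arange(n) * dt
    spout = np.asarray(geometry.spout_xy, dtype=float)

    in_bout = np.zeros(n, dtype=bool)
    for s, e in truth.bout_intervals:
        in_bout[(t >= s) & (t <= e)] = True

    alpha = math.exp(-dt / geometry.speed_tau_s)
    kick = geometry.speed_sd_cm_s * math.sqrt(1.0 - alpha * alpha)
    mouth = np.empty((n, 2))
    pos = np.array([geometry.width_cm / 2.0, geometry.height_cm / 2.0])
    vel = rng.normal(0.0, geometry.speed_sd_cm_s, size=2)
    for i in range(n):
        if in_bout[i]:
            pos = spout + rng.normal(0.0, geometry.mouth_jitter_cm, size=2)
            vel = rng.normal(0.0, 0.2 * geometry.speed_sd_cm_s, size=2)
        else:
            vel = alpha * vel + rng.normal(0.0, kick, size=2)
            pos = pos + vel * dt
            for ax, hi in ((0, geometry.width_cm), (1, geometry.height_cm)):
                if pos[ax] < 0.0 or pos[ax] > hi:
                    vel[ax] = -vel[ax]
            pos[0] = _reflect(pos[0], 0.0, geometry.width_cm)
            pos[1] = _reflect(pos[1], 0.0, geometry.height_cm)
        mouth[i] = pos

    theta = np.cumsum(rng.normal(0.0, 0.1, size=n))
    lengths = geometry.body_length_cm + (
        rng.normal(0.0, geometry.body_length_jitter_cm, size=n)
        if geometry.body_length_jitter_cm > 0
        else np.zeros(n)
    )
    lengths = np.clip(lengths, 0.1, None)
    tail = mouth - np.column_stack([np.cos(theta), np.sin(theta)]) * lengths[:, None]
    return PoseTrack(frame_times_s=t, mouth_xy=mouth, tailbase_xy=tail, spout_xy=spout)


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    x = (x - lo) % (2 * span)
    return lo + (x if x <= span else 2 * span - x)


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------


def transient_kernel(dt: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Difference-of-exponentials kernel sampled at dt, unit peak."""
    t_peak = math.log(decay_s / rise_s) / (1.0 / rise_s - 1.0 / decay_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    horizon = t_peak + 8.0 * decay_s
    tau = np.arange(0.0, horizon, dt)
    k = (np.exp(-tau / decay_s) - np.exp(-tau / rise_s)) / peak
    return k


def simulate_photometry(
    session: LickSession,
    truth: SimTruth,
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
) -> PhotometryTrace:
    """Two-channel raw photometry for a session.

    The interleaved acquisition is emulated by sampling the 415 nm
    channel on the frame grid and the 470 nm channel half a frame
    later.  Signal model::

        470(t) = F0 * exp(-t/tau470) * (1 + sum_c A_c * c_c(t)) + m(t) + noise
        415(t) = F0 * exp(-t/tau415) + g * m(t) + noise

    where ``c_c`` is the per-lick impulse train of condition ``c``
    convolved with the unit-peak transient kernel, and ``m`` is the
    shared low-pass motion artifact.  The multiplicative-artifact
    stress-test option scales both bleach curves by ``(1 + m)``
    instead.
    """
    if params is None:
        params = truth.params
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    cfg = session.config
    rate = cfg.photometry_rate_hz
    dt = 1.0 / rate
    n = int(math.floor(cfg.session_length_s * rate))
    t415 = np.arange(n) * dt
    t470 = t415 + dt / 2.0

    # noise-free fractional calcium/dopamine drive on the 470 grid
    drive = np.zeros(n)
    kernel = transient_kernel(dt, params.kernel_rise_s, params.kernel_decay_s)
    labels = np.asarray(session.spout_ids, dtype=object)
    for label in dict.fromkeys(labels.tolist()):
        amp = params.transient_amplitude.get(str(label))
        if amp is None:
            raise ValidationError(f"no transient_amplitude entry for label {label!r}")
        impulses = np.zeros(n)
        licks = session.lick_times_s[labels == label]
        idx = np.clip(np.round((licks - t470[0]) / dt).astype(int), 0, n - 1)
        np.add.at(impulses, idx, 1.0)
        conv = fftconvolve(impulses, kernel)[:n]
        drive += amp * conv

    # shared motion artifact: unit-variance low-pass noise, scaled
    if params.motion_sd > 0:
        white = rng.standard_normal(n)
        smooth = gaussian_filter1d(white, sigma=params.motion_lowpass_s * rate)
        sd = smooth.std()
        motion_unit = smooth / sd if sd > 0 else smooth
        motion = params.motion_sd * params.baseline_F * motion_unit
    else:
        motion = np.zeros(n)

    bleach_470 = params.baseline_F * np.exp(-t470 / params.bleach_tau_470_s)
    bleach_415 = params.baseline_F * np.exp(-t415 / params.bleach_tau_415_s)
    m415 = np.interp(t415, t470, motion)
    if params.motion_multiplicative:
        raw_470 = bleach_470 * (1.0 + drive) * (1.0 + motion / params.baseline_F)
        raw_415 = bleach_415 * (
            1.0 + params.motion_coupling_415 * m415 / params.baseline_F
        )
    else:
        raw_470 = bleach_470 * (1.0 + drive) + motion
        raw_415 = bleach_415 + params.motion_coupling_415 * m415
    if params.noise_sd > 0:
        scale = params.noise_sd * params.baseline_F
        raw_470 = raw_470 + rng.normal(0.0, scale, size=n)
        raw_415 = raw_415 + rng.normal(0.0, scale, size=n)

    truth.motion = motion
    truth.calcium_drive = drive
    return PhotometryTrace(
        time_s=t470, raw_415=raw_415, raw_470=raw_470, time_415_s=t415
    )


# ---------------------------------------------------------------------------
# full bundles
# ---------------------------------------------------------------------------


def simulate_session(
    config: SessionConfig,
    params: SimParams,
    geometry: ArenaGeometry | None = ArenaGeometry(),
    protocol: StimProtocol | None = None,
    on_label: str = "ON",
) -> SessionBundle:
    """Compose licks, pose, photometry and (optionally) a laser log.

    When ``protocol`` is given, a lick-contingent laser log is produced
    (pulsed protocols via the stimulation controller, continuous ones
    via the inhibition controller); the session's block labels must then
    include ``on_label``.  Identical seeds yield bit-identical bundles.
    """
    session, truth = simulate_licks(config, params)
    schedule = default_schedule(config)
    pose = (
        simulate_pose(session, truth, geometry) if geometry is not None else None
    )
    trace = simulate_photometry(session, truth, params)
    laser_log = None
    if protocol is not None:
        if protocol.mode == "pulsed":
            laser_log = contingent_stim_log(session, schedule, protocol, on_label)
        else:
            laser_log = contingent_inhib_log(session, schedule, protocol, on_label)
    return SessionBundle(
        session=session,
        truth=truth,
        schedule=schedule,
        pose=pose,
        trace=trace,
        laser_log=laser_log,
    )
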