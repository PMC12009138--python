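"""Deterministic simulation of closed-loop optogenetic session logic.

In the closed-loop (lick-contingent) design a session is tiled by
alternating laser-OFF/laser-ON blocks.  During ON blocks each lick
triggers a laser train: pulsed excitation for stimulation (default
25 ms pulses at 20 pulses/s for 1 s) or continuous illumination for
inhibition, with a linear 1-s ramp-off after licking stops (to limit
rebound firing).  Each lick within the train window extends the train;
it closes once no lick arrives for the train duration.  The yoked
(noncontingent) control delivers the same number of laser events per ON
block at random times, decoupling the perturbation from behavior.

Retrigger semantics: by default, extending a train preserves the pulse
grid anchored at the opening lick so the emitted rate never exceeds the
protocol rate; a phase-restart option re-anchors the grid at each lick
(overlapping pulses are merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .session_io import LickSession, ValidationError


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    start_s: float
    end_s: float
    label: str

    def __iter__(self):
        # allow tuple-style unpacking (start, end, label)
        yield self.start_s
        yield self.end_s
        yield self.label


@dataclass
class BlockSchedule:
    """Alternating condition blocks tiling ``[0, session_length_s)`` exactly."""

    blocks: list[Block]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for b in self.blocks:
            if abs(b.start_s - prev_end) > 1e-9 or b.end_s <= b.start_s:
                raise ValidationError("blocks must tile the session with no gaps/overlaps")
            prev_end = b.end_s

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def session_length_s(self) -> float:
        return self.blocks[-1].end_s if self.blocks else 0.0

    def index_at(self, t: float) -> int:
        starts = np.array([b.start_s for b in self.blocks])
        i = int(np.searchsorted(starts, t, side="right") - 1)
        if i < 0 or t >= self.blocks[i].end_s:
            raise ValidationError(f"time {t} outside schedule")
        return i

    def label_at(self, t: float) -> str:
        return self.blocks[self.index_at(t)].label

    def blocks_with_label(self, label: str) -> list[tuple[int, Block]]:
        return [(i, b) for i, b in enumerate(self.blocks) if b.label == label]


def build_schedule(
    session_length_s: float,
    block_length_s: float,
    first_label: str = "OFF",
    labels: Sequence[str] = ("OFF", "ON"),
) -> BlockSchedule:
    """Alternating block schedule starting with ``first_label``."""
    if session_length_s <= 0 or block_length_s <= 0:
        raise ValidationError("session and block lengths must be > 0")
    ratio = session_length_s / block_length_s
    n = round(ratio)
    if abs(ratio - n) > 1e-9:
        raise ValidationError(
            "session_length_s must be an integer multiple of block_length_s"
        )
    if first_label not in labels:
        raise ValidationError(f"first_label {first_label!r} not in labels {labels!r}")
    other = labels[1] if first_label == labels[0] else labels[0]
    pair = (first_label, other)
    blocks = [
        Block(i * block_length_s, (i + 1) * block_length_s, pair[i % 2])
        for i in range(int(n))
    ]
    return BlockSchedule(blocks)


# ---------------------------------------------------------------------------
# protocols and logs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimProtocol:
    """Laser train parameters.

    Defaults follow the standard lick-triggered excitation protocol:
    20 pulses/s, 25 ms pulse width, 1-s trains.  Inhibition uses
    ``mode="continuous"`` with a 1-s linear ramp-off after the last
    train closes.
    """

    pulse_rate_hz: float = 20.0
    pulse_width_s: float = 0.025
    train_s: float = 1.0
    mode: str = "pulsed"  # "pulsed" | "continuous"
    ramp_off_s: float = 0.0
    retrigger: str = "grid"  # "grid" (preserve anchor) | "restart" (re-anchor per lick)

    def __post_init__(self) -> None:
        if self.train_s <= 0:
            raise ValidationError("train_s must be > 0")
        if self.mode not in ("pulsed", "continuous"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "pulsed" and self.pulse_width_s > 1.0 / self.pulse_rate_hz + 1e-12:
            raise ValidationError("pulse_width_s must not exceed the pulse period")
        if self.retrigger not in ("grid", "restart"):
            raise ValidationError(f"unknown retrigger mode {self.retrigger!r}")


INHIBITION_PROTOCOL = StimProtocol(mode="continuous", ramp_off_s=1.0)


@dataclass
class Train:
    """One laser train: ``[start_s, end_s)`` triggered by lick ``trigger_index``."""

    start_s: float
    end_s: float
    trigger_index: int
    overhangs_block: bool = False


@dataclass
class LaserLog:
    """All laser events of a session.

    ``pulses`` are merged, nonoverlapping illumination intervals;
    ``trains`` record the event-level bookkeeping (start, end, trigger
    lick); ``ramps`` are the linear ramp-off intervals appended after
    inhibition plateaus.
    """

    pulses: list[tuple[float, float]] = field(default_factory=list)
    trains: list[Train] = field(default_factory=list)
    ramps: list[tuple[float, float]] = field(default_factory=list)
    contingent: bool = True

    def total_illumination_s(self, ramp_weight: float = 0.5) -> float:
        """Summed illumination time; ramps count at their mean power fraction."""
        full = sum(b - a for a, b in self.pulses)
        if not self.pulses:
            full = sum(t.end_s - t.start_s for t in self.trains)
        return float(full + ramp_weight * sum(b - a for a, b in self.ramps))

    def trains_per_block(self, schedule: BlockSchedule) -> dict[int, int]:
        counts = {i: 0 for i, _ in enumerate(schedule.blocks)}
        for tr in self.trains:
            counts[schedule.index_at(tr.start_s)] += 1
        return counts


def merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of intervals as a sorted, disjoint list."""
    out: list[tuple[float, float]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# contingent controllers
# ---------------------------------------------------------------------------


def _collect_trains(
    trigger_times: np.ndarray,
    trigger_indices: np.ndarray,
    schedule: BlockSchedule,
    protocol: StimProtocol,
    on_label: str,
) -> tuple[list[Train], list[list[float]]]:
    """Group gated triggers into trains with grid-preserving extension.

    Returns the trains plus, per train, the anchor times of its pulse
    grids (one anchor in ``grid`` mode; one per lick in ``restart``).
    """
    trains: list[Train] = []
    anchors: list[list[float]] = []
    open_end = None
    for t, idx in zip(trigger_times, trigger_indices):
        if schedule.label_at(t) != on_label:
            continue
        if open_end is not None and t < open_end:
            open_end = t + protocol.train_s
            trains[-1].end_s = open_end
            if protocol.retrigger == "restart":
                anchors[-1].append(t)
        else:
            open_end = t + protocol.train_s
            block = schedule.blocks[schedule.index_at(t)]
            trains.append(Train(float(t), float(open_end), int(idx)))
            anchors.append([float(t)])
    for tr in trains:
        tr.overhangs_block = tr.end_s > schedule.blocks[schedule.index_at(tr.start_s)].end_s
    return trains, anchors


def contingent_stim_log(
    session: LickSession,
    schedule: BlockSchedule,
    protocol: StimProtocol = StimProtocol(),
    on_label: str = "ON",
) -> LaserLog:
    """Lick-contingent pulsed stimulation log.

    The first lick inside an ON block opens a pulse train at the
    protocol rate anchored at that lick; each subsequent ON-block lick
    within the train window extends the train end to ``lick + train_s``
    while (by default) preserving the pulse-grid anchor.  A train may
    overhang its block boundary (flagged) rather than being truncated:
    block gating tests the trigger lick's time.
    """
    if protocol.mode != "pulsed":
        raise ValidationError("contingent_stim_log requires a pulsed protocol")
    idx = np.arange(session.n_licks)
    trains, anchors = _collect_trains(
        session.lick_times_s, idx, schedule, protocol, on_label
    )
    period = 1.0 / protocol.pulse_rate_hz
    pulses: list[tuple[float, float]] = []
    for tr, anchor_list in zip(trains, anchors):
        for anchor in anchor_list:
            # pulses on the anchor's grid whose onset falls inside the train
            n = int(np.ceil((tr.end_s - anchor) / period - 1e-12))
            for k in range(max(0, n)):
                on = anchor + k * period
                if on >= tr.end_s - 1e-12:
                    break
                if on < tr.start_s - 1e-12:
                    continue
                pulses.append((on, on + protocol.pulse_width_s))
    return LaserLog(pulses=merge_intervals(pulses), trains=trains, contingent=True)


def contingent_inhib_log(
    session: LickSession,
    schedule: BlockSchedule,
    protocol: StimProtocol = INHIBITION_PROTOCOL,
    on_label: str = "ON",
) -> LaserLog:
    """Lick-contingent continuous inhibition log.

    Each ON-block lick illuminates for ``train_s``, extended by
    subsequent licks; once licking stops for ``train_s`` the light ramps
    linearly to zero over ``ramp_off_s``.
    """
    if protocol.mode != "continuous":
        raise ValidationError("contingent_inhib_log requires a continuous protocol")
    if protocol.ramp_off_s <= 0:
        raise ValidationError("inhibition requires ramp_off_s > 0")
    idx = np.arange(session.n_licks)
    trains, _ = _collect_trains(session.lick_times_s, idx, schedule, protocol, on_label)
    plateaus = [(tr.start_s, tr.end_s) for tr in trains]
    ramps = [(tr.end_s, tr.end_s + protocol.ramp_off_s) for tr in trains]
    return LaserLog(
        pulses=merge_intervals(plateaus), trains=trains, ramps=ramps, contingent=True
    )


# ---------------------------------------------------------------------------
# yoked control
# ---------------------------------------------------------------------------


def yoked_pseudo_events(
    contingent_log: LaserLog,
    schedule: BlockSchedule,
    seed: int,
    on_label: str = "ON",
) -> np.ndarray:
    """Pseudo-event times for the noncontingent (yoked) control.

    For each ON block, draws as many event times as the contingent log
    opened trains in that block, uniformly at random within the block.
    Counts per block are conserved exactly; times are sorted.
    """
    rng = np.random.default_rng(seed)
    counts = contingent_log.trains_per_block(schedule)
    events: list[float] = []
    for i, block in schedule.blocks_with_label(on_label):
        k = counts.get(i, 0)
        if k:
            events.extend(rng.uniform(block.start_s, block.end_s, size=k))
    return np.sort(np.asarray(events))


def noncontingent_log(
    pseudo_events: np.ndarray,
    schedule: BlockSchedule,
    protocol: StimProtocol = StimProtocol(),
    on_label: str = "ON",
) -> LaserLog:
    """Generate laser events from pseudo-event triggers (no extension).

    Each pseudo event opens one standard train independent of behavior,
    reproducing the contingent session's illumination statistics.
    """
    trains: list[Train] = []
    pulses: list[tuple[float, float]] = []
    ramps: list[tuple[float, float]] = []
    period = 1.0 / protocol.pulse_rate_hz
    for j, t in enumerate(np.sort(np.asarray(pseudo_events, dtype=float))):
        end = t + protocol.train_s
        block = schedule.blocks[schedule.index_at(t)]
        trains.append(Train(float(t), float(end), -1 - j, overhangs_block=end > block.end_s))
        if protocol.mode == "pulsed":
            n = int(np.ceil(protocol.train_s * protocol.pulse_rate_hz - 1e-12))
            for k in range(n):
                on = t + k * period
                if on >= end - 1e-12:
                    break
                pulses.append((on, on + protocol.pulse_width_s))
        else:
            pulses.append((t, end))
            ramps.append((end, end + protocol.ramp_off_s))
    return LaserLog(
        pulses=merge_intervals(pulses), trains=trains, ramps=ramps, contingent=False
    )


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    """Transduction-normalized stimulation target.

    Only a fraction ``penetrance`` of the target neurons express the
    opsin, so driving the recorded (transduced) subpopulation to
    ``target_ratio`` times the high-palatability reference response
    requires a multiplier of ``target_ratio / penetrance`` — e.g. at
    50% penetrance the transduced cells are driven to twice the
    reference level.
    """

    penetrance: float
    target_ratio: float
    multiplier: float
    reference_auc: float
    target_auc: float


def calibration_target(
    reference_auc: float,
    penetrance: float,
    target_ratio: float = 1.0,
) -> CalibrationResult:
    if not 0 < penetrance <= 1:
        raise ValidationError("penetrance must lie in (0, 1]")
    if not np.isfinite(reference_auc):
        raise ValidationError("reference_auc must be finite")
    if target_ratio <= 0:
        raise ValidationError("target_ratio must be > 0")
    multiplier = target_ratio / penetrance
    return CalibrationResult(
        penetrance=penetrance,
        target_ratio=target_ratio,
        multiplier=multiplier,
        reference_auc=float(reference_auc),
        target_auc=float(reference_auc * multiplier),
    )


class CalibrationError(ValueError):
    """No stimulation gain on the grid reached the calibration target."""

    def __init__(self, message: str, best_gain: float, best_auc: float):
        super().__init__(message)
        self.best_gain = best_gain
        self.best_auc = best_auc


@dataclass
class StimCalibration:
    """Chosen stimulation gain and the AUC it achieved."""

    gain: float
    achieved_auc: float
    target_auc: float
    grid: list[tuple[float, float]]  # (gain, mean per-bout AUC) for gains tried


def calibrate_stim_gain(
    config,
    low_params,
    target: CalibrationResult,
    gain_grid: Sequence[float],
    evoked_amplitude: float | None = None,
    seed: int | None = None,
    isosbestic_mode: str = "chunked",
) -> StimCalibration:
    """Titrate stimulation gain until the low-palatability response reaches target.

    Simulates low-palatability sessions in which lick-triggered
    stimulation adds an evoked transient of amplitude
    ``gain * evoked_amplitude`` on top of the intrinsic low-condition
    response, runs the standard photometry pipeline, and returns the
    smallest grid gain whose mean per-bout AUC reaches
    ``target.target_auc``.  ``evoked_amplitude`` defaults to the
    low-condition amplitude (gain 1 doubles the drive).
    """
    from dataclasses import replace as dc_replace

    from . import photometry as ph
    from . import synthetic_data as syn

    grid = sorted(float(g) for g in gain_grid)
    if not grid:
        raise ValidationError("gain grid must be nonempty")
    label = config.block_labels[0]
    base_amp = low_params.transient_amplitude[label]
    if evoked_amplitude is None:
        evoked_amplitude = base_amp
    if seed is None:
        seed = low_params.seed
    tried: list[tuple[float, float]] = []
    for gain in grid:
        amps = dict(low_params.transient_amplitude)
        amps[label] = base_amp + gain * evoked_amplitude
        params = dc_replace(low_params, transient_amplitude=amps, seed=seed)
        session, truth = syn.simulate_licks(config, params)
        trace = syn.simulate_photometry(session, truth, params)
        trace = ph.preprocess(trace, session, mode=isosbestic_mode)
        records = ph.bout_auc_records(trace, truth.bout_table())
        mean_auc = float(records["auc"].mean()) if len(records) else float("nan")
        tried.append((gain, mean_auc))
        if np.isfinite(mean_auc) and mean_auc >= target.target_auc:
            return StimCalibration(gain, mean_auc, target.target_auc, tried)
    best_gain, best_auc = max(tried, key=lambda ga: (ga[1] if np.isfinite(ga[1]) else -np.inf))
    raise CalibrationError(
        f"no gain on the grid reached target AUC {target.target_auc:.3f}; "
        f"best was {best_auc:.3f} at gain {best_gain}",
        best_gain=best_gain,
        best_auc=best_auc,
    )
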