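"""Reading and writing session artifacts as delimited text.

A *session* is one self-paced consumption experiment: a mouse licks a
spout for liquid food while lick events, pose frames, two-channel
photometry frames, and (optionally) laser events are logged.  All
artifacts are plain comma-separated text with a header row.  Times are
seconds from session start, serialized at fixed 6-decimal precision;
every interval in this package is half-open ``[start, end)`` so that
block and bout membership is unambiguous.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: decimal places used whenever a time is written to disk
TIME_DECIMALS = 6


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    """Session-level constants.

    Parameters
    ----------
    session_length_s:
        Total session duration in seconds.  Must be a positive integer
        multiple of ``block_length_s``.
    block_length_s:
        Length of one condition block (default 120 s, i.e. alternating
        2-minute blocks).
    block_labels:
        Ordered pair of condition labels that alternate across blocks,
        e.g. ``("high", "low")`` palatability or ``("OFF", "ON")`` laser.
    licks_per_delivery:
        Licks required to trigger one pump delivery (default 3).
    volume_per_delivery_ul:
        Volume dispensed per delivery in microliters (default 3).
    caloric_density_kcal_per_ml:
        Caloric density of the undiluted liquid diet; default is
        220 kcal per 237 mL (manufacturer's value for Ensure).
    photometry_rate_hz:
        Per-channel photometry sampling rate (default 20 Hz).
    pose_rate_hz:
        Video/pose frame rate (default 30 frames/s).
    seed:
        Default seed for stochastic operations that consume this config.
    """

    session_length_s: float
    block_length_s: float = 120.0
    block_labels: tuple[str, str] = ("high", "low")
    licks_per_delivery: int = 3
    volume_per_delivery_ul: float = 3.0
    caloric_density_kcal_per_ml: float = 220.0 / 237.0
    photometry_rate_hz: float = 20.0
    pose_rate_hz: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_length_s <= 0:
            raise ValidationError("session_length_s must be > 0")
        if self.block_length_s <= 0:
            raise ValidationError("block_length_s must be > 0")
        ratio = self.session_length_s / self.block_length_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValidationError(
                "session_length_s must be an integer multiple of block_length_s "
                f"(got {self.session_length_s} / {self.block_length_s})"
            )
        if len(self.block_labels) != 2:
            raise ValidationError("block_labels must be an ordered pair")
        for name in ("photometry_rate_hz", "pose_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.licks_per_delivery < 1:
            raise ValidationError("licks_per_delivery must be >= 1")

    @property
    def n_blocks(self) -> int:
        return int(round(self.session_length_s / self.block_length_s))

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["block_labels"] = list(self.block_labels)
        Path(path).write_text(yaml.safe_dump({"session": doc}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict) or "session" not in doc:
            raise ParseError(f"{path}: expected a top-level 'session' section")
        kwargs = dict(doc["session"])
        if "block_labels" in kwargs:
            kwargs["block_labels"] = tuple(kwargs["block_labels"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# lick sessions
# ---------------------------------------------------------------------------


@dataclass
class LickSession:
    """A timestamped lick train plus its session configuration.

    ``lick_times_s`` are strictly increasing and lie in
    ``[0, session_length_s)``; ``spout_ids`` gives the per-lick spout
    label (which barrel delivered food on that lick).
    """

    lick_times_s: np.ndarray
    spout_ids: np.ndarray
    config: SessionConfig

    def __post_init__(self) -> None:
        self.lick_times_s = np.asarray(self.lick_times_s, dtype=float)
        self.spout_ids = np.asarray(self.spout_ids, dtype=object)
        if self.lick_times_s.shape != self.spout_ids.shape:
            raise ValidationError("lick_times_s and spout_ids must align")
        if self.lick_times_s.size:
            if np.any(np.diff(self.lick_times_s) <= 0):
                i = int(np.flatnonzero(np.diff(self.lick_times_s) <= 0)[0])
                raise ValidationError(
                    f"lick times not strictly increasing at index {i + 1} "
                    f"({self.lick_times_s[i]} -> {self.lick_times_s[i + 1]})"
                )
            if self.lick_times_s[0] < 0 or self.lick_times_s[-1] >= self.config.session_length_s:
                raise ValidationError(
                    "lick times must lie in [0, session_length_s)"
                )

    @property
    def n_licks(self) -> int:
        return int(self.lick_times_s.size)

    def interlick_intervals(self) -> np.ndarray:
        return np.diff(self.lick_times_s)


def _infer_config(last_time: float) -> SessionConfig:
    block = 120.0
    n = max(1, math.ceil((last_time + 1e-9) / block))
    if last_time >= n * block:  # pragma: no cover - guard against float edge
        n += 1
    return SessionConfig(session_length_s=n * block)


def read_lick_log(path: str | Path, config: SessionConfig | None = None) -> LickSession:
    """Read a lick log (columns ``time_s, spout``) into a :class:`LickSession`.

    Rejects malformed rows (with the offending line number) and
    non-monotone time stamps.  When no config is supplied, the session
    length is inferred as the smallest multiple of 120 s covering the
    last lick.
    """
    path = Path(path)
    frame = _read_csv(path, required=("time_s", "spout"))
    times = pd.to_numeric(frame["time_s"], errors="coerce")
    bad = times.index[times.isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ParseError(f"{path}: malformed time_s on line {int(bad[0]) + 2}")
    times = times.to_numpy(dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        i = int(np.flatnonzero(np.diff(times) <= 0)[0])
        raise ValidationError(
            f"{path}: lick times not strictly increasing at line {i + 3}"
        )
    if config is None:
        config = _infer_config(times[-1] if times.size else 0.0)
    return LickSession(times, frame["spout"].to_numpy(dtype=object), config)


def write_lick_log(session: LickSession, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"time_s": np.round(session.lick_times_s, TIME_DECIMALS), "spout": session.spout_ids}
    )
    frame.to_csv(path, index=False, float_format=f"%.{TIME_DECIMALS}f")


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # tokenizer reports the line itself
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return frame


# ---------------------------------------------------------------------------
# photometry frames
# ---------------------------------------------------------------------------

KNOWN_CHANNELS = ("415", "470")


def read_photometry_frames(path: str | Path) -> pd.DataFrame:
    """Read interleaved two-channel photometry frames and deinterleave.

    The file has columns ``time_s, channel, value`` with channel labels
    415 (isosbestic) and 470 (signal) interleaved in time.  Each 470
    sample is paired with the nearest-in-time 415 sample; the 470
    timestamps form the common time base, since the signal channel
    drives all downstream alignment.

    Returns a frame with columns ``time_s, raw_415, raw_470`` (one row
    per 470 sample).
    """
    path = Path(path)
    frame = _read_csv(path, required=("time_s", "channel", "value"))
    labels = frame["channel"].astype(str).str.strip()
    unknown = sorted(set(labels) - set(KNOWN_CHANNELS))
    if unknown:
        raise ParseError(f"{path}: unknown channel label(s) {unknown}")
    t = pd.to_numeric(frame["time_s"], errors="coerce").to_numpy(dtype=float)
    v = pd.to_numeric(frame["value"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(v).any():
        line = int(np.flatnonzero(np.isnan(t) | np.isnan(v))[0]) + 2
        raise ParseError(f"{path}: malformed numeric value on line {line}")
    is470 = (labels == "470").to_numpy()
    t470, v470 = t[is470], v[is470]
    t415, v415 = t[~is470], v[~is470]
    if abs(len(t470) - len(t415)) > 1:
        raise ValidationError(
            f"{path}: channel count imbalance ({len(t415)} x 415 vs {len(t470)} x 470)"
        )
    if len(t470) == 0 or len(t415) == 0:
        raise ValidationError(f"{path}: both channels must be present")
    paired = v415[pair_nearest(t470, t415)]
    return pd.DataFrame({"time_s": t470, "raw_415": paired, "raw_470": v470})


def pair_nearest(query_times: np.ndarray, ref_times: np.ndarray) -> np.ndarray:
    """Index of the nearest ``ref_times`` entry for each query time.

    Exact ties (a query sample equidistant between two reference frames,
    the generic case for interleaved acquisition) resolve to the earlier
    frame, with a 1-ns tolerance so the choice survives fixed-precision
    serialization.
    """
    ref_times = np.asarray(ref_times, dtype=float)
    idx = np.searchsorted(ref_times, query_times)
    idx = np.clip(idx, 1, len(ref_times) - 1)
    left = ref_times[idx - 1]
    right = ref_times[idx]
    idx -= (query_times - left) <= (right - query_times) + 1e-9
    return np.clip(idx, 0, len(ref_times) - 1)


def write_photometry_frames(
    time_415_s: np.ndarray,
    raw_415: np.ndarray,
    time_470_s: np.ndarray,
    raw_470: np.ndarray,
    path: str | Path,
) -> None:
    """Write two channel series back to the interleaved on-disk layout."""
    frame = pd.DataFrame(
        {
            "time_s": np.concatenate([time_415_s, time_470_s]),
            "channel": ["415"] * len(time_415_s) + ["470"] * len(time_470_s),
            "value": np.concatenate([raw_415, raw_470]),
        }
    ).sort_values("time_s", kind="stable")
    frame["time_s"] = frame["time_s"].round(TIME_DECIMALS)
    frame.to_csv(path, index=False, float_format=f"%.{TIME_DECIMALS}f")


# ---------------------------------------------------------------------------
# bout tables and laser logs
# ---------------------------------------------------------------------------

_BOUT_COLUMNS = [
    "start_s",
    "end_s",
    "duration_s",
    "n_licks",
    "block_index",
    "block_label",
    "spans_block",
]


def write_bout_table(bouts, path: str | Path) -> None:
    """Serialize a :class:`~boutometry.microstructure.BoutTable` to CSV.

    Session-level metadata rides in ``# key: value`` comment lines; the
    round trip reproduces the table bit-exactly at 6-decimal time
    precision.
    """
    frame = bouts.frame.copy()
    for col in ("start_s", "end_s", "duration_s"):
        frame[col] = frame[col].round(TIME_DECIMALS)
    header = [
        f"# ili_threshold_s: {_fmt_meta(bouts.ili_threshold_s)}",
        f"# fundamental_lick_interval_s: {_fmt_meta(bouts.fundamental_lick_interval_s)}",
        f"# n_discarded_licks: {bouts.n_discarded_licks}",
    ]
    body = frame[_BOUT_COLUMNS].to_csv(index=False, float_format=f"%.{TIME_DECIMALS}f")
    Path(path).write_text("\n".join(header) + "\n" + body)


def read_bout_table(path: str | Path):
    from .microstructure import BoutTable  # deferred: microstructure imports us

    path = Path(path)
    meta = _read_meta(path)
    frame = _read_csv(path, required=tuple(_BOUT_COLUMNS))
    frame["block_label"] = frame["block_label"].fillna("").astype(str)
    frame["spans_block"] = frame["spans_block"].astype(bool)
    frame["block_index"] = frame["block_index"].astype(int)
    frame["n_licks"] = frame["n_licks"].astype(int)
    return BoutTable(
        frame=frame,
        ili_threshold_s=_parse_meta(meta.get("ili_threshold_s")),
        fundamental_lick_interval_s=_parse_meta(meta.get("fundamental_lick_interval_s")),
        n_discarded_licks=int(meta.get("n_discarded_licks", 0)),
    )


def write_laser_log(log, path: str | Path) -> None:
    """Serialize a :class:`~boutometry.closedloop.LaserLog` to CSV."""
    rows = []
    for p in log.pulses:
        rows.append(("pulse", p[0], p[1], "", ""))
    for tr in log.trains:
        rows.append(("train", tr.start_s, tr.end_s, tr.trigger_index, int(tr.overhangs_block)))
    for r in log.ramps:
        rows.append(("ramp", r[0], r[1], "", ""))
    frame = pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "trigger_index", "flag"])
    header = f"# contingent: {int(log.contingent)}\n"
    body = frame.to_csv(index=False, float_format=f"%.{TIME_DECIMALS}f")
    Path(path).write_text(header + body)


def read_laser_log(path: str | Path):
    from .closedloop import LaserLog, Train  # deferred import

    path = Path(path)
    meta = _read_meta(path)
    frame = _read_csv(path, required=("kind", "start_s", "end_s"))
    pulses, trains, ramps = [], [], []
    for row in frame.itertuples(index=False):
        if row.kind == "pulse":
            pulses.append((float(row.start_s), float(row.end_s)))
        elif row.kind == "train":
            trains.append(
                Train(
                    float(row.start_s),
                    float(row.end_s),
                    int(float(row.trigger_index)),
                    bool(int(float(row.flag))),
                )
            )
        elif row.kind == "ramp":
            ramps.append((float(row.start_s), float(row.end_s)))
        else:
            raise ParseError(f"{path}: unknown event kind {row.kind!r}")
    return LaserLog(
        pulses=pulses,
        trains=trains,
        ramps=ramps,
        contingent=bool(int(meta.get("contingent", 1))),
    )


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _fmt_meta(value: float | None) -> str:
    return "" if value is None else f"{value:.{TIME_DECIMALS}f}"


def _parse_meta(text: str | None) -> float | None:
    if text is None or text == "":
        return None
    return float(text)
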