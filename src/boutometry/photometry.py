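"""Fiber-photometry preprocessing and bout-locked response statistics.

The pipeline follows the standard dual-excitation design: a
calcium/ligand-sensitive 470 nm channel and a calcium-independent
isosbestic 415 nm channel share the fiber, so bleaching and motion
appear in both.  The 415 nm series is robustly scaled to the 470 nm
series (iteratively reweighted least squares with bisquare weights,
the robust-regression default), either globally or in 5-minute chunks
when the two channels bleach at different rates.  The motion- and
bleach-corrected signal is the ratio dF = 470 / fitted 415, z-scored
against non-consummatory baseline periods.

Bout-locked statistics: peri-event matrices aligned to bout onset over
a -5..+20 s window; a fixed-window mean response and a variable-length
mean that NaN-pads samples after each bout's end (so long bouts are not
penalized by bouts that already ended); per-bout trapezoidal AUC of the
z-scored signal; and linear regressions of AUC on bout duration (the
palatability slope) and of AUC/duration on bout index across a session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .microstructure import BoutTable
from .session_io import LickSession, ValidationError

#: bisquare (Tukey biweight) tuning constant — 95% efficiency at the normal
BISQUARE_C = 4.685
IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8
MIN_SAMPLES_PER_FIT = 10


@dataclass
class PhotometryTrace:
    """Paired photometry series on the common (470 nm) time base.

    ``fitted_415``, ``dff``, ``z`` and ``baseline_mask`` are filled in
    by the pipeline stages; ``time_415_s`` optionally retains the raw
    isosbestic timestamps for file round-trips.
    """

    time_s: np.ndarray
    raw_415: np.ndarray
    raw_470: np.ndarray
    fitted_415: np.ndarray | None = None
    dff: np.ndarray | None = None
    z: np.ndarray | None = None
    baseline_mask: np.ndarray | None = None
    time_415_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.raw_415 = np.asarray(self.raw_415, dtype=float)
        self.raw_470 = np.asarray(self.raw_470, dtype=float)
        n = self.time_s.size
        for name in ("raw_415", "raw_470", "fitted_415", "dff", "z", "baseline_mask"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).size != n:
                raise ValidationError(f"{name} must match time_s in length")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)

    @property
    def dt(self) -> float:
        if self.n_samples < 2:
            raise ValidationError("need >= 2 samples to infer the sample interval")
        return float(np.median(np.diff(self.time_s)))


# ---------------------------------------------------------------------------
# isosbestic correction
# ---------------------------------------------------------------------------


def _robust_linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """IRLS fit of y on x with bisquare weights; returns (intercept, slope)."""
    if x.size < MIN_SAMPLES_PER_FIT:
        raise ValidationError(
            f"fit unit has {x.size} samples; need >= {MIN_SAMPLES_PER_FIT}"
        )
    if np.ptp(x) == 0:
        raise ValidationError("isosbestic channel has zero variance in a fit unit")
    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    res = model.fit(maxiter=IRLS_MAX_ITER, tol=IRLS_TOL)
    return float(res.params[0]), float(res.params[1])


def _chunk_slices(time_s: np.ndarray, chunk_s: float) -> list[slice]:
    """Contiguous chunk boundaries by time.

    A trailing partial chunk of at least half the chunk length is fit
    alone; a shorter tail is merged into the previous chunk.
    """
    t0, t1 = time_s[0], time_s[-1]
    span = t1 - t0
    n_full = int(span // chunk_s)
    edges = [t0 + k * chunk_s for k in range(max(1, n_full) + 1)]
    tail = t1 - edges[-1]
    if n_full >= 1 and tail >= chunk_s / 2:
        edges.append(t1)
    idx = np.searchsorted(time_s, edges[1:-1])
    bounds = [0, *idx.tolist(), time_s.size]
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def fit_isosbestic(
    trace: PhotometryTrace,
    mode: str = "global",
    chunk_s: float = 300.0,
) -> np.ndarray:
    """Scale the 415 nm channel to the 470 nm channel by robust regression.

    ``mode="global"`` fits one line over the whole session;
    ``mode="chunked"`` fits contiguous ``chunk_s`` (default 5-minute)
    chunks independently and concatenates, which absorbs channel-specific
    slow bleaching.
    """
    if mode not in ("global", "chunked"):
        raise ValidationError(f"unknown isosbestic mode {mode!r}")
    x, y = trace.raw_415, trace.raw_470
    fitted = np.empty_like(y)
    if mode == "global":
        b0, b1 = _robust_linear_fit(x, y)
        fitted[:] = b0 + b1 * x
    else:
        for sl in _chunk_slices(trace.time_s, chunk_s):
            b0, b1 = _robust_linear_fit(x[sl], y[sl])
            fitted[sl] = b0 + b1 * x[sl]
    return fitted


def compute_dff(trace: PhotometryTrace, min_fraction_of_median: float = 0.01) -> np.ndarray:
    """dF as the ratio 470 / fitted 415.

    Fitted values within ``min_fraction_of_median`` of zero (relative to
    the median fitted level) indicate a degenerate fit; those indices are
    reported as an error rather than silently clipped.
    """
    if trace.fitted_415 is None:
        raise ValidationError("fit_isosbestic must run before compute_dff")
    fitted = np.asarray(trace.fitted_415, dtype=float)
    floor = min_fraction_of_median * abs(float(np.median(fitted)))
    bad = np.flatnonzero(np.abs(fitted) < floor)
    if bad.size:
        head = bad[:10].tolist()
        raise ValidationError(
            f"fitted 415 is near zero at {bad.size} sample(s), e.g. indices {head}"
        )
    return trace.raw_470 / fitted


def baseline_mask(
    trace: PhotometryTrace,
    session: LickSession,
    exclusion_s: float = 10.0,
    settle_s: float = 60.0,
) -> np.ndarray:
    """Non-consummatory baseline samples.

    True for samples farther than ``exclusion_s`` from every lick and at
    least ``settle_s`` after session start (letting the preparation
    settle).  Errors if no baseline sample remains.
    """
    if exclusion_s < 0:
        raise ValidationError("exclusion_s must be >= 0")
    t = trace.time_s
    mask = t >= settle_s
    licks = session.lick_times_s
    if licks.size:
        idx = np.searchsorted(licks, t)
        dist = np.full(t.size, np.inf)
        has_right = idx < licks.size
        dist[has_right] = licks[idx[has_right]] - t[has_right]
        has_left = idx > 0
        dist[has_left] = np.minimum(dist[has_left], t[has_left] - licks[idx[has_left] - 1])
        mask &= dist > exclusion_s
    if not mask.any():
        raise ValidationError("no baseline samples available (continuous licking?)")
    return mask


def zscore_trace(dff: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """z-score dF against the baseline mean and standard deviation."""
    dff = np.asarray(dff, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("baseline mask is empty")
    base = dff[mask]
    sd = float(base.std(ddof=0))
    if sd == 0:
        raise ValidationError("baseline standard deviation is zero")
    return (dff - float(base.mean())) / sd


def preprocess(
    trace: PhotometryTrace,
    session: LickSession,
    mode: str = "global",
    chunk_s: float = 300.0,
    exclusion_s: float = 10.0,
    settle_s: float = 60.0,
) -> PhotometryTrace:
    """Run the full correction pipeline; returns a completed trace."""
    fitted = fit_isosbestic(trace, mode=mode, chunk_s=chunk_s)
    out = replace(trace, fitted_415=fitted)
    out.dff = compute_dff(out)
    out.baseline_mask = baseline_mask(out, session, exclusion_s, settle_s)
    out.z = zscore_trace(out.dff, out.baseline_mask)
    return out


# ---------------------------------------------------------------------------
# peri-event matrices
# ---------------------------------------------------------------------------


@dataclass
class PSTHMatrix:
    """Bout-onset-aligned peri-event matrix at the native sample interval.

    ``matrix`` holds the fixed-window view (NaN only where the window
    fell outside the recording; those rows are flagged ``clipped``);
    ``matrix_variable`` additionally NaN-pads samples after each bout's
    end, for the variable-length estimator.
    """

    offsets_s: np.ndarray
    matrix: np.ndarray
    matrix_variable: np.ndarray
    bout_durations_s: np.ndarray
    alignment_times_s: np.ndarray
    clipped: np.ndarray

    @property
    def n_bouts(self) -> int:
        return self.matrix.shape[0]


def align_psth(
    trace: PhotometryTrace,
    bouts: BoutTable,
    window_s: tuple[float, float] = (-5.0, 20.0),
) -> PSTHMatrix:
    """Align the z-scored signal to bout onsets on a common grid."""
    if trace.z is None:
        raise ValidationError("trace has no z-scored signal; run preprocess first")
    dt = trace.dt
    k0 = int(round(window_s[0] / dt))
    k1 = int(round(window_s[1] / dt))
    rel = np.arange(k0, k1 + 1)
    offsets = rel * dt
    starts = bouts.frame["start_s"].to_numpy()
    durations = bouts.frame["duration_s"].to_numpy()
    n = trace.n_samples
    mat = np.full((len(starts), rel.size), np.nan)
    clipped = np.zeros(len(starts), dtype=bool)
    t0 = trace.time_s[0]
    for i, s in enumerate(starts):
        onset = int(round((s - t0) / dt))
        cols = onset + rel
        ok = (cols >= 0) & (cols < n)
        clipped[i] = not ok.all()
        mat[i, ok] = trace.z[cols[ok]]
    var = mat.copy()
    var[offsets[None, :] > durations[:, None]] = np.nan
    return PSTHMatrix(
        offsets_s=offsets,
        matrix=mat,
        matrix_variable=var,
        bout_durations_s=durations,
        alignment_times_s=starts,
        clipped=clipped,
    )


def mean_response_fixed(psth: PSTHMatrix) -> np.ndarray:
    """Per-bin mean over all bouts, post-bout samples included.

    Bouts that have already ended keep contributing their (typically
    low) post-bout signal, which depresses the late part of the profile.
    """
    if psth.n_bouts == 0:
        raise ValidationError("PSTH matrix has no rows")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(psth.matrix, axis=0)


def mean_response_variable(psth: PSTHMatrix) -> np.ndarray:
    """Per-bin mean ignoring samples after each bout's end.

    Bins past the longest bout are NaN.  For every bin at or before the
    shortest bout duration this estimator coincides exactly with the
    fixed-window mean.
    """
    if psth.n_bouts == 0:
        raise ValidationError("PSTH matrix has no rows")
    with np.errstate(invalid="ignore"):
        out = np.full(psth.offsets_s.size, np.nan)
        valid = ~np.all(np.isnan(psth.matrix_variable), axis=0)
        out[valid] = np.nanmean(psth.matrix_variable[:, valid], axis=0)
    return out


# ---------------------------------------------------------------------------
# AUC and regressions
# ---------------------------------------------------------------------------


def bout_auc(
    trace: PhotometryTrace,
    start_s: float,
    end_s: float,
    window_mode: str = "bout",
    fixed_horizon_s: float = 20.0,
) -> float:
    """Trapezoidal integral of z over one bout (units: z·s).

    ``window_mode="bout"`` integrates onset to offset (the default; the
    statistic is regressed on bout duration), ``"fixed"`` integrates
    onset to onset + ``fixed_horizon_s``.  Endpoints off the sample grid
    are linearly interpolated, making the integral exactly additive over
    interior split points.
    """
    if trace.z is None:
        raise ValidationError("trace has no z-scored signal")
    if window_mode not in ("bout", "fixed"):
        raise ValidationError(f"unknown window_mode {window_mode!r}")
    if window_mode == "fixed":
        end_s = start_s + fixed_horizon_s
    if end_s < start_s:
        raise ValidationError("bout end precedes start")
    t = trace.time_s
    # interleaved acquisition leaves up to one sample interval of slack at
    # the session edges; clip that, but reject genuinely out-of-range bouts
    slack = trace.dt if trace.n_samples > 1 else 0.0
    if start_s < t[0] - slack or end_s > t[-1] + slack:
        raise ValidationError("bout lies outside the recorded trace")
    start_s = max(start_s, t[0])
    end_s = min(end_s, t[-1])
    if end_s <= start_s:
        return 0.0
    if end_s == start_s:
        return 0.0
    lo = np.searchsorted(t, start_s, side="right")
    hi = np.searchsorted(t, end_s, side="left")
    ts = np.concatenate([[start_s], t[lo:hi], [end_s]])
    zs = np.interp(ts, t, trace.z)
    return float(np.trapezoid(zs, ts))


def bout_auc_records(
    trace: PhotometryTrace,
    bouts: BoutTable,
    window_mode: str = "bout",
    fixed_horizon_s: float = 20.0,
) -> pd.DataFrame:
    """Per-bout AUC records: ``bout_id, auc, duration_s, block_label``."""
    rows = []
    for i, row in enumerate(bouts.frame.itertuples(index=False)):
        auc = bout_auc(trace, row.start_s, row.end_s, window_mode, fixed_horizon_s)
        rows.append(
            {
                "bout_id": i,
                "auc": auc,
                "duration_s": row.duration_s,
                "block_label": row.block_label,
                "spans_block": row.spans_block,
            }
        )
    return pd.DataFrame(
        rows, columns=["bout_id", "auc", "duration_s", "block_label", "spans_block"]
    )


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary for AUC-vs-duration or session-order regressions."""

    slope: float
    intercept: float
    n: int
    r_squared: float
    group: str = ""


def _ols(x: np.ndarray, y: np.ndarray, group: str = "") -> RegressionResult:
    if x.size < 2:
        raise ValidationError(f"need >= 2 points to regress (group {group!r})")
    if np.ptp(x) == 0:
        raise ValidationError(f"zero predictor variance (group {group!r})")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
        r_squared=float(fit.rvalue**2),
        group=group,
    )


def auc_duration_regression(
    records: pd.DataFrame,
    group_by: str | None = "block_label",
    exclude_spanning: bool = True,
) -> dict[str, RegressionResult]:
    """OLS of per-bout AUC on bout duration, optionally per condition.

    The slope (z·s per s of consumption) is the palatability metric:
    sustained responses during longer bouts of more palatable food show
    as a steeper slope.  Bouts spanning two blocks are excluded from
    block-conditioned fits.
    """
    frame = records
    if exclude_spanning and "spans_block" in frame.columns and group_by:
        frame = frame[~frame["spans_block"].astype(bool)]
    out: dict[str, RegressionResult] = {}
    if group_by is None:
        out["all"] = _ols(
            frame["duration_s"].to_numpy(float), frame["auc"].to_numpy(float), "all"
        )
        return out
    for label, sub in frame.groupby(group_by, sort=True):
        out[str(label)] = _ols(
            sub["duration_s"].to_numpy(float), sub["auc"].to_numpy(float), str(label)
        )
    return out


def session_order_regression(records: pd.DataFrame) -> dict[str, RegressionResult]:
    """AUC and bout duration regressed on bout index across the session.

    A negative AUC slope across a session indicates within-session
    decline (e.g. increasing satiety with accumulating intake).
    """
    idx = records["bout_id"].to_numpy(float)
    return {
        "auc_vs_index": _ols(idx, records["auc"].to_numpy(float), "auc_vs_index"),
        "duration_vs_index": _ols(
            idx, records["duration_s"].to_numpy(float), "duration_vs_index"
        ),
    }
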