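"""Block-wise and bout-wise comparisons, and the session report.

The comparisons mirror the standard closed-loop analysis: paired
per-subject condition means (laser-ON vs laser-OFF, or high vs low
palatability), two-sample Kolmogorov-Smirnov tests on bout-duration
distributions, and per-1-s-bin lick-count contrasts over the first
20 s of each bout.  The binned counts are emitted as a long-format
table ready for an external negative-binomial mixed-model fit (animal
and bout-within-animal random intercepts); a self-contained permutation
alternative — condition labels shuffled across bouts within animal —
provides per-bin p-values without mixed-model machinery.  All
multiple-comparison adjustment uses Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .microstructure import BoutTable, bout_lick_rate_profile
from .session_io import LickSession, ValidationError


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical comparison: estimate, raw and adjusted p, test name."""

    test: str
    estimate: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# paired summaries and distribution tests
# ---------------------------------------------------------------------------


def paired_block_summary(
    values: pd.DataFrame,
    subject_col: str = "subject",
    condition_col: str = "condition",
    value_col: str = "value",
) -> tuple[pd.DataFrame, ComparisonResult]:
    """Per-subject condition means and the paired t comparison.

    ``values`` is long-format with one row per observation.  Exactly two
    conditions are compared; subjects missing a condition are excluded
    with a warning.  When every paired difference is zero the t
    statistic is indeterminate and is reported as 0 with a degeneracy
    flag.
    """
    conditions = sorted(values[condition_col].astype(str).unique())
    if len(conditions) != 2:
        raise ValidationError(f"need exactly 2 conditions, got {conditions}")
    a, b = conditions
    rows = []
    for subject, sub in values.groupby(subject_col, sort=True):
        by_cond = sub.groupby(sub[condition_col].astype(str))[value_col].mean()
        if a not in by_cond.index or b not in by_cond.index:
            warnings.warn(
                f"subject {subject!r} lacks condition(s); excluded from pairing",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "subject": subject,
                f"mean_{a}": float(by_cond[a]),
                f"mean_{b}": float(by_cond[b]),
                "difference": float(by_cond[b] - by_cond[a]),
            }
        )
    summary = pd.DataFrame(rows)
    if summary.empty:
        raise ValidationError("no subject has both conditions")
    diffs = summary["difference"].to_numpy()
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        result = ComparisonResult(
            test="paired_t",
            estimate=float(diffs.mean()),
            p_value=1.0,
            n=len(diffs),
            degenerate=True,
        )
    else:
        t = sps.ttest_rel(
            summary[f"mean_{b}"].to_numpy(), summary[f"mean_{a}"].to_numpy()
        )
        result = ComparisonResult(
            test="paired_t",
            estimate=float(diffs.mean()),
            p_value=float(t.pvalue),
            n=len(diffs),
        )
    return summary, result


def ks_compare(durations_a: Sequence[float], durations_b: Sequence[float]) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov comparison of two duration samples."""
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, mode="asymp")
    return ComparisonResult(
        test="ks_2samp",
        estimate=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(a.size + b.size),
    )


# ---------------------------------------------------------------------------
# binned count table
# ---------------------------------------------------------------------------


@dataclass
class BinnedCountTable:
    """Long-format per-(bout, bin) lick counts for mixed-model fitting.

    ``frame`` columns: ``animal_id, bout_id, bin_index`` (1-based 1-s
    bins over the first 20 s), ``condition``, ``count`` (NaN where the
    bout had already ended), ``missing``.  ``zero_fraction`` summarizes
    the observed proportion of zero counts per bin among non-missing
    entries — in bout-structured data this generally increases across
    bins, motivating zero-inflated count models.
    """

    frame: pd.DataFrame
    zero_fraction: pd.DataFrame
    bin_s: float = 1.0


def make_binned_count_table(
    bouts: BoutTable,
    session: LickSession,
    animal_id: str = "m0",
    bin_s: float = 1.0,
    horizon_s: float = 20.0,
    exclude_spanning: bool = True,
) -> BinnedCountTable:
    """Build the long-format binned lick-count table for one session."""
    frame = bouts.frame
    if exclude_spanning and len(frame):
        keep = ~frame["spans_block"].astype(bool)
        bouts = BoutTable(
            frame=frame[keep].reset_index(drop=True),
            ili_threshold_s=bouts.ili_threshold_s,
            fundamental_lick_interval_s=bouts.fundamental_lick_interval_s,
            n_discarded_licks=bouts.n_discarded_licks,
        )
    profile = bout_lick_rate_profile(bouts, session, bin_s=bin_s, horizon_s=horizon_s)
    n_bins = profile.counts.shape[1]
    rows = []
    for i, row in enumerate(bouts.frame.itertuples(index=False)):
        for k in range(n_bins):
            c = profile.counts[i, k]
            rows.append(
                {
                    "animal_id": animal_id,
                    "bout_id": i,
                    "bin_index": k + 1,
                    "condition": row.block_label,
                    "count": c,
                    "missing": bool(np.isnan(c)),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["animal_id", "bout_id", "bin_index", "condition", "count", "missing"],
    )
    zf_rows = []
    for k in range(n_bins):
        col = profile.counts[:, k]
        valid = col[~np.isnan(col)]
        zf_rows.append(
            {
                "bin_index": k + 1,
                "n_valid": int(valid.size),
                "zero_fraction": float((valid == 0).mean()) if valid.size else float("nan"),
            }
        )
    return BinnedCountTable(frame=table, zero_fraction=pd.DataFrame(zf_rows), bin_s=bin_s)


def concat_tables(tables: Sequence[BinnedCountTable]) -> BinnedCountTable:
    """Stack per-session tables (e.g. one per animal) into one."""
    frame = pd.concat([t.frame for t in tables], ignore_index=True)
    zf = (
        pd.concat([t.zero_fraction for t in tables])
        .groupby("bin_index", as_index=False)
        .apply(
            lambda g: pd.Series(
                {
                    "n_valid": int(g["n_valid"].sum()),
                    "zero_fraction": float(
                        np.average(
                            g["zero_fraction"].fillna(0.0), weights=np.maximum(g["n_valid"], 1)
                        )
                    ),
                }
            ),
            include_groups=False,
        )
        .reset_index(drop=True)
    )
    return BinnedCountTable(frame=frame, zero_fraction=zf, bin_s=tables[0].bin_s)


# ---------------------------------------------------------------------------
# permutation contrast and BH adjustment
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _count_assignments(group_sizes: list[tuple[int, int]]) -> float:
    total = 1.0
    for n, k in group_sizes:
        total *= math.comb(n, k)
    return total


def per_bin_permutation_test(
    table: BinnedCountTable,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin permutation contrast of lick counts between two conditions.

    The observed statistic per bin is the absolute difference of
    condition means across bouts (missing bins ignored).  Condition
    labels are permuted across bouts *within each animal*, respecting
    the nesting structure.  When the number of distinct label
    assignments does not exceed ``n_perm`` the test enumerates them
    exhaustively (exact); otherwise it samples ``n_perm`` random
    permutations and reports the add-one Monte-Carlo p-value.  BH
    adjustment is applied across bins.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    frame = table.frame
    conditions = sorted(frame["condition"].astype(str).unique())
    if len(conditions) != 2:
        raise ValidationError(f"need exactly 2 conditions, got {conditions}")
    wide = frame.pivot_table(
        index=["animal_id", "bout_id"],
        columns="bin_index",
        values="count",
        dropna=False,
    ).sort_index()
    labels = (
        frame.drop_duplicates(["animal_id", "bout_id"])
        .set_index(["animal_id", "bout_id"])["condition"]
        .astype(str)
        .reindex(wide.index)
    )
    counts = wide.to_numpy(dtype=float)
    lab = labels.to_numpy()
    animals = wide.index.get_level_values(0).to_numpy()
    is_b = lab == conditions[1]

    def stat(flags: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_b = np.nanmean(np.where(flags[:, None], counts, np.nan), axis=0)
            mean_a = np.nanmean(np.where(flags[:, None], np.nan, counts), axis=0)
        return np.abs(mean_b - mean_a)

    observed = stat(is_b)
    groups = [np.flatnonzero(animals == a) for a in dict.fromkeys(animals.tolist())]
    sizes = [(len(g), int(is_b[g].sum())) for g in groups]
    total = _count_assignments(sizes)

    n_bins = counts.shape[1]
    if total <= n_perm:
        exceed = np.zeros(n_bins)
        n_done = 0
        choices = [itertools.combinations(range(len(g)), k) for g, (_, k) in zip(groups, sizes)]
        for combo in itertools.product(*choices):
            flags = np.zeros(len(lab), dtype=bool)
            for g, picked in zip(groups, combo):
                flags[g[list(picked)]] = True
            exceed += stat(flags) >= observed - 1e-12
            n_done += 1
        p_raw = exceed / n_done
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(n_bins)
        for _ in range(n_perm):
            flags = np.zeros(len(lab), dtype=bool)
            for g, (_, k) in zip(groups, sizes):
                flags[rng.choice(g, size=k, replace=False)] = True
            exceed += stat(flags) >= observed - 1e-12
        p_raw = (1.0 + exceed) / (n_perm + 1.0)

    p_raw = np.where(np.isnan(observed), np.nan, p_raw)
    ok = ~np.isnan(p_raw)
    p_adj = np.full(n_bins, np.nan)
    if ok.any():
        p_adj[ok] = bh_adjust(p_raw[ok])
    return pd.DataFrame(
        {
            "bin_index": wide.columns.to_numpy(),
            "observed_diff": observed,
            "p_raw": p_raw,
            "p_bh": p_adj,
            "significant": p_adj < alpha,
        }
    )


# ---------------------------------------------------------------------------
# session report
# ---------------------------------------------------------------------------


def _fmt(x: float | None, nd: int = 4) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{nd}f}"


def session_report(
    microstructure: dict | None = None,
    photometry: dict | None = None,
    closedloop: dict | None = None,
    stats: dict | None = None,
    title: str = "Session report",
) -> str:
    """Assemble a deterministic markdown report from pipeline outputs.

    Each argument is a flat mapping of labels to scalars/strings as
    produced by :func:`analyze_session`; missing stages are reported as
    explicit gaps rather than omitted.  Identical inputs yield a
    byte-identical document.
    """
    lines = [f"# {title}", ""]
    for heading, section in (
        ("Feeding microstructure", microstructure),
        ("Photometry", photometry),
        ("Closed-loop stimulation", closedloop),
        ("Statistics", stats),
    ):
        lines.append(f"## {heading}")
        if not section:
            lines.append("*not available for this session*")
        else:
            for key in sorted(section):
                value = section[key]
                if isinstance(value, float):
                    value = _fmt(value)
                lines.append(f"- {key}: {value}")
        lines.append("")
    return "\n".join(lines)


def analyze_session(
    session: LickSession,
    bouts: BoutTable,
    schedule=None,
    trace=None,
    laser_log=None,
) -> dict[str, dict]:
    """Compute the standard summary sections for :func:`session_report`."""
    from . import microstructure as ms
    from . import photometry as ph

    sections: dict[str, dict] = {}
    micro = {
        "n_licks": session.n_licks,
        "n_bouts": bouts.n_bouts,
        "discarded_licks": bouts.n_discarded_licks,
        "ili_threshold_s": bouts.ili_threshold_s,
        "mean_bout_duration_s": (
            float(bouts.frame["duration_s"].mean()) if bouts.n_bouts else float("nan")
        ),
        "energy_intake_kcal": ms.energy_intake(session.config, n_licks=session.n_licks),
    }
    if session.n_licks >= 2:
        micro["fundamental_lick_interval_s"] = ms.fundamental_lick_interval(session)
    sections["microstructure"] = micro

    if trace is not None and trace.z is not None and bouts.n_bouts:
        records = ph.bout_auc_records(trace, bouts)
        photo = {
            "n_samples": trace.n_samples,
            "mean_bout_auc_zs": float(records["auc"].mean()),
        }
        try:
            regs = ph.auc_duration_regression(records, group_by="block_label")
            for label, reg in regs.items():
                photo[f"auc_slope[{label}]"] = reg.slope
        except ValidationError:
            try:
                reg = ph.auc_duration_regression(records, group_by=None)["all"]
                photo["auc_slope[all]"] = reg.slope
            except ValidationError:
                pass
        sections["photometry"] = photo
    else:
        sections["photometry"] = {}

    if laser_log is not None:
        sections["closedloop"] = {
            "n_trains": len(laser_log.trains),
            "n_pulses": len(laser_log.pulses),
            "total_illumination_s": laser_log.total_illumination_s(),
            "contingent": str(laser_log.contingent),
        }
    else:
        sections["closedloop"] = {}

    stats: dict = {}
    if schedule is not None and bouts.n_bouts:
        labeled = bouts.frame[~bouts.frame["spans_block"].astype(bool)]
        by_label = labeled.groupby("block_label")["duration_s"]
        groups = {k: v.to_numpy() for k, v in by_label}
        if len(groups) == 2 and all(len(v) for v in groups.values()):
            (la, va), (lb, vb) = sorted(groups.items())
            ks = ks_compare(va, vb)
            stats[f"ks_D[{la} vs {lb}]"] = ks.estimate
            stats[f"ks_p[{la} vs {lb}]"] = ks.p_value
    sections["stats"] = stats
    return sections
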