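"""Avalanche definition and statistics: binning, clustering, controls.

An avalanche is a maximal run of consecutive occupied time bins of width dt
on the whole array; its size s is the number of events it contains. The
temporal resolution dt is not free: it is the inverse of the mean array-wide
event rate — computed once over the whole analyzed span (fixed binning), or
per trial and per behavioral epoch (adaptive binning), which restores the
separation of time scales when the event rate is transiently modulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .raster import EpochSpec, EventRaster

__all__ = [
    "BinningPlan",
    "compute_fixed_dt",
    "compute_adaptive_dt",
    "cluster",
    "cluster_raster_fixed",
    "cluster_raster_adaptive",
    "rate_size_timecourse",
    "shift_predictor",
    "split_trials_by_rate",
    "per_trial_size_difference",
]

AVALANCHE_COLUMNS = ["trial", "epoch", "start", "duration", "size", "dt"]


@dataclass
class BinningPlan:
    """Per-(trial, epoch) temporal resolutions for adaptive binning."""

    mode: str  # "fixed" | "adaptive"
    dt_global: float | None = None
    dt_table: dict = field(default_factory=dict)  # (trial, epoch) -> dt
    empty_cells: list = field(default_factory=list)  # (trial, epoch) with no events


def compute_fixed_dt(raster: EventRaster, total_time: float | None = None) -> float:
    """dt = analyzed time / array-wide event count (inverse mean event rate).

    ``total_time`` defaults to the per-trial span times the number of trials
    (or the observed time extent for continuous recordings).
    """
    n = len(raster.events)
    if n < 2:
        raise ValueError("cannot define dt from fewer than 2 events")
    if total_time is None:
        if raster.trial_span is not None:
            total_time = raster.span_duration() * raster.n_trials
        else:
            total_time = raster.span_duration()
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    return total_time / n


def compute_adaptive_dt(raster: EventRaster, epochs: EpochSpec) -> BinningPlan:
    """Per-trial, per-epoch dt = epoch duration / event count in that cell.

    Cells with no events have no defined dt; they are listed in
    ``empty_cells`` and contribute no avalanches downstream.
    """
    ev = raster.events
    plan = BinningPlan(mode="adaptive")
    trials = raster.trials
    for trial in trials:
        tr_ev = ev[ev["trial"] == trial]
        for name, (a, b) in epochs.items():
            n = int(((tr_ev["time"] >= a) & (tr_ev["time"] < b)).sum())
            if n == 0:
                plan.empty_cells.append((int(trial), name))
            else:
                plan.dt_table[(int(trial), name)] = (b - a) / n
    if plan.empty_cells:
        warnings.warn(
            f"{len(plan.empty_cells)} (trial, epoch) cells without events: "
            "no dt defined there"
        )
    return plan


def cluster(times: np.ndarray, dt: float, origin: float = 0.0) -> list[np.ndarray]:
    """Partition event times into maximal runs of consecutive occupied bins.

    Bins of width ``dt`` are anchored at ``origin``; a cluster starts at the
    transition from an empty to an occupied bin and ends before the next
    empty bin. Returns the member-event index arrays (into the sorted order
    of ``times``), each index appearing in exactly one cluster.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return []
    order = np.argsort(t, kind="stable")
    b = np.floor((t[order] - origin) / dt).astype(np.int64)
    breaks = np.flatnonzero(np.diff(b) > 1) + 1
    return [order[g] for g in np.split(np.arange(t.size), breaks)]


def _avalanche_rows(times, dt, origin, trial, epoch_of_start) -> list[tuple]:
    t = np.asarray(times, dtype=float)
    rows = []
    for members in cluster(t, dt, origin):
        tt = t[members]
        b = np.floor((tt - origin) / dt).astype(np.int64)
        rows.append(
            (
                trial,
                epoch_of_start,
                float(tt.min()),
                float((b.max() - b.min() + 1) * dt),
                int(len(members)),
                dt,
            )
        )
    return rows


def cluster_raster_fixed(
    raster: EventRaster,
    dt: float,
    epochs: EpochSpec | None = None,
    anchor: str = "trial",
) -> pd.DataFrame:
    """Cluster each trial at one global dt.

    With ``anchor='trial'`` (default) bins are anchored at the trial start and
    clusters may span epoch boundaries; the epoch label is the epoch of the
    cluster's first event. With ``anchor='epoch'`` each epoch is clustered
    independently (bins re-anchored at the epoch start).
    """
    ev = raster.events
    t0 = raster.trial_span[0] if raster.trial_span is not None else float(ev["time"].min())
    rows: list[tuple] = []
    for trial in raster.trials:
        tt = ev.loc[ev["trial"] == trial, "time"].to_numpy()
        if anchor == "trial" or epochs is None:
            rows.extend(_avalanche_rows(tt, dt, t0, int(trial), ""))
        elif anchor == "epoch":
            for name, (a, b) in epochs.items():
                sub = tt[(tt >= a) & (tt < b)]
                rows.extend(_avalanche_rows(sub, dt, a, int(trial), name))
        else:
            raise ValueError("anchor must be 'trial' or 'epoch'")
    df = pd.DataFrame(rows, columns=AVALANCHE_COLUMNS)
    if epochs is not None and anchor == "trial" and len(df):
        df["epoch"] = epochs.label_times(df["start"].to_numpy())
    return df


def cluster_raster_adaptive(
    raster: EventRaster, plan: BinningPlan, epochs: EpochSpec
) -> pd.DataFrame:
    """Cluster each (trial, epoch) cell at its own dt, bins anchored at epoch start.

    Avalanches never span epoch boundaries (dt differs across epochs, so a
    boundary-spanning cluster would be ill-defined); empty cells contribute
    nothing.
    """
    ev = raster.events
    rows: list[tuple] = []
    for trial in raster.trials:
        tt = ev.loc[ev["trial"] == trial, "time"].to_numpy()
        for name, (a, b) in epochs.items():
            dt = plan.dt_table.get((int(trial), name))
            if dt is None:
                continue
            sub = tt[(tt >= a) & (tt < b)]
            rows.extend(_avalanche_rows(sub, dt, a, int(trial), name))
    return pd.DataFrame(rows, columns=AVALANCHE_COLUMNS)


def _window_stats(av: pd.DataFrame, centers, window, n_trials):
    half = window / 2.0
    rate = np.empty(len(centers))
    msize = np.full(len(centers), np.nan)
    t = av["start"].to_numpy()
    s = av["size"].to_numpy()
    for i, c in enumerate(centers):
        m = (t >= c - half) & (t < c + half)
        rate[i] = m.sum() / (n_trials * window)
        if m.any():
            msize[i] = s[m].mean()
    return rate, msize


def rate_size_timecourse(
    avalanches: pd.DataFrame,
    trial_span: tuple[float, float],
    window: float = 0.1,
    step: float = 0.05,
    n_shuffles: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Time-resolved avalanche rate and mean size with shuffle significance.

    The observed time courses (sliding window) are compared per time point
    against ``n_shuffles`` surrogate sets: sizes permuted across avalanches
    with occurrence times kept (size null, rate-preserving), and occurrence
    times redrawn uniformly within the trial (rate null). Two-sided flags at
    p <= 0.05 with p = (1 + #shuffles-as-extreme) / (1 + n_shuffles).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    av = avalanches
    n_trials = max(int(av["trial"].nunique()), 1)
    if n_trials < 2:
        warnings.warn("time-course significance with fewer than 2 trials")
    t0, t1 = trial_span
    centers = np.arange(t0 + window / 2.0, t1 - window / 2.0 + 1e-12, step)
    rate_obs, size_obs = _window_stats(av, centers, window, n_trials)

    sizes = av["size"].to_numpy()
    n_av = len(av)
    rate_null = np.empty((n_shuffles, len(centers)))
    size_null = np.empty((n_shuffles, len(centers)))
    for b in range(n_shuffles):
        perm = av.assign(size=sizes[rng.permutation(n_av)])
        _, size_null[b] = _window_stats(perm, centers, window, n_trials)
        moved = av.assign(start=rng.uniform(t0, t1, n_av))
        rate_null[b], _ = _window_stats(moved, centers, window, n_trials)

    def flags(obs, null):
        with np.errstate(invalid="ignore"):
            ge = np.nansum(null >= obs[None, :], axis=0)
            le = np.nansum(null <= obs[None, :], axis=0)
        p_high = (1.0 + ge) / (1.0 + n_shuffles)
        p_low = (1.0 + le) / (1.0 + n_shuffles)
        return p_high, p_low

    p_rate_high, p_rate_low = flags(rate_obs, rate_null)
    p_size_high, p_size_low = flags(size_obs, size_null)
    return pd.DataFrame(
        {
            "time": centers,
            "rate": rate_obs,
            "mean_size": size_obs,
            "rate_high": p_rate_high <= 0.05,
            "rate_low": p_rate_low <= 0.05,
            "size_high": p_size_high <= 0.05,
            "size_low": p_size_low <= 0.05,
            "p_rate_high": p_rate_high,
            "p_rate_low": p_rate_low,
            "p_size_high": p_size_high,
            "p_size_low": p_size_low,
        }
    )


def shift_predictor(
    raster: EventRaster, rng: np.random.Generator | None = None
) -> EventRaster:
    """Shuffle the trial order independently per electrode (shift predictor).

    Per-electrode event times within each trial slot are preserved, so every
    electrode's trial-averaged rate profile is exactly unchanged, while
    within-trial correlations across electrodes are destroyed.
    """
    trials = raster.trials
    if len(trials) < 2:
        warnings.warn("shift predictor with a single trial is a no-op")
        return EventRaster(raster.events.copy(), raster.geometry, raster.trial_span)
    if rng is None:
        rng = np.random.default_rng(0)
    ev = raster.events.copy()
    pos = {t: i for i, t in enumerate(trials)}
    out_trial = ev["trial"].to_numpy().copy()
    for elec in np.sort(ev["electrode"].unique()):
        sel = ev["electrode"].to_numpy() == elec
        perm = trials[rng.permutation(len(trials))]
        out_trial[sel] = np.asarray([perm[pos[t]] for t in ev.loc[sel, "trial"]])
    ev["trial"] = out_trial
    return EventRaster(ev, raster.geometry, raster.trial_span)


def split_trials_by_rate(
    raster: EventRaster, epochs: EpochSpec, epoch: str
) -> tuple[np.ndarray, np.ndarray]:
    """Median split of trials by their event rate in the given epoch.

    Trials are ordered by (epoch event count, trial id); the lower half is
    the low-rate set (ties straddling the median go to the low set by this
    deterministic ordering). Returns (low trial ids, high trial ids).
    """
    a, b = epochs[epoch]
    ev = raster.events
    counts = {
        int(t): int(((ev["trial"] == t) & (ev["time"] >= a) & (ev["time"] < b)).sum())
        for t in raster.trials
    }
    if len(set(counts.values())) == 1:
        warnings.warn("all trials have identical epoch rate: split is arbitrary")
    order = sorted(counts, key=lambda t: (counts[t], t))
    half = len(order) // 2
    return np.asarray(order[:half]), np.asarray(order[half:])


def per_trial_size_difference(
    av_fixed: pd.DataFrame,
    av_adaptive: pd.DataFrame,
    epoch_a: str,
    epoch_b: str,
) -> dict:
    """Per-trial mean-size differences (epoch_a - epoch_b), fixed vs adaptive.

    Trials lacking avalanches in either epoch (for a given binning) are
    excluded and counted. The two difference distributions are compared with
    a two-sample Kolmogorov-Smirnov test (significant at p <= 0.05).
    """

    def diffs(av: pd.DataFrame) -> tuple[np.ndarray, int]:
        out, excluded = [], 0
        for trial, g in av.groupby("trial"):
            sa = g.loc[g["epoch"] == epoch_a, "size"]
            sb = g.loc[g["epoch"] == epoch_b, "size"]
            if len(sa) == 0 or len(sb) == 0:
                excluded += 1
                continue
            out.append(sa.mean() - sb.mean())
        return np.asarray(out), excluded

    d_fixed, excl_f = diffs(av_fixed)
    d_adaptive, excl_a = diffs(av_adaptive)
    if len(d_fixed) and len(d_adaptive):
        ks = stats.ks_2samp(d_fixed, d_adaptive)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = np.nan, np.nan
    return {
        "diff_fixed": d_fixed,
        "diff_adaptive": d_adaptive,
        "excluded_trials_fixed": excl_f,
        "excluded_trials_adaptive": excl_a,
        "ks_stat": ks_stat,
        "ks_p": ks_p,
        "significant": bool(ks_p <= 0.05) if np.isfinite(ks_p) else False,
    }
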