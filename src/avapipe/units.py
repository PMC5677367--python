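"""Spike-train statistics: PSTH with surrogate significance, Fano factor.

Spikes arrive as a table of (unit, trial, time) with times relative to the
trial alignment point. The PSTH is the trial-averaged firing rate in a
sliding window (250 ms, stepped by 50 ms). Significance of rate excursions is
assessed against surrogate trains built by permuting inter-spike intervals
within each trial, which preserves the spike count and interval content but
destroys the temporal locking to the trial event.

The Fano factor is estimated per time window as the slope of the ordinary
least-squares regression of the across-trial spike-count variance on the
mean, one point per unit; a population of Poisson units has slope 1. To
control for rate confounds, mean-matching greedily removes the units that
contribute most to the across-period rate difference until that difference
is no longer significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FanoResult", "psth", "surrogate_trains", "rate_significance", "fano_factor"]


@dataclass
class FanoResult:
    """Per-window Fano slope with 95% CI and the mean-matching outcome."""

    times: np.ndarray
    fano: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    surviving_fraction: float = 1.0
    surviving_units: np.ndarray | None = None


def _window_centers(trial_span, window, step):
    t0, t1 = trial_span
    return np.arange(t0 + window / 2.0, t1 - window / 2.0 + 1e-12, step)


def _counts(spikes: pd.DataFrame, units, trials, centers, window) -> np.ndarray:
    """Spike counts: (n_units, n_trials, n_windows)."""
    half = window / 2.0
    u_ix = {u: i for i, u in enumerate(units)}
    t_ix = {t: i for i, t in enumerate(trials)}
    out = np.zeros((len(units), len(trials), len(centers)), dtype=float)
    times = spikes["time"].to_numpy()
    for k, c in enumerate(centers):
        m = (times >= c - half) & (times < c + half)
        if not m.any():
            continue
        sub = spikes[m]
        grouped = sub.groupby(["unit", "trial"]).size()
        for (u, t), cnt in grouped.items():
            out[u_ix[u], t_ix[t], k] = cnt
    return out


def psth(
    spikes: pd.DataFrame,
    trial_span: tuple[float, float],
    n_trials: int | None = None,
    window: float = 0.25,
    step: float = 0.05,
) -> pd.DataFrame:
    """Trial-averaged firing rate (Hz) per unit in a sliding window.

    Returns a tidy frame with columns ``unit``, ``time`` (window center) and
    ``rate``. ``n_trials`` may exceed the number of trials with spikes (silent
    trials count toward the average).
    """
    units = np.sort(spikes["unit"].unique()) if len(spikes) else np.array([], dtype=int)
    trials = np.sort(spikes["trial"].unique()) if len(spikes) else np.array([0])
    if n_trials is None:
        n_trials = max(len(trials), 1)
    centers = _window_centers(trial_span, window, step)
    rows = []
    times = spikes["time"].to_numpy() if len(spikes) else np.empty(0)
    for u in units:
        ut = times[spikes["unit"].to_numpy() == u]
        for c in centers:
            cnt = int(((ut >= c - window / 2.0) & (ut < c + window / 2.0)).sum())
            rows.append((u, c, cnt / (n_trials * window)))
    if not rows:
        rows = [(-1, c, 0.0) for c in centers]
    return pd.DataFrame(rows, columns=["unit", "time", "rate"])


def surrogate_trains(
    spikes: pd.DataFrame,
    trial_span: tuple[float, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Surrogate by permuting inter-event intervals per unit and trial.

    The interval from the trial start to the first spike joins the pool, so
    spike count and total span per (unit, trial) are conserved exactly.
    """
    t0 = trial_span[0]
    out = spikes.reset_index(drop=True).copy()
    new_times = out["time"].to_numpy().copy()
    key = out[["unit", "trial"]].to_numpy()
    for u, tr in np.unique(key, axis=0):
        pos = np.flatnonzero((key[:, 0] == u) & (key[:, 1] == tr))
        t = np.sort(new_times[pos])
        isi = np.diff(np.r_[t0, t])
        new_times[pos] = t0 + np.cumsum(isi[rng.permutation(len(isi))])
    out["time"] = new_times
    return out


def rate_significance(
    spikes: pd.DataFrame,
    trial_span: tuple[float, float],
    n_surrogates: int = 1000,
    window: float = 0.25,
    step: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Flag windows where a unit's rate is in the top/bottom 2.5% of surrogates.

    Units averaging fewer than 3 spikes per trial are skipped with a warning
    (their surrogate rate distribution is too coarse to define the tails).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    centers = _window_centers(trial_span, window, step)
    units = np.sort(spikes["unit"].unique())
    trials = np.sort(spikes["trial"].unique())
    n_trials = len(trials)
    frames = []
    for u in units:
        su = spikes[spikes["unit"] == u]
        if len(su) / max(n_trials, 1) < 3:
            warnings.warn(f"unit {u}: fewer than 3 spikes/trial on average; skipped")
            continue
        obs = psth(su, trial_span, n_trials, window, step)["rate"].to_numpy()
        null = np.empty((n_surrogates, len(centers)))
        for b in range(n_surrogates):
            surr = surrogate_trains(su, trial_span, rng)
            null[b] = psth(surr, trial_span, n_trials, window, step)["rate"].to_numpy()
        hi = obs > np.quantile(null, 0.975, axis=0)
        lo = obs < np.quantile(null, 0.025, axis=0)
        frames.append(
            pd.DataFrame(
                {"unit": u, "time": centers, "rate": obs, "high": hi, "low": lo}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["unit", "time", "rate", "high", "low"])
    return pd.concat(frames, ignore_index=True)


def _fano_slope(mean: np.ndarray, var: np.ndarray) -> tuple[float, float]:
    """OLS slope of var on mean (free intercept) and its standard error."""
    x = np.c_[np.ones_like(mean), mean]
    beta, res, rank, _ = np.linalg.lstsq(x, var, rcond=None)
    dof = len(mean) - 2
    if dof <= 0 or np.ptp(mean) == 0:
        return float(beta[1]) if rank == 2 else np.nan, np.nan
    resid = var - x @ beta
    s2 = float(resid @ resid) / dof
    sxx = float(((mean - mean.mean()) ** 2).sum())
    return float(beta[1]), np.sqrt(s2 / sxx) if sxx > 0 else np.nan


def _mean_match(
    counts: np.ndarray, period_a: np.ndarray, period_b: np.ndarray
) -> np.ndarray:
    """Greedy unit removal until mean rates in two periods stop differing.

    ``counts`` is (units, trials, windows); the periods are boolean window
    masks. Removes the unit with the largest absolute rate difference until a
    paired two-tailed t-test across the remaining units gives p > 0.05.
    Returns the indices of surviving units.
    """
    keep = list(range(counts.shape[0]))
    while len(keep) > 2:
        ra = counts[keep][:, :, period_a].mean(axis=(1, 2))
        rb = counts[keep][:, :, period_b].mean(axis=(1, 2))
        if np.allclose(ra, rb):
            break
        p = stats.ttest_rel(ra, rb).pvalue
        if np.isnan(p) or p > 0.05:
            break
        worst = int(np.argmax(np.abs(ra - rb)))
        keep.pop(worst)
    if len(keep) <= 2:
        raise RuntimeError("mean-matching removed almost all units")
    return np.asarray(keep)


def fano_factor(
    spikes: pd.DataFrame,
    trial_span: tuple[float, float],
    window: float = 0.1,
    step: float = 0.04,
    mean_match: bool = False,
    match_periods: tuple[tuple[float, float], tuple[float, float]] | None = None,
    zero_intercept: bool = False,
) -> FanoResult:
    """Per-window Fano factor as the variance-vs-mean regression slope.

    For each window, the across-trial spike-count mean and variance of every
    unit give one point; the OLS slope (free intercept by default) is the
    Fano factor and its 95% CI comes from the slope's standard error. With
    ``mean_match=True`` (requires ``match_periods``, two (start, end) windows
    in trial time) units are greedily removed until the periods' mean rates
    no longer differ, and the surviving fraction is reported.
    """
    units = np.sort(spikes["unit"].unique())
    trials = np.sort(spikes["trial"].unique())
    if len(units) < 5 or len(trials) < 10:
        warnings.warn("Fano estimate unstable below ~5 units / ~10 trials")
    centers = _window_centers(trial_span, window, step)
    counts = _counts(spikes, units, trials, centers, window)

    surviving = np.arange(len(units))
    if mean_match:
        if match_periods is None:
            raise ValueError("mean_match requires match_periods")
        (a0, a1), (b0, b1) = match_periods
        pa = (centers >= a0) & (centers < a1)
        pb = (centers >= b0) & (centers < b1)
        surviving = _mean_match(counts, pa, pb)
        counts = counts[surviving]

    mean = counts.mean(axis=1)  # (units, windows)
    var = counts.var(axis=1, ddof=1)
    fano = np.empty(len(centers))
    lo = np.empty(len(centers))
    hi = np.empty(len(centers))
    tcrit = stats.t.ppf(0.975, max(counts.shape[0] - 2, 1))
    for k in range(len(centers)):
        if zero_intercept:
            sxx = float((mean[:, k] ** 2).sum())
            slope = float((mean[:, k] @ var[:, k]) / sxx) if sxx > 0 else np.nan
            resid = var[:, k] - slope * mean[:, k]
            dof = max(counts.shape[0] - 1, 1)
            se = np.sqrt(float(resid @ resid) / dof / sxx) if sxx > 0 else np.nan
        else:
            slope, se = _fano_slope(mean[:, k], var[:, k])
        fano[k] = slope
        lo[k] = slope - tcrit * se
        hi[k] = slope + tcrit * se
    return FanoResult(
        times=centers,
        fano=fano,
        ci_low=lo,
        ci_high=hi,
        surviving_fraction=len(surviving) / len(units),
        surviving_units=units[surviving],
    )
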