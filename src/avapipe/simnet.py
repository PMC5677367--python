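"""Branching cellular-automaton network model of cortical avalanche dynamics.

A grid of sites (default 10x10, mimicking a multi-electrode array) evolves in
discrete time steps. Each site cycles through ``n_states`` states: 0 is
quiescent, 1 is active, 2..n_states-1 are refractory. A quiescent site becomes
active at the next step if any active pre-synaptic neighbour transmits, each of
the ``k`` outgoing connections independently with probability ``P``. Active and
refractory sites advance deterministically, ``x -> (x + 1) mod n_states``, so a
site that fires is silenced for ``n_states - 2`` further steps before it can
fire again. With ``P = 1/k`` the expected number of offspring per active site
is one: the cascade is a critical branching process and avalanche sizes follow
an approximate power law with exponent -3/2, cut off near the system size.

Baseline activity seeds one random site in a quiescent network, lets the
cascade run to extinction, then waits a random quiescent interval before the
next seed (separation of time scales). Trial-locked rate transients are
modelled by three distinct drives: Poisson inputs that trigger avalanches
(``input_driven``), a transient multiplicative boost of the transmission
probability (``supercritical``), and Poisson events that are logged but never
touch the network (``poisson_noise``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "NetworkState",
    "SimEventLog",
    "build_network",
    "step_automaton",
    "run_baseline",
    "run_avalanches",
    "run_driven_trials",
    "jitter_events",
]

DRIVE_MODES = ("none", "input_driven", "supercritical", "poisson_noise")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the branching-network simulation.

    ``P`` defaults to ``1/k`` (critical). ``drive_peak`` is a rate in events/s
    per site for ``input_driven`` and ``poisson_noise``, and a dimensionless
    multiplier (>= 1) of ``P`` for ``supercritical``. The drive amplitude
    ramps linearly from zero (or one) at the start of ``drive_window`` to its
    peak at the window midpoint and back down, matching a symmetric triangular
    profile. ``quiescent_model`` specifies the inter-avalanche-interval
    distribution: ``("lognormal", mu, sigma)`` with mu/sigma on the log scale
    in seconds, ``("constant", value)``, or ``("empirical", samples)`` with a
    sequence of intervals in seconds to resample from.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    k: int = 16
    P: float | None = None
    n_states: int = 11
    dt_model: float = 0.002
    drive_mode: str = "none"
    drive_peak: float = 0.0
    drive_window: tuple[float, float] = (-0.35, -0.05)
    trial_span: tuple[float, float] = (-0.8, 0.4)
    quiescent_model: tuple = ("lognormal", math.log(0.04), 1.0)
    rng_seed: int = 0

    @property
    def n_sites(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def p(self) -> float:
        return 1.0 / self.k if self.P is None else self.P

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.k >= self.n_sites:
            raise ValueError(
                f"out-degree k={self.k} must be smaller than the number of "
                f"sites ({self.n_sites})"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"transmission probability P={self.p} outside [0, 1]")
        if self.dt_model <= 0:
            raise ValueError("dt_model must be positive")
        if self.n_states < 2:
            raise ValueError("need at least the quiescent and active states")
        if self.drive_mode not in DRIVE_MODES:
            raise ValueError(f"drive_mode must be one of {DRIVE_MODES}")
        if self.drive_mode == "supercritical":
            if self.drive_peak < 1.0:
                raise ValueError("supercritical modifier peak must be >= 1")
            if self.drive_peak * self.p > 1.0:
                raise ValueError("modifier * P exceeds 1: not a probability")
        elif self.drive_peak < 0:
            raise ValueError("drive_peak must be non-negative")
        t0, t1 = self.trial_span
        w0, w1 = self.drive_window
        if not (t0 <= w0 < w1 <= t1):
            raise ValueError("drive_window must lie inside trial_span")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        qm = d["quiescent_model"]
        if len(qm) > 1 and isinstance(qm[1], (np.ndarray, list, tuple)):
            d["quiescent_model"] = (qm[0], [float(x) for x in np.asarray(qm[1]).ravel()])
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=list)


@dataclass
class NetworkState:
    """Instantaneous automaton state: per-site phase and the wiring."""

    site_states: np.ndarray  # (n_sites,) int, values in 0..n_states-1
    connectivity: np.ndarray  # (n_sites, k) int site indices
    t: int = 0
    n_states: int = 11

    def __post_init__(self) -> None:
        self.site_states = np.asarray(self.site_states, dtype=np.int64)
        if self.site_states.min(initial=0) < 0 or self.site_states.max(initial=0) >= self.n_states:
            raise ValueError("site states outside the automaton state range")


@dataclass
class SimEventLog:
    """Event log of a simulation run.

    ``events`` has columns ``site``, ``trial``, ``time`` (seconds) and
    ``label`` — the ground-truth avalanche id by causal ancestry of the seed
    (-1 for pure noise events that never entered the network). Labels are an
    artifact of the simulator used for oracle tests; cascades merged by drive
    inputs share a label.
    """

    events: pd.DataFrame
    config: SimConfig

    def __post_init__(self) -> None:
        expected = {"site", "trial", "time", "label"}
        if not expected.issubset(self.events.columns):
            raise ValueError(f"event log needs columns {sorted(expected)}")

    @property
    def sizes(self) -> np.ndarray:
        """Ground-truth avalanche sizes (noise events excluded)."""
        ev = self.events[self.events["label"] >= 0]
        return ev.groupby("label").size().to_numpy()

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False, float_format="%.6f")


def build_network(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the random directed graph: k distinct targets per site, no self-loops.

    Returns an ``(n_sites, k)`` integer array of post-synaptic targets,
    reproducible from ``config.rng_seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    n, k = config.n_sites, config.k
    conn = np.empty((n, k), dtype=np.int64)
    others = np.arange(n - 1)
    for i in range(n):
        pick = rng.choice(n - 1, size=k, replace=False)
        targets = others[pick]
        targets[targets >= i] += 1  # skip self
        conn[i] = targets
    return conn


def step_automaton(
    state: NetworkState,
    P_t: float,
    rng: np.random.Generator,
    external_activations: Sequence[int] | np.ndarray = (),
) -> NetworkState:
    """Advance the automaton one time step.

    Transmission from each site active at ``t`` to each of its quiescent
    targets is an independent Bernoulli(``P_t``); non-quiescent sites advance
    deterministically through the state cycle; ``external_activations`` force
    listed sites to fire if (and only if) they are quiescent.
    """
    if not 0.0 <= P_t <= 1.0:
        raise ValueError("P_t must be a probability")
    states = state.site_states
    newly = _next_active(states, state.connectivity, P_t, rng, external_activations)
    nxt = states.copy()
    nonq = nxt > 0
    nxt[nonq] = (nxt[nonq] + 1) % state.n_states
    nxt[newly] = 1
    return NetworkState(nxt, state.connectivity, state.t + 1, state.n_states)


def _next_active(
    states: np.ndarray,
    conn: np.ndarray,
    P_t: float,
    rng: np.random.Generator,
    external: Sequence[int] | np.ndarray = (),
) -> np.ndarray:
    """Sites that fire at t+1 (transmission targets plus external triggers)."""
    active = np.flatnonzero(states == 1)
    hit: np.ndarray
    if active.size and P_t > 0:
        targets = conn[active]  # (n_active, k)
        if P_t >= 1.0:
            hit = targets.ravel()
        else:
            mask = rng.random(targets.shape) < P_t
            hit = targets[mask]
        hit = np.unique(hit)
        hit = hit[states[hit] == 0]
    else:
        hit = np.empty(0, dtype=np.int64)
    if len(external):
        ext = np.asarray(external, dtype=np.int64)
        ext = ext[states[ext] == 0]
        hit = np.union1d(hit, ext)
    return hit


def _sample_intervals(model: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = model[0]
    if kind == "lognormal":
        _, mu, sigma = model
        out = rng.lognormal(mean=mu, sigma=sigma, size=n)
    elif kind == "constant":
        out = np.full(n, float(model[1]))
    elif kind == "empirical":
        samples = np.asarray(model[1], dtype=float)
        if samples.size == 0:
            raise ValueError("empirical quiescent model needs at least one interval")
        out = rng.choice(samples, size=n, replace=True)
    else:
        raise ValueError(f"unknown quiescent model kind {kind!r}")
    if np.any(out < 0):
        raise ValueError("quiescent model produced negative intervals")
    return out


def run_avalanches(
    config: SimConfig,
    n_avalanches: int,
    rng: np.random.Generator | None = None,
    collect_events: bool = False,
) -> tuple[np.ndarray, list | None]:
    """Generate ``n_avalanches`` independent seeded cascades and their sizes.

    Each cascade starts from one random site in a fully quiescent network and
    runs to extinction (including decay of all refractory tails), exactly the
    protocol used to characterise the model's critical statistics. Returns the
    integer size array and, if requested, a list of per-avalanche
    ``(site, step)`` activation records.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    conn = build_network(config, rng)
    n_states = config.n_states
    p = config.p
    n = config.n_sites
    sizes = np.empty(n_avalanches, dtype=np.int64)
    all_records: list | None = [] if collect_events else None
    states = np.zeros(n, dtype=np.int64)
    for i in range(n_avalanches):
        seed_site = int(rng.integers(n))
        rec: list | None = [] if collect_events else None
        size = _run_to_extinction(states, conn, p, n_states, seed_site, rng, rec)
        sizes[i] = size
        if collect_events:
            all_records.append(rec)
    return sizes, all_records


def _run_to_extinction(
    states: np.ndarray,
    conn: np.ndarray,
    p: float,
    n_states: int,
    seed_site: int,
    rng: np.random.Generator,
    record: list | None = None,
) -> int:
    """Propagate a single cascade until the network is quiescent again."""
    states[seed_site] = 1
    size = 1
    step = 0
    if record is not None:
        record.append((seed_site, step))
    while True:
        newly = _next_active(states, conn, p, rng)
        nonq = states > 0
        if not nonq.any() and newly.size == 0:
            break
        states[nonq] = (states[nonq] + 1) % n_states
        step += 1
        if newly.size:
            states[newly] = 1
            size += newly.size
            if record is not None:
                record.extend((int(s), step) for s in newly)
        elif not (states == 1).any():
            # no active sites left: let refractory tails decay deterministically
            while (states > 0).any():
                nonq = states > 0
                states[nonq] = (states[nonq] + 1) % n_states
            break
    return size


def run_baseline(
    config: SimConfig,
    n_avalanches: int = 1000,
    rng: np.random.Generator | None = None,
) -> SimEventLog:
    """Baseline regime: seeded cascades separated by random quiescent intervals.

    Event times are continuous (seconds, trial id 0, starting at 0). If a
    cascade is still decaying when the next scheduled initiation arrives, the
    initiation is deferred until the network is quiescent, preserving the
    separation of time scales.
    """
    if config.drive_mode != "none":
        raise ValueError("run_baseline requires drive_mode='none'")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    sizes, records = run_avalanches(config, n_avalanches, rng, collect_events=True)
    intervals = _sample_intervals(config.quiescent_model, n_avalanches, rng)
    dt = config.dt_model
    rows_site = []
    rows_time = []
    rows_label = []
    t_cursor = 0.0
    for label, rec in enumerate(records):
        last_step = rec[-1][1]
        for site, step in rec:
            rows_site.append(site)
            rows_time.append(t_cursor + step * dt)
            rows_label.append(label)
        # extinction (incl. refractory decay) takes n_states-1 steps after the
        # last activation; the next seed waits at least the quiescent interval
        t_cursor += (last_step + config.n_states - 1) * dt + intervals[label]
    events = pd.DataFrame(
        {
            "site": np.asarray(rows_site, dtype=np.int64),
            "trial": np.zeros(len(rows_site), dtype=np.int64),
            "time": np.asarray(rows_time, dtype=float),
            "label": np.asarray(rows_label, dtype=np.int64),
        }
    )
    return SimEventLog(events, config)


class _Labels:
    """Union-find over avalanche labels (cascades merged by drive inputs)."""

    def __init__(self) -> None:
        self.parent: list[int] = []

    def new(self) -> int:
        self.parent.append(len(self.parent))
        return len(self.parent) - 1

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)
        return min(ra, rb)


def _drive_profile(t: float, config: SimConfig) -> float:
    """Triangular drive amplitude at trial time t: 0 -> peak -> 0 (or 1 -> peak -> 1)."""
    w0, w1 = config.drive_window
    lo = 1.0 if config.drive_mode == "supercritical" else 0.0
    if t <= w0 or t >= w1:
        return lo
    mid = 0.5 * (w0 + w1)
    frac = (t - w0) / (mid - w0) if t <= mid else (w1 - t) / (w1 - mid)
    return lo + frac * (config.drive_peak - lo)


def run_driven_trials(
    config: SimConfig,
    n_trials: int,
    rng: np.random.Generator | None = None,
) -> SimEventLog:
    """Simulate trials with baseline cascades plus the configured transient drive.

    Each trial spans ``config.trial_span`` in steps of ``dt_model``. The
    baseline process seeds avalanches separated by quiescent-model intervals;
    the drive adds, depending on ``drive_mode``, per-site Poisson triggers
    (``input_driven``), a multiplicative transient in the transmission
    probability (``supercritical``), or logged-only Poisson events
    (``poisson_noise``, label -1). A ``drive_peak`` of zero (or one for
    supercritical) reduces to the baseline process.
    """
    if config.drive_mode == "none":
        raise ValueError("run_driven_trials requires a drive_mode other than 'none'")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    # independent stream for drive inputs: switching a non-interacting drive
    # on or off must not perturb the network's own random trajectory
    rng, drive_rng = rng.spawn(2)
    conn = build_network(config, rng)
    n = config.n_sites
    n_states = config.n_states
    p = config.p
    dt = config.dt_model
    t0, t1 = config.trial_span
    n_steps = int(round((t1 - t0) / dt))
    mode = config.drive_mode

    rows_site: list[int] = []
    rows_trial: list[int] = []
    rows_time: list[float] = []
    rows_label: list[int] = []

    for trial in range(n_trials):
        trial_row_start = len(rows_trial)
        states = np.zeros(n, dtype=np.int64)
        site_label = np.full(n, -1, dtype=np.int64)  # label of currently propagating site
        labels = _Labels()
        next_seed = t0 + float(_sample_intervals(config.quiescent_model, 1, rng)[0])
        was_active = False
        for step in range(n_steps):
            t = t0 + step * dt
            amp = _drive_profile(t, config)
            P_t = min(p * amp, 1.0) if mode == "supercritical" else p

            active = np.flatnonzero(states == 1)
            # transmissions from currently active sites
            if active.size and P_t > 0:
                targets = conn[active]
                mask = rng.random(targets.shape) < P_t if P_t < 1.0 else np.ones(targets.shape, bool)
                src = np.repeat(active, mask.sum(axis=1))
                tgt = targets[mask]
                ok = states[tgt] == 0
                src, tgt = src[ok], tgt[ok]
            else:
                src = tgt = np.empty(0, dtype=np.int64)

            newly: dict[int, int] = {}
            for s_i, t_i in zip(src, tgt):
                lab = labels.find(int(site_label[s_i]))
                prev = newly.get(int(t_i))
                newly[int(t_i)] = lab if prev is None else labels.union(prev, lab)

            # baseline seeding: only when the network is fully quiescent
            network_quiescent = not (states > 0).any()
            if network_quiescent and not newly and t >= next_seed:
                seed_site = int(rng.integers(n))
                newly[seed_site] = labels.new()

            # drive inputs
            if mode == "input_driven" and amp > 0:
                n_inputs = drive_rng.poisson(amp * dt, size=n)
                for site in np.flatnonzero(n_inputs):
                    if states[site] == 0:
                        site = int(site)
                        if site in newly:
                            continue  # already being activated this step
                        newly[site] = labels.new()
            elif mode == "poisson_noise" and amp > 0:
                n_noise = drive_rng.poisson(amp * dt, size=n)
                for site in np.flatnonzero(n_noise):
                    for _ in range(int(n_noise[site])):
                        rows_site.append(int(site))
                        rows_trial.append(trial)
                        rows_time.append(t)
                        rows_label.append(-1)

            # advance refractory/active states, then apply new activations
            nonq = states > 0
            if nonq.any():
                states[nonq] = (states[nonq] + 1) % n_states
            if newly:
                for site, lab in newly.items():
                    states[site] = 1
                    site_label[site] = lab
                    rows_site.append(site)
                    rows_trial.append(trial)
                    rows_time.append(t + dt)  # activation takes effect at t+1
                    rows_label.append(lab)
                was_active = True
            elif was_active and not (states == 1).any():
                # cascade over (refractory tails may persist); schedule next seed
                next_seed = t + dt + float(_sample_intervals(config.quiescent_model, 1, rng)[0])
                was_active = False

        # resolve merged labels to their union-find roots
        for i in range(trial_row_start, len(rows_trial)):
            if rows_label[i] >= 0:
                rows_label[i] = labels.find(rows_label[i])

    # globally unique labels: (trial, local label) -> dense id
    lab_arr = np.asarray(rows_label, dtype=np.int64)
    tri_arr = np.asarray(rows_trial, dtype=np.int64)
    key = np.where(lab_arr >= 0, tri_arr * (lab_arr.max(initial=0) + 1) + lab_arr, -1)
    uniq, inv = np.unique(key, return_inverse=True)
    dense = inv - (1 if (uniq.size and uniq[0] == -1) else 0)
    dense = np.where(key < 0, -1, dense)

    events = pd.DataFrame(
        {
            "site": np.asarray(rows_site, dtype=np.int64),
            "trial": tri_arr,
            "time": np.asarray(rows_time, dtype=float),
            "label": dense.astype(np.int64),
        }
    ).sort_values(["trial", "time", "site"], kind="stable", ignore_index=True)
    return SimEventLog(events, config)


def jitter_events(
    log: SimEventLog,
    max_jitter: float,
    rng: np.random.Generator | None = None,
) -> SimEventLog:
    """Add independent uniform jitter in [-max_jitter, +max_jitter] to event times.

    De-discretises the model's event times so adaptive binning with dt below
    the model step does not artificially split cascades; the event count and
    all ids are untouched.
    """
    if max_jitter < 0:
        raise ValueError("max_jitter must be non-negative")
    if max_jitter == 0:
        return SimEventLog(log.events.copy(), log.config)
    if rng is None:
        rng = np.random.default_rng(log.config.rng_seed + 1)
    ev = log.events.copy()
    ev["time"] = ev["time"] + rng.uniform(-max_jitter, max_jitter, size=len(ev))
    ev = ev.sort_values(["trial", "time", "site"], kind="stable", ignore_index=True)
    return SimEventLog(ev, log.config)
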