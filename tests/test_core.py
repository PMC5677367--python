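"""Avalanche clustering, binning plans, shuffle controls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avapipe import core
from avapipe.raster import EpochSpec
from conftest import make_raster

EPOCHS = EpochSpec({"BASE": (-0.4, 0.0), "PRE": (0.0, 0.4)})


def brute_force_cluster(times, dt, origin):
    """Independent oracle: scan bins one by one and accumulate runs."""
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        return []
    bins = np.floor((times - origin) / dt).astype(int)
    clusters, current = [], []
    for b in range(bins.min(), bins.max() + 1):
        members = np.flatnonzero(bins == b)
        if members.size:
            current.extend(members.tolist())
        else:
            if current:
                clusters.append(current)
            current = []
    if current:
        clusters.append(current)
    return clusters


class TestFixedDt:
    def test_inverse_rate_definition(self):
        r = make_raster([(0, 0, t) for t in np.linspace(0, 0.99, 100)], trial_span=(0, 1))
        assert core.compute_fixed_dt(r) == pytest.approx(0.01)

    def test_halves_when_count_doubles(self):
        ev1 = [(0, 0, t) for t in np.linspace(0, 0.9, 50)]
        ev2 = ev1 + [(1, 0, t + 1e-4) for _, _, t in ev1]
        r1 = make_raster(ev1, trial_span=(0, 1))
        r2 = make_raster(ev2, trial_span=(0, 1))
        assert core.compute_fixed_dt(r2) == pytest.approx(core.compute_fixed_dt(r1) / 2)

    def test_zero_events_undefined(self):
        r = make_raster([], trial_span=(0, 1))
        with pytest.raises(ValueError):
            core.compute_fixed_dt(r)


class TestAdaptiveDt:
    def test_inverse_proportional_to_epoch_rate(self):
        ev = [(0, 0, -0.4 + i * 0.04) for i in range(10)]  # 10 events in BASE
        ev += [(0, 0, 0.0 + i * 0.013) for i in range(30)]  # 30 events in PRE
        plan = core.compute_adaptive_dt(make_raster(ev, (-0.4, 0.4)), EPOCHS)
        assert plan.dt_table[(0, "BASE")] == pytest.approx(0.4 / 10)
        assert plan.dt_table[(0, "PRE")] == pytest.approx(0.4 / 30)
        assert plan.dt_table[(0, "PRE")] / plan.dt_table[(0, "BASE")] == pytest.approx(1 / 3)

    def test_empty_cell_flagged(self):
        ev = [(0, 0, -0.2)]
        with pytest.warns(UserWarning):
            plan = core.compute_adaptive_dt(make_raster(ev, (-0.4, 0.4)), EPOCHS)
        assert (0, "PRE") in plan.empty_cells
        assert (0, "PRE") not in plan.dt_table


class TestCluster:
    def test_contiguous_bins_merge(self):
        [c] = core.cluster(np.array([0.001, 0.002, 0.003]), dt=0.001, origin=0.0)
        assert len(c) == 3

    def test_empty_bin_separates(self):
        parts = core.cluster(np.array([0.001, 0.010]), dt=0.001, origin=0.0)
        assert [len(p) for p in parts] == [1, 1]

    def test_every_event_in_exactly_one_cluster(self, rng):
        t = rng.uniform(0, 1, 200)
        parts = core.cluster(t, dt=0.01, origin=0.0)
        all_idx = np.sort(np.concatenate(parts))
        assert np.array_equal(all_idx, np.arange(200))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        t = rng.uniform(0, 0.5, n)
        dt = float(rng.uniform(0.001, 0.05))
        ours = core.cluster(t, dt, origin=0.0)
        ref = brute_force_cluster(t, dt, origin=0.0)
        order = np.argsort(t, kind="stable")
        ours_sets = [sorted(np.asarray(m).tolist()) for m in ours]
        ref_sets = [sorted(order[m].tolist()) for m in ref]
        assert ours_sets == ref_sets

    def test_dt_limits(self, rng):
        t = np.sort(rng.uniform(0, 1, 50))
        assert len(core.cluster(t, dt=100.0, origin=0.0)) == 1
        tiny = np.diff(t).min() / 2
        assert all(len(c) == 1 for c in core.cluster(t, dt=tiny, origin=0.0))

    def test_cluster_count_non_increasing_in_dt(self, rng):
        t = rng.uniform(0, 1, 300)
        counts = [len(core.cluster(t, dt, 0.0)) for dt in (0.001, 0.003, 0.01, 0.03, 0.1)]
        assert counts == sorted(counts, reverse=True)


class TestClusterRaster:
    def test_event_conservation_all_dt(self, rng):
        ev = [(int(e), int(tr), float(t)) for e, tr, t in
              zip(rng.integers(0, 96, 400), rng.integers(0, 5, 400), rng.uniform(-0.4, 0.4, 400))]
        r = make_raster(ev, (-0.4, 0.4))
        for dt in (0.001, 0.005, 0.02, 0.1):
            av = core.cluster_raster_fixed(r, dt)
            assert av["size"].sum() == 400

    def test_adaptive_conservation_and_epoch_confinement(self, rng):
        ev = [(int(e), int(tr), float(t)) for e, tr, t in
              zip(rng.integers(0, 96, 600), rng.integers(0, 4, 600), rng.uniform(-0.4, 0.4, 600))]
        r = make_raster(ev, (-0.4, 0.4))
        plan = core.compute_adaptive_dt(r, EPOCHS)
        av = core.cluster_raster_adaptive(r, plan, EPOCHS)
        assert av["size"].sum() == 600
        for _, row in av.iterrows():
            a, b = EPOCHS[row["epoch"]]
            assert a <= row["start"] < b
            assert row["start"] + row["duration"] <= b + row["dt"]


class TestShiftPredictor:
    def _raster(self, rng):
        ev = [(int(e), int(tr), float(t)) for e, tr, t in
              zip(rng.integers(0, 10, 500), rng.integers(0, 8, 500), rng.uniform(0, 1, 500))]
        return make_raster(ev, (0, 1), n_electrodes=10)

    def test_per_electrode_counts_conserved(self, rng):
        r = self._raster(rng)
        sp = core.shift_predictor(r, rng)
        assert (
            r.events["electrode"].value_counts().sort_index()
            .equals(sp.events["electrode"].value_counts().sort_index())
        )

    def test_rate_profile_preserved_exactly(self, rng):
        """Per-electrode trial-averaged rate course is invariant: times move trials, not times."""
        r = self._raster(rng)
        sp = core.shift_predictor(r, rng)
        for e in range(10):
            a = np.sort(r.events.loc[r.events["electrode"] == e, "time"].to_numpy())
            b = np.sort(sp.events.loc[sp.events["electrode"] == e, "time"].to_numpy())
            assert np.array_equal(a, b)

    def test_single_trial_noop_with_warning(self, rng):
        r = make_raster([(0, 0, 0.5), (1, 0, 0.6)], (0, 1))
        with pytest.warns(UserWarning):
            sp = core.shift_predictor(r, rng)
        assert sp.events.equals(r.events)


class TestTimecourse:
    def test_null_calibration_flags_about_five_percent(self, rng):
        """Stationary avalanche stream: ~5% of time points flagged (nominal rate)."""
        n = 4000
        av = pd.DataFrame(
            {
                "trial": rng.integers(0, 40, n),
                "epoch": "",
                "start": rng.uniform(-0.8, 0.4, n),
                "duration": 0.01,
                "size": rng.geometric(0.3, n),
                "dt": 0.01,
            }
        )
        tc = core.rate_size_timecourse(av, (-0.8, 0.4), n_shuffles=100, rng=rng)
        frac = np.mean(
            tc[["rate_high", "rate_low", "size_high", "size_low"]].to_numpy().mean(axis=0)
        )
        assert frac < 0.20  # nominal ~5% two-sided per trace; allow sampling slack

    def test_planted_rate_transient_flagged(self, rng):
        base = rng.uniform(-0.8, 0.4, 2000)
        burst = rng.uniform(-0.35, -0.05, 1500)
        start = np.concatenate([base, burst])
        av = pd.DataFrame(
            {
                "trial": rng.integers(0, 40, len(start)),
                "epoch": "",
                "start": start,
                "duration": 0.01,
                "size": rng.geometric(0.3, len(start)),
                "dt": 0.01,
            }
        )
        tc = core.rate_size_timecourse(av, (-0.8, 0.4), n_shuffles=100, rng=rng)
        inside = tc[(tc["time"] > -0.3) & (tc["time"] < -0.1)]
        assert inside["rate_high"].all()

    def test_constant_sizes_never_flag_size_course(self, rng):
        av = pd.DataFrame(
            {
                "trial": rng.integers(0, 20, 1000),
                "epoch": "",
                "start": rng.uniform(0, 1, 1000),
                "duration": 0.01,
                "size": 3,
                "dt": 0.01,
            }
        )
        tc = core.rate_size_timecourse(av, (0, 1), n_shuffles=100, rng=rng)
        assert not tc["size_high"].any() and not tc["size_low"].any()


class TestRateSplit:
    def test_bimodal_rates_split_perfectly(self, rng):
        ev = []
        for tr in range(20):
            n = 40 if tr % 2 else 10
            for t in rng.uniform(0.0, 0.4, n):
                ev.append((0, tr, float(t)))
        r = make_raster(ev, (-0.4, 0.4))
        low, high = core.split_trials_by_rate(r, EPOCHS, "PRE")
        assert set(low) == set(range(0, 20, 2))
        assert set(high) == set(range(1, 20, 2))

    def test_median_split_balanced(self, rng):
        ev = [(0, tr, float(t)) for tr in range(11) for t in rng.uniform(0, 0.4, tr + 1)]
        r = make_raster(ev, (-0.4, 0.4))
        low, high = core.split_trials_by_rate(r, EPOCHS, "PRE")
        assert abs(len(low) - len(high)) <= 1

    def test_degenerate_equal_rates_warn(self, rng):
        ev = [(0, tr, 0.2) for tr in range(6)]
        r = make_raster(ev, (-0.4, 0.4))
        with pytest.warns(UserWarning):
            core.split_trials_by_rate(r, EPOCHS, "PRE")


class TestSizeDifference:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=core.AVALANCHE_COLUMNS)

    def test_identical_epochs_give_zero_differences(self):
        rows = []
        for tr in range(10):
            rows.append((tr, "BASE", -0.2, 0.01, 5, 0.01))
            rows.append((tr, "PRE", 0.2, 0.01, 5, 0.01))
        res = core.per_trial_size_difference(self._table(rows), self._table(rows), "PRE", "BASE")
        assert np.allclose(res["diff_fixed"], 0)
        assert res["ks_p"] == pytest.approx(1.0)

    def test_planted_shift_detected(self, rng):
        rows_f, rows_a = [], []
        for tr in range(60):
            b = float(rng.poisson(5) + 1)
            rows_f.append((tr, "BASE", -0.2, 0.01, b, 0.01))
            rows_f.append((tr, "PRE", 0.2, 0.01, b + 10, 0.01))  # fixed: large bias
            rows_a.append((tr, "BASE", -0.2, 0.01, b, 0.01))
            rows_a.append((tr, "PRE", 0.2, 0.01, b + rng.normal(0, 0.5), 0.01))
        res = core.per_trial_size_difference(self._table(rows_f), self._table(rows_a), "PRE", "BASE")
        assert res["diff_fixed"].mean() > res["diff_adaptive"].mean()
        assert res["significant"]

    def test_trials_missing_an_epoch_excluded(self):
        rows = [(0, "BASE", -0.2, 0.01, 4, 0.01), (1, "BASE", -0.2, 0.01, 4, 0.01),
                (1, "PRE", 0.2, 0.01, 6, 0.01)]
        res = core.per_trial_size_difference(self._table(rows), self._table(rows), "PRE", "BASE")
        assert res["excluded_trials_fixed"] == 1
        assert len(res["diff_fixed"]) == 1
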