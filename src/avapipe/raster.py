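"""Event rasters and trial-epoch bookkeeping.

The :class:`EventRaster` is the common currency of the pipeline: a table of
(electrode, trial, time, amplitude) events — nLFP peak times from detection,
or simulated site activations — together with the array geometry and the
per-trial recording span. Epochs are named 400 ms trial segments such as
BASE/EARLY/LATE (cue-aligned) or BASE/PRE/POST (touch-aligned).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayGeometry",
    "EpochSpec",
    "EventRaster",
    "CUE_EPOCHS",
    "TOUCH_EPOCHS",
    "read_raster_csv",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Electrode-array layout: 10x10 grid, corners missing, 400 um pitch."""

    n_electrodes: int = 96
    grid_rows: int = 10
    grid_cols: int = 10
    pitch_um: float = 400.0


class EpochSpec(dict):
    """Named, non-overlapping (start, end) windows in trial time (seconds)."""

    def __init__(self, epochs: dict[str, tuple[float, float]]):
        super().__init__(epochs)
        items = sorted(self.items(), key=lambda kv: kv[1][0])
        for name, (a, b) in items:
            if not (np.isfinite(a) and np.isfinite(b) and a < b):
                raise ValueError(f"epoch {name!r} has invalid bounds ({a}, {b})")
        for (n1, (a1, b1)), (n2, (a2, b2)) in zip(items, items[1:]):
            if b1 > a2 + 1e-12:
                raise ValueError(f"epochs {n1!r} and {n2!r} overlap")

    def duration(self, name: str) -> float:
        a, b = self[name]
        return b - a

    def label_times(self, times: np.ndarray) -> np.ndarray:
        """Epoch name per time (object array, '' where no epoch covers t)."""
        out = np.full(len(times), "", dtype=object)
        for name, (a, b) in self.items():
            out[(times >= a) & (times < b)] = name
        return out


CUE_EPOCHS = EpochSpec({"BASE": (-0.4, 0.0), "EARLY": (0.0, 0.4), "LATE": (0.4, 0.8)})
TOUCH_EPOCHS = EpochSpec({"BASE": (-0.8, -0.4), "PRE": (-0.4, 0.0), "POST": (0.0, 0.4)})


@dataclass
class EventRaster:
    """Per-electrode, per-trial event timestamps.

    ``events`` columns: ``electrode`` (int), ``trial`` (int), ``time``
    (seconds, trial-relative when ``trial_span`` is set) and ``amplitude``
    (<= 0 for nLFPs; 0 when undefined, e.g. simulated events).
    """

    events: pd.DataFrame
    geometry: ArrayGeometry = field(default_factory=ArrayGeometry)
    trial_span: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        need = {"electrode", "trial", "time"}
        if not need.issubset(self.events.columns):
            raise ValueError(f"raster needs columns {sorted(need)}")
        if "amplitude" not in self.events.columns:
            self.events = self.events.assign(amplitude=0.0)
        self.events = self.events.sort_values(
            ["trial", "time", "electrode"], kind="stable", ignore_index=True
        )

    @property
    def n_trials(self) -> int:
        return int(self.events["trial"].nunique())

    @property
    def trials(self) -> np.ndarray:
        return np.sort(self.events["trial"].unique())

    def span_duration(self) -> float:
        if self.trial_span is None:
            t = self.events["time"]
            return float(t.max() - t.min())
        return self.trial_span[1] - self.trial_span[0]

    def select_epoch(self, epochs: EpochSpec, name: str) -> "EventRaster":
        a, b = epochs[name]
        ev = self.events[(self.events["time"] >= a) & (self.events["time"] < b)]
        return EventRaster(ev.reset_index(drop=True), self.geometry, (a, b))

    def to_csv(self, path) -> None:
        out = self.events.rename(columns={"time": "time_s"})
        out.to_csv(path, index=False, float_format="%.6f")

    @staticmethod
    def from_sim_log(log, trial_span=None) -> "EventRaster":
        """Adopt a simulator event log (sites become electrodes; noise kept)."""
        ev = log.events.rename(columns={"site": "electrode"})[["electrode", "trial", "time"]]
        span = trial_span if trial_span is not None else (
            log.config.trial_span if log.config.drive_mode != "none" else None
        )
        geom = ArrayGeometry(
            n_electrodes=log.config.n_sites,
            grid_rows=log.config.grid_rows,
            grid_cols=log.config.grid_cols,
        )
        return EventRaster(ev.assign(amplitude=0.0), geom, span)


def read_raster_csv(path, geometry: ArrayGeometry | None = None, trial_span=None) -> EventRaster:
    df = pd.read_csv(path).rename(columns={"time_s": "time"})
    return EventRaster(df, geometry or ArrayGeometry(), trial_span)
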