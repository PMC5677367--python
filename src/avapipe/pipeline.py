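"""Config-driven end-to-end runs: simulate -> cluster -> fit -> report.

The orchestrator composes the module operations without computing anything
itself: every number in a summary is traceable to one library call. A single
global seed is expanded deterministically into independent per-stage child
seeds through ``numpy.random.SeedSequence.spawn``, so a run is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import core, distfit, simnet
from .raster import EpochSpec, EventRaster

__all__ = ["PipelineConfig", "run_pipeline", "run_three_regimes", "stage_rngs"]

#: drive settings of the three rate-transient regimes at their strong level
REGIMES = {
    "input_driven": {"drive_mode": "input_driven", "drive_peak": 6.5},
    "supercritical": {"drive_mode": "supercritical", "drive_peak": 2.5},
    "poisson_noise": {"drive_mode": "poisson_noise", "drive_peak": 35.0},
}

#: epochs of a simulated trial: baseline before the drive window, the drive
#: epoch itself, and the release period after it
SIM_EPOCHS = EpochSpec({"BASE": (-0.75, -0.35), "DRIVE": (-0.35, 0.05), "POST": (0.05, 0.4)})


@dataclass
class PipelineConfig:
    """End-to-end run description (simulation source only needs these knobs)."""

    drive_mode: str = "none"
    drive_peak: float = 0.0
    n_trials: int = 200
    n_avalanches: int = 20000  # baseline mode only
    jitter: float = 0.001  # half the 2 ms model step
    epochs: EpochSpec = field(default_factory=lambda: SIM_EPOCHS)
    seed: int = 0
    out_dir: str | None = None

    def sim_config(self, seed: int) -> simnet.SimConfig:
        return simnet.SimConfig(
            drive_mode=self.drive_mode, drive_peak=self.drive_peak, rng_seed=seed
        )


def stage_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """One independent generator per named stage from a single global seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _fit_block(sizes: np.ndarray) -> dict:
    fit = distfit.fit_truncated_powerlaw(sizes)
    exp = distfit.fit_exponential(sizes, s_max=fit.s_max)
    lt = distfit.likelihood_test(fit.logL, exp.logL, df=2)
    return {
        "n": int(len(sizes)),
        "alpha": fit.alpha,
        "s0": fit.s0,
        "gamma": fit.gamma,
        "logL_pl": fit.logL,
        "logL_exp": exp.logL,
        "D": lt.D,
        "p": lt.p,
        "favored": lt.favored,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, jitter, bin (fixed and adaptive), cluster, fit, and report.

    Returns a summary dict; if ``config.out_dir`` is set, writes the event
    log, avalanche tables and the JSON summary there alongside a manifest.
    """
    rngs = stage_rngs(config.seed, ["simulate", "jitter", "shuffle"])
    if config.drive_mode == "none":
        log = simnet.run_baseline(
            config.sim_config(config.seed), config.n_avalanches, rngs["simulate"]
        )
    else:
        log = simnet.run_driven_trials(
            config.sim_config(config.seed), config.n_trials, rngs["simulate"]
        )
    log = simnet.jitter_events(log, config.jitter, rngs["jitter"])
    raster = EventRaster.from_sim_log(log)

    summary: dict = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "epochs"
        },
        "n_events": int(len(raster.events)),
    }
    av_tables = {}
    if config.drive_mode == "none":
        dt = core.compute_fixed_dt(raster)
        av = core.cluster_raster_fixed(raster, dt)
        summary["dt_fixed"] = dt
        summary["fixed"] = _fit_block(av["size"].to_numpy())
        av_tables["fixed"] = av
    else:
        network = raster.events  # includes noise events for poisson_noise runs
        dt = core.compute_fixed_dt(raster)
        av_fixed = core.cluster_raster_fixed(raster, dt, config.epochs, anchor="trial")
        plan = core.compute_adaptive_dt(raster, config.epochs)
        av_adaptive = core.cluster_raster_adaptive(raster, plan, config.epochs)
        summary["dt_fixed"] = dt
        summary["fixed"] = _fit_block(av_fixed["size"].to_numpy())
        summary["adaptive"] = _fit_block(av_adaptive["size"].to_numpy())
        summary["empty_cells"] = len(plan.empty_cells)
        av_tables = {"fixed": av_fixed, "adaptive": av_adaptive}

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        log.to_csv(out / "events.csv")
        log.config.to_json(out / "sim_config.json")
        for name, tab in av_tables.items():
            tab.to_csv(out / f"avalanches_{name}.csv", index=False, float_format="%.6f")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary


def run_three_regimes(
    seed: int = 0,
    n_trials: int = 200,
    out_dir: str | None = None,
) -> dict:
    """The three-regime comparison: one driven run per regime, both binnings.

    Reports, per regime, the sharp-cutoff power-law and exponential fits and
    their likelihood test for fixed and adaptive binning — the contrast in
    which adaptive binning rescues the input-driven power law, fails to
    remove the supercritical cutoff excess, and cannot restore a cutoff for
    Poisson noise.
    """
    report: dict = {}
    for i, (name, drive) in enumerate(REGIMES.items()):
        cfg = PipelineConfig(
            drive_mode=drive["drive_mode"],
            drive_peak=drive["drive_peak"],
            n_trials=n_trials,
            seed=seed * 1000 + i,
            out_dir=None if out_dir is None else f"{out_dir}/{name}",
        )
        report[name] = run_pipeline(cfg)
    return report
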