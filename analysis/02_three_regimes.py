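#!/usr/bin/env python
"""Three rate-transient regimes under fixed vs adaptive binning.

Input-driven Poisson triggers (h_max = 6.5 /s), a supercritical transmission
transient (modifier 2.5), and state-blind Poisson noise (35 /s) all raise the
event rate; only for the input-driven regime does adaptive binning restore
the baseline-like sharp-cutoff power law. Writes results/02_three_regimes.csv.
"""

import pandas as pd

from avapipe import pipeline

OUT = "results/02_three_regimes.csv"
SEED = 2
N_TRIALS = {"input_driven": 250, "supercritical": 500, "poisson_noise": 150}


def main() -> None:
    rows = []
    base = pipeline.run_pipeline(pipeline.PipelineConfig(n_avalanches=11_000, seed=SEED))
    rows.append(("baseline", "fixed", *[base["fixed"][k] for k in ("n", "alpha", "s0", "gamma", "p")]))
    for name, drive in pipeline.REGIMES.items():
        s = pipeline.run_pipeline(
            pipeline.PipelineConfig(
                drive_mode=drive["drive_mode"],
                drive_peak=drive["drive_peak"],
                n_trials=N_TRIALS[name],
                seed=SEED + hash(name) % 1000,
            )
        )
        for binning in ("fixed", "adaptive"):
            b = s[binning]
            rows.append((name, binning, b["n"], b["alpha"], b["s0"], b["gamma"], b["p"]))
    df = pd.DataFrame(rows, columns=["regime", "binning", "n", "alpha", "s0", "gamma", "p_vs_exp"])
    df.to_csv(OUT, index=False, float_format="%.6g")
    print(df.to_string(index=False))
    print(
        "\nReading: baseline cutoff s0 sits at the network saturation scale with a "
        "sharp decay (gamma >> 1). Input-driven: fixed binning pushes s0 past the "
        "100-site system; adaptive binning pulls it back. Supercritical: s0 stays "
        "past system size even after adaptation. Poisson noise: gamma collapses "
        "below 1 under both binnings - no sharp cutoff survives."
    )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
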