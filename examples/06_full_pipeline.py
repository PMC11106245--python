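"""One-call pipeline run: simulate -> preprocess -> univariate -> screen ->
GFS -> evaluate -> report, into a single reproducible run directory.
"""

import pandas as pd

from mspanel import GeneratorConfig, RunConfig, ScreenConfig, run_pipeline

config = RunConfig(
    out_dir="scratch/example_run",
    rng_seed=9,
    bootstrap_reps=50,      # scaled down for a quick demonstration
    screen_repeats=100,     # desk preset: 200 reps / 2,000 repeats
    generator=GeneratorConfig(
        n_proteins=24,
        rng_seed=9,
        n_samples={"CLIMB-like": 150, "EPIC-like": 80, "ACP-like": 60},
    ),
    screen=ScreenConfig(sizes=(3, 6, 9), panel_budget=8),
)
run_dir = run_pipeline(config)
print(f"run directory: {run_dir} (config hash {config.config_hash()})")

table = pd.read_csv(run_dir / "report" / "performance_table.csv")
print("\nperformance table (mean +/- sd over bootstrap splits):")
print(table.to_string(index=False))
# Rows: the lesion-count regression (R^2) and the five classification
# contrasts (AUROC); columns: the GFS panel, the anchor alone, and
# everything except the anchor.  Rerunning with the same config and seed
# reproduces every artifact bit for bit.
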