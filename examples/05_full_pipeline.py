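"""Run the complete pipeline — generator, behavior, signal conditioning,
rates, tuning, dPCA, EMG correlation — from one config, writing TSV/HDF5/
JSON outputs to a directory.

Equivalent shell command: graspdyn run --seed 7 --out graspdyn_out
"""

import json

from graspdyn.dpca import DPCAConfig
from graspdyn.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/pipeline_demo",
    rng_seed=7,
    n_units=15,
    n_trials=120,
    # reduced cross-validation budget for a quick demo
    dpca=DPCAConfig(n_components=10, lambda_repetitions=3,
                    cv_iterations=15, n_shuffles=15),
)
report = run_pipeline(cfg)

print(json.dumps(report["stages"], indent=1, default=str))
# The report summarizes each stage: trial/exclusion counts, per-effect
# numbers of tuned units, dPCA variance shares, decoding intervals, and the
# neural-EMG R^2 table at the chosen time shift (positive = neural leads).
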