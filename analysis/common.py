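"""Shared configuration of the demo analysis: an ALK-like cohort of 63
patients (the main analysis) plus an EGFR-like null cohort of 105 patients
(the negative control), simulated at the generator's default study
conditions.

Bulky pipeline artifacts (NRRD volumes, the full feature table) live under
scratch/run/; each numbered script copies its small text summaries into
results/.
"""

import shutil
from pathlib import Path

from ctradiomics.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def demo_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        output_dir=str(SCRATCH / "run"),
        seed=seed,
        n=63,
        n_null=105,
        stability_splits=10,
    )


def publish(*names: str) -> None:
    """Copy small text artifacts from scratch/run into results/."""
    RESULTS.mkdir(exist_ok=True)
    for name in names:
        src = SCRATCH / "run" / name
        if src.exists():
            shutil.copy(src, RESULTS / name)
            print(f"published results/{name}")
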