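"""Shared setup for the numbered analysis scripts: one study-scale synthetic
bundle (56 miRNAs, 24 up / 32 down; 89 patients) and the pipeline run over it.
"""

from pathlib import Path

from mirsubnet import PipelineConfig, SimulationConfig, simulate
from mirsubnet.pipeline import run_pipeline

STUDY_SEED = 7

RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_bundle(seed: int = STUDY_SEED):
    return simulate(SimulationConfig(seed=seed))


def get_result(bundle=None):
    return run_pipeline(bundle or get_bundle(), PipelineConfig())


def outdir(name: str = "") -> Path:
    path = RESULTS / name if name else RESULTS
    path.mkdir(parents=True, exist_ok=True)
    return path
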