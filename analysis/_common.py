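"""Shared configuration for the numbered analysis drivers.

The full synthetic study is executed once by 01_simulate_and_run.py into
``scratch/study`` (bulky intermediate data lives under scratch/); the
later drivers read the staged outputs from there, narrate what each
analysis step found, and write their curated tables under ``results/``.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

STUDY_SEED = 2023

STUDY_CONFIG = {
    "seed": STUDY_SEED,
    "out_dir": str(SCRATCH),
    "genotypes": {"n": 800, "m": 250},
    "proteins": [
        {"name": "PROT1", "n_causal": 1, "h2": 0.25},
        {"name": "PROT2", "n_causal": 2, "h2": 0.20},
        {"name": "PROT3", "n_causal": 0, "h2": 0.0},
    ],
    "coloc": {"n": 2000, "m": 600, "mode": "shared", "h2_a": 0.05, "h2_b": 0.05},
}


def ensure_study() -> Path:
    """Run the pipeline into scratch/study unless its outputs already exist."""
    if not (SCRATCH / "manifest.json").exists():
        from cispqtl.pipeline import run_pipeline

        run_pipeline(STUDY_CONFIG)
    RESULTS.mkdir(exist_ok=True)
    return SCRATCH
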