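"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

from fdgsig.pipeline import load_config, run_pipeline

HERE = Path(__file__).resolve().parent
CONFIG = HERE / "config.yaml"
OUTDIR = HERE.parent / "results" / "study"


def run_stage(*stages: str) -> None:
    run_pipeline(load_config(CONFIG), outdir=OUTDIR, stages=list(stages))
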