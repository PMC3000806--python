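"""Shared paths and loading for the numbered analysis drivers."""

from __future__ import annotations

import logging
from pathlib import Path

from phenocopy.core_io import AnalysisConfig, read_study

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1

logging.disable(logging.INFO)


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS


def load_study():
    return read_study(RESULTS / "matrix.tsv", RESULTS / "design.csv")


def analysis_config() -> AnalysisConfig:
    return AnalysisConfig(seed=SEED, permutations_B=1000)
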