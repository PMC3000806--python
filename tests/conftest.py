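import logging

import numpy as np
import pytest

from phenocopy.core_io import AnalysisConfig, ExpressionStudy, SampleRecord
from phenocopy.simdata import SimConfig, generate_study

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def noisy_study():
    """Moderate-size study at the default noise conditions, with truth."""
    sim = SimConfig(n_genes=900, seed=101)
    return generate_study(sim)


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free study: every mean-model effect is exact."""
    sim = SimConfig(n_genes=500, seed=202, noise_sd_scale=0.0)
    return generate_study(sim)


@pytest.fixture()
def config():
    return AnalysisConfig(seed=7, permutations_B=199)


@pytest.fixture()
def tiny_study():
    """Hand-built 3-gene study with two vehicle arms for direct checks."""
    samples = []
    values = []
    rng = np.random.default_rng(5)
    for stim in (True, False):
        for r in (1, 2, 3):
            samples.append(
                SampleRecord(
                    sample_id=f"V_{'tgf' if stim else 'wotgf'}_r{r}",
                    modulator="none",
                    compound_id=None,
                    concentration_uM=None,
                    time_h=2.0,
                    stimulated=stim,
                    vehicle="dmso",
                    replicate=r,
                )
            )
    base = np.array([8.0, 9.0, 7.0])
    effect = np.array([2.0, -1.5, 0.0])
    cols = []
    for s in samples:
        cols.append(base + (effect if s.stimulated else 0) + rng.normal(0, 0.05, 3))
    values = np.column_stack(cols)
    return ExpressionStudy(genes=["G1", "G2", "G3"], samples=samples, values=values)
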