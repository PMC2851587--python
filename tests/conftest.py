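import numpy as np
import pandas as pd
import pytest

from pepquant.dataio import IntensityMatrix, load_bundled_design
from pepquant.simulate import SimulationConfig, generate_design, simulate_intensities


@pytest.fixture(scope="session")
def bundled_design():
    return load_bundled_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides):
    """A compact factorial (4 samples per cell, 1 block, few peptides)."""
    base = dict(
        group_sizes={g: 4 for g in
                     ("ed12MC", "ed12FC", "ed12ME", "ed12FE",
                      "ed17MC", "ed17FC", "ed17ME", "ed17FE")},
        n_blocks=1,
        reference_replicates=0,
        n_peptides=30,
        age_effect_fraction=0.0,
        sex_effect_fraction=0.0,
        treatment_effect_fraction=0.0,
        interaction_fraction=0.0,
        drift_amplitude=0.0,
        run_slope_sd=0.0,
        run_intercept_sd=0.0,
        noise_sd=0.3,
        miss_floor=0.0,
        miss_steepness=np.inf,
        miss_midpoint=-np.inf,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture()
def clean_dataset():
    """Complete (no-missing) simulated matrix + design, mild noise, no drift."""
    cfg = small_config(seed=7)
    design = generate_design(cfg)
    matrix, truth = simulate_intensities(cfg, design)
    return matrix, design, truth


def toy_matrix(values, peptides=None, runs=None, state=("log2",)):
    values = np.asarray(values, float)
    peptides = peptides or [f"p{i}" for i in range(values.shape[0])]
    runs = runs or [f"r{j}" for j in range(values.shape[1])]
    return IntensityMatrix(
        values=pd.DataFrame(values, index=peptides, columns=runs), state=state)
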