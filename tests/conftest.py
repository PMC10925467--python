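import numpy as np
import pandas as pd
import pytest

from brainlipid import preprocess, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimConfig(
        seed=11,
        n_control=20,
        n_aad=15,
        n_sad=25,
        n_features=80,
        n_qc=12,
        modules=[
            simulate.ModuleSpec(10, 0.7, ("LPE", "LPC"), "diagnosis", -0.8),
            simulate.ModuleSpec(10, 0.7, ("TAG",)),
        ],
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate.simulate_all(small_config)


@pytest.fixture(scope="session")
def small_log(small_sim):
    """Filtered, missing-handled, drift-corrected log2 table of the small cohort."""
    filt = preprocess.filter_features(small_sim.lipidome)
    clean = preprocess.handle_missing(filt.table)
    corrected, _ = preprocess.qc_drift_correct(
        clean, preprocess.DriftParams(seed=11, n_trees=50)
    )
    return preprocess.log2_transform(corrected)


def planted_blocks(seed, n_modules=6, size=20, rho=0.7, n=300, n_noise=0):
    """Block-correlated features (plus optional independent noise features)."""
    rng = np.random.default_rng(seed)
    cols, truth = [], []
    for m in range(n_modules):
        f = rng.standard_normal(n)
        for _ in range(size):
            cols.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n))
            truth.append(m)
    for _ in range(n_noise):
        cols.append(rng.standard_normal(n))
        truth.append(-1)
    data = pd.DataFrame(
        np.array(cols).T, columns=[f"f{i}" for i in range(len(cols))]
    )
    return data, np.array(truth)
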