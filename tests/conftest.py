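import numpy as np
import pandas as pd
import pytest

from colonylapse.simulate import SimConfig, simulate_curves


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_experiment():
    """Small noiseless experiment covering every phenotype class."""
    cfg = SimConfig(
        n_strains=40, n_replicates=3, noise_sigma=0.0, gradient_amplitude=0.0,
        n_rows=5, n_cols=8, fill_extra_positions=False, seed=1,
    )
    return simulate_curves(cfg)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Small noisy experiment with gradients, for statistical smoke tests."""
    cfg = SimConfig(
        n_strains=60, n_replicates=6, n_rows=8, n_cols=10,
        fill_extra_positions=True, seed=2,
    )
    return simulate_curves(cfg)


@pytest.fixture
def replicate_table(rng):
    """Replicate metrics table: 8 strains x 2 conditions x 8 replicates."""
    rows = []
    for i in range(8):
        for cond in ("untreated", "treated"):
            shift = 2.0 if (i < 2 and cond == "treated") else 0.0
            for rep in range(8):
                rows.append({
                    "strain_id": f"s{i:02d}", "plate_id": f"{cond}_p{rep}",
                    "condition": cond, "replicate": rep,
                    "lag_v_stall": rng.normal(shift, 1.0),
                    "colony_fitness": rng.normal(100 - 10 * shift, 5.0),
                })
    return pd.DataFrame(rows)
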