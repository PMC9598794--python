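import numpy as np
import pandas as pd
import pytest

from cernet.containers import CountMatrix
from cernet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_ds():
    """Compact dataset with three planted sponge triplets."""
    cfg = SimulationConfig(n_mrna=60, n_lncrna=30, n_mirna=15, n_triplets=3,
                           frac_null=0.8, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_ds():
    """One instance of the default study conditions (500/200/100, 6 vs 6,
    5 planted triplets)."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def toy_counts():
    """5 features x 4 samples, all counts positive."""
    rng = np.random.default_rng(42)
    vals = rng.integers(10, 200, size=(5, 4))
    df = pd.DataFrame(vals, index=pd.Index([f"g{i}" for i in range(5)], name="id"),
                      columns=["H1", "H2", "L1", "L2"])
    groups = {"H1": "high", "H2": "high", "L1": "low", "L2": "low"}
    return CountMatrix(df, "mRNA", groups)


def make_block_expr(seed, n_blocks=3, n_per=50, n_samples=12, within_r=0.9,
                    kme_range=None):
    """Planted-partition expression: genes share a per-block latent profile.

    With ``kme_range`` the gene-latent correlation varies per gene (uneven
    module tightness); otherwise it is sqrt(within_r) for everyone.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for b in range(n_blocks):
        z = rng.normal(size=n_samples)
        for _ in range(n_per):
            w = (rng.uniform(*kme_range) if kme_range
                 else np.sqrt(within_r))
            rows.append(w * z + np.sqrt(1 - w**2) * rng.normal(size=n_samples))
            labels.append(b)
    expr = pd.DataFrame(rows, index=[f"G{i:03d}" for i in range(len(rows))],
                        columns=[f"S{j}" for j in range(n_samples)])
    return expr, labels
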