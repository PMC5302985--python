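import numpy as np
import pandas as pd
import pytest

import cerna_sponge as cs


@pytest.fixture(scope="session")
def default_dataset() -> cs.SyntheticDataset:
    """The standard synthetic study (60 cancer / 30 normal, seed 1)."""
    return cs.generate_dataset(cs.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset() -> cs.SyntheticDataset:
    """A reduced study for fast end-to-end tests."""
    cfg = cs.SyntheticConfig(
        n_cancer=40, n_normal=24, n_lncrna=100, n_mrna=200, n_mirna=40,
        n_planted_triples=12, n_diff_edges=4, seed=7,
    )
    return cs.generate_dataset(cfg)


def random_expression(seed: int, n_features: int = 10, n_samples: int = 10,
                      feature_class: str = "lncRNA") -> cs.ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return cs.ExpressionMatrix(
        pd.DataFrame(
            rng.normal(5, 2, (n_features, n_samples)),
            index=[f"F{i:03d}" for i in range(n_features)],
            columns=[f"S{j:03d}" for j in range(n_samples)],
        ),
        feature_class,
    )


def random_network(seed: int, n_edges: int = 50, condition: str = "cancer") -> cs.CeRNANetwork:
    rng = np.random.default_rng(seed)
    edges = {}
    while len(edges) < n_edges:
        lnc = f"L{rng.integers(40):03d}"
        mrna = f"G{rng.integers(200):03d}"
        mirnas = frozenset(
            f"M{m:03d}" for m in rng.choice(30, size=rng.integers(1, 5), replace=False)
        )
        edges[(lnc, mrna)] = cs.EdgeData(
            mirnas, float(rng.normal()), float(rng.uniform(1e-4, 0.01))
        )
    return cs.CeRNANetwork(condition, edges)
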