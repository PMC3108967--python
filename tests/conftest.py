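import numpy as np
import pandas as pd
import pytest

import cssqtl as c


@pytest.fixture(scope="session")
def small_map():
    """15 markers at 2 cM / 3 Mb spacing on one chromosome."""
    return c.MarkerMap.evenly_spaced(n_markers=15, spacing_cm=2.0, spacing_bp=3_000_000)


@pytest.fixture(scope="session")
def two_marker_map():
    return c.MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ["m1", "m2"],
                "chromosome": "15",
                "position_bp": [1_000_000, 21_000_000],
                "position_cm": [0.0, 20.0],
            }
        )
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small complete dataset with all planted features, shared across tests."""
    return c.simulate_dataset(
        seed=7,
        n_individuals=40,
        n_expression_samples=None,
        n_probes=220,
        module_size=20,
        n_cis=5,
        n_trans=5,
        n_snp_probes=3,
    )


def exact_correlated_pair(r: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two length-n vectors with sample Pearson correlation exactly r."""
    rng = np.random.default_rng(12345)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    y = y - y.mean()
    y -= x * np.dot(x, y) / np.dot(x, x)  # orthogonalize
    y /= y.std()
    return x, r * x + np.sqrt(1 - r * r) * y
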