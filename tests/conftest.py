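import numpy as np
import pandas as pd
import pytest

from paraloverlap.data import CONDITIONS, CountMatrix
from paraloverlap.synth import SimConfig, simulate_counts


def make_matrix(counts: np.ndarray, n_reps: int) -> CountMatrix:
    """Wrap a raw array (genes × 6·n_reps) into a labelled CountMatrix."""
    n_genes = counts.shape[0]
    sample_ids = [f"{c}_r{j + 1}" for c in CONDITIONS for j in range(n_reps)]
    sheet = pd.Series(
        [c for c in CONDITIONS for _ in range(n_reps)], index=sample_ids
    )
    genes = [f"g{i}" for i in range(n_genes)]
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids), sheet)


@pytest.fixture
def toy_matrix() -> CountMatrix:
    """Deterministic 5-gene, 6×3-sample matrix with exact condition means."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(5, 18))
    return make_matrix(counts, n_reps=3)


@pytest.fixture(scope="session")
def small_sim():
    """One small default simulation shared across tests."""
    cfg = SimConfig(n_genes=600, n_targets_tf1=60, n_targets_tf2=60, seed=11)
    cm, truth = simulate_counts(cfg)
    return cfg, cm, truth
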