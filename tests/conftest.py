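import numpy as np
import pandas as pd
import pytest

from omicmatch import (
    CisAssociationSet,
    OmicsMatrix,
    SimulationConfig,
    iterate_alignment,
    simulate_dataset,
)


def make_matrix(values, feature_ids=None, sample_ids=None, data_type="test"):
    values = np.asarray(values, dtype=float)
    f = feature_ids or [f"g{i}" for i in range(values.shape[0])]
    s = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(values, f, s, data_type)


def make_cis(pairs, rhos=None, significant=None, n_used=50):
    """Hand-built CisAssociationSet for tests that bypass discovery."""
    n = len(pairs)
    rhos = rhos if rhos is not None else [0.9] * n
    significant = significant if significant is not None else [True] * n
    table = pd.DataFrame(
        {
            "feature_a": [a for a, _ in pairs],
            "feature_b": [b for _, b in pairs],
            "rho": rhos,
            "p": [1e-6] * n,
            "q": [1e-5] * n,
            "n_used": [n_used] * n,
            "significant": significant,
        }
    )
    return CisAssociationSet(table=table, alpha=0.05)


@pytest.fixture(scope="session")
def sim_clean():
    """Error-free paired dataset: 300 planted cis pairs, 120 core samples."""
    return simulate_dataset(SimulationConfig(n_cis=300, m_samples=120, seed=7))


@pytest.fixture(scope="session")
def outcome_prob_clean(sim_clean):
    return iterate_alignment(
        sim_clean.matA, sim_clean.matB, sim_clean.candidates, matcher="probabilistic", seed=7
    )


@pytest.fixture(scope="session")
def outcome_rank_clean(sim_clean):
    return iterate_alignment(
        sim_clean.matA, sim_clean.matB, sim_clean.candidates, matcher="rank", seed=7
    )
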