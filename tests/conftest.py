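import numpy as np
import pytest

from raftscreen import synthdata
from raftscreen.panel import default_mfn2_panel


@pytest.fixture(scope="session")
def panel():
    return default_mfn2_panel()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale experiment used by most module tests."""
    return synthdata.SimConfig(
        cells_per_well=120,
        n_features=30,
        n_informative=6,
        effect_size=1.5,
        leaky_feature_count=2,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    cells, layout, truth = synthdata.simulate_plate(small_config)
    return small_config, cells, layout, truth


def two_class_scores(rng, n_pos, n_neg, sep=1.0):
    """Random score/label instance for AUC oracle checks."""
    scores = np.concatenate([rng.normal(sep, 1, n_pos), rng.normal(0, 1, n_neg)])
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    return scores, labels


def pairwise_concordance_auc(scores, labels):
    """Brute-force AUC oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
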