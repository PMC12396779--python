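import numpy as np
import pytest

from medconf import (
    SimulatorConfig,
    grade_log,
    simulate_items,
    simulate_responses,
)


@pytest.fixture(scope="session")
def default_sim():
    """One simulated study at the default conditions (seeded)."""
    cfg = SimulatorConfig(n_items=1000, seed=20240610)
    items = simulate_items(cfg)
    records = simulate_responses(items, cfg)
    return cfg, items, records


@pytest.fixture(scope="session")
def default_graded(default_sim):
    cfg, items, records = default_sim
    graded, exclusions = grade_log(items, records)
    return graded, exclusions


def brute_force_auc(scores, outcomes):
    """O(n^2) pairwise AUROC oracle: P(pos > neg) + 0.5 P(tie).

    Materializes every (positive, negative) pair explicitly — no ranking
    shortcut — so it is an independent check on the fast implementation.
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    pos = scores[outcomes][:, None]
    neg = scores[~outcomes][None, :]
    wins = (pos > neg).sum()
    ties = (pos == neg).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)
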