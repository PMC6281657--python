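import numpy as np
import pytest

from valencepop.preprocessing import TrialTensor
from valencepop.synthetic import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Compact generator config for fast structural tests."""
    return GeneratorConfig(n_mice=2, n_neurons_per_mouse=10, seed=99)


@pytest.fixture
def null_tensor(rng):
    """Pure-noise tensor: 20 neurons, 10 trials of each stimulus."""
    stimuli = np.repeat(["CS1", "CS2", "US1", "US2"], 10)
    values = 0.5 + 0.05 * rng.standard_normal((20, 40, 230))
    return TrialTensor(values, 10.0, 100, stimuli, stage="pre",
                       mouse_ids=np.zeros(20, dtype=int))


def exact_signed_rank_pvalue(diffs: np.ndarray) -> float:
    """Brute-force oracle: two-sided exact signed-rank p by enumerating all
    2^n sign assignments of the ranked |differences| (midranks for ties,
    zeros dropped). Independent of the implementation under test."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = 2 ** n
    stats = np.zeros(total)
    for mask in range(total):
        picks = [(mask >> i) & 1 for i in range(n)]
        stats[mask] = sum(r for r, p in zip(ranks, picks) if p)
    ge = np.sum(stats >= w_obs - 1e-9) / total
    le = np.sum(stats <= w_obs + 1e-9) / total
    return float(min(1.0, 2.0 * min(ge, le)))
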