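import itertools

import pytest
from hypothesis import settings

from vapewatch import GeneratorConfig, StudyConfig, generate_corpus

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def brute_force_itemsets(transactions, min_support):
    """Independent oracle: exhaustive subset enumeration with pruning.

    Counts every candidate itemset over the observed alphabet directly
    against the transaction list; anti-monotonicity lets us stop once a size
    level yields nothing frequent.
    """
    transactions = [frozenset(t) for t in transactions]
    alphabet = sorted(set(itertools.chain.from_iterable(transactions)))
    out = {}
    for k in range(1, len(alphabet) + 1):
        found = False
        for combo in itertools.combinations(alphabet, k):
            s = frozenset(combo)
            support = sum(1 for t in transactions if s <= t)
            if support >= min_support:
                out[s] = support
                found = True
        if not found:
            break
    return out


@pytest.fixture(scope="session")
def study_config() -> StudyConfig:
    return StudyConfig.default()


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus with ground truth (1/100 scale)."""
    config = GeneratorConfig(users_per_period=(1268, 484, 1897), seed=42)
    return generate_corpus(config)
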