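import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from napcensus import (
    Category,
    default_classmap,
    default_glossary,
    default_synonyms,
)
from napcensus.synth import SyntheticConfig, generate_corpus

settings.register_profile(
    "census",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("census")


@pytest.fixture(scope="session")
def glossary():
    return default_glossary()


@pytest.fixture(scope="session")
def synonyms():
    return default_synonyms()


@pytest.fixture(scope="session")
def classmap():
    return default_classmap()


@pytest.fixture(scope="session")
def random_corpus_factory():
    """Small rate-mode corpora with every exclusion branch active."""

    def make(seed: int, n: int = 30):
        cfg = SyntheticConfig(
            n_studies=n,
            seed=seed,
            universe_sizes={Category.METABOLITE: 20, Category.TARGET: 25,
                            Category.PATHWAY: 15},
            mean_list_length={Category.METABOLITE: 4.0, Category.TARGET: 5.0,
                              Category.PATHWAY: 3.0},
            over_threshold_rate={Category.METABOLITE: 0.05,
                                 Category.TARGET: 0.05,
                                 Category.PATHWAY: 0.05},
            threshold=10,
            max_list_length=14,
            single_compound_rate=0.2,
            no_heading_rate={c: 0.15 for c in Category},
            incomplete_rate={c: 0.05 for c in Category},
            p_integrated={Category.METABOLITE: 0.3, Category.TARGET: 0.2,
                          Category.PATHWAY: 0.0},
            p_unknown_method=0.1,
        )
        return generate_corpus(cfg), cfg

    return make
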