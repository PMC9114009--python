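import numpy as np
import pytest

from m6alens.synthetic_grammar import (GenomeConfig, GrammarScorer,
                                       generate_genome, make_grammar)


@pytest.fixture(scope="session")
def linear_grammar():
    return make_grammar(seed=5)


@pytest.fixture(scope="session")
def oracle(linear_grammar):
    return GrammarScorer(linear_grammar)


@pytest.fixture(scope="session")
def small_genome(linear_grammar):
    return generate_genome(linear_grammar, GenomeConfig(n_genes=8), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def seq_with_site(rng, length=200, site=80):
    """Random sequence carrying a guaranteed RAC consensus at ``site``."""
    s = random_seq(rng, length)
    return s[:site - 1] + "GAC" + s[site + 2:]
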