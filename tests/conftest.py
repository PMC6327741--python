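"""Shared fixtures: synthetic datasets and their cross-validation results.

The 400-site planted-signal and no-signal datasets (and their seeded
10-fold CV reports) are session-scoped because the random-forest runs
are the expensive part of the suite and several tests assert against
the same experiment.
"""

import numpy as np
import pytest

from ramfeat import SyntheticSpec, assemble, crossval_10fold, generate_sequences


@pytest.fixture(scope="session")
def planted_sites():
    """400 sites where the label is determined by tryptophan proximity."""
    spec = SyntheticSpec(n_proteins=200, cys_range=(2, 2), seed=11)
    _, sites = generate_sequences(spec)
    return sites


@pytest.fixture(scope="session")
def planted_table(planted_sites):
    """RAMseq-only feature table over the planted-signal sites."""
    return assemble(planted_sites, n_seq=6)


@pytest.fixture(scope="session")
def planted_cv(planted_table):
    return crossval_10fold(planted_table, classifier="rf", seed=11)


@pytest.fixture(scope="session")
def nosignal_table():
    spec = SyntheticSpec(
        n_proteins=200, cys_range=(2, 2), signal_kind="none", seed=11
    )
    _, sites = generate_sequences(spec)
    return assemble(sites, n_seq=6)


@pytest.fixture(scope="session")
def nosignal_cv(nosignal_table):
    return crossval_10fold(nosignal_table, classifier="rf", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
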