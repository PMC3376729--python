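"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pytest

import dinucmap as dm


@pytest.fixture(scope="session")
def small_sim() -> dm.synthetic.SimResult:
    """A compact full simulation (2 x 60 kb, 12 genes) shared read-only."""
    cfg = dm.SimConfig(seed=4, n_contigs=2, contig_length=60_000, n_genes=12,
                       n_mono_fragments=80_000, n_di_fragments=80_000)
    return dm.simulate_all(cfg)


@pytest.fixture(scope="session")
def default_sim() -> dm.synthetic.SimResult:
    """One simulation at full package defaults (2 x 100 kb, 30 genes)."""
    return dm.simulate_all(dm.SimConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
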