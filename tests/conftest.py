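import numpy as np
import pytest

from foldsel.synthetic import SyntheticConfig, generate_catalog


@pytest.fixture(scope="session")
def small_catalog():
    """A 30-gene synthetic catalog with decoy regions, reused read-only."""
    cfg = SyntheticConfig(n_genes=30, min_codons=20, max_codons=60,
                          n_pseudogenes=2, n_is_elements=1, seed=42)
    catalog, labels = generate_catalog(cfg)
    return catalog, labels, cfg


def random_cds(rng: np.random.Generator, n_codons: int, gc: float = 0.5) -> str:
    from foldsel.synthetic import _random_cds
    return _random_cds(rng, n_codons, gc)
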