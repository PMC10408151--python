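import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cptransfer import GeneratorConfig, generate_family


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic family shared across tests (read-only)."""
    return generate_family(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Noise-free, missingness-free family for exact-recovery checks."""
    return generate_family(GeneratorConfig.noise_free(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_msa(query: str, rows: list[str], source: str = "vert100", gene: str = "G"):
    from cptransfer import AnchoredMSA

    return AnchoredMSA(gene=gene, query=query, rows=[query] + rows, source=source)
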