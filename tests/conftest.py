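import numpy as np
import pytest

from triticolor.synthetic import PanelConfig, decode_genome, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 300-kb, 6-founder, 11-cultivar panel shared across tests."""
    cfg = PanelConfig(chrom_len=300_000, seed=3)
    base, founders, cultivars, donor, truth = generate_panel(cfg)
    return {
        "cfg": cfg,
        "base": base,
        "founders": founders,
        "cultivars": cultivars,
        "donor": donor,
        "truth": truth,
        "ref": decode_genome(base),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
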