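import numpy as np
import pytest

from silencerscope.genome_io import Replicon
from silencerscope.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def dataset():
    """One shared synthetic dataset at the default study conditions."""
    return generate(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A cheaper dataset for tests that re-run pipeline stages."""
    cfg = SyntheticConfig(
        seed=11,
        replicons=[("chromosome", 60_000, 62.0), ("plasmidA", 40_000, 59.0)],
        n_peaks=120,
        n_islands_per_replicon=2,
        n_promoters=60,
    )
    return generate(cfg)


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return {"chr": Replicon("chr", seq, "chromosome")}


def random_dna(rng, n, letters="ACGT"):
    return "".join(rng.choice(list(letters), size=n))
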