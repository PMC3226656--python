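import numpy as np
import pytest

from cdhtest.core import GenotypeVector, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort(rng):
    """An associated low-frequency pair: recessive+CH effect at GRR 6."""
    from cdhtest.simulate import simulate_hwe_pair, simulate_phenotype_ch

    g1, g2 = simulate_hwe_pair(0.05, 0.04, 4000, rng)
    y = simulate_phenotype_ch(g1, g2, alpha=0.05, grr=6.0, rng=rng)
    return g1, g2, y


@pytest.fixture
def fixture_bundle(tmp_path):
    from cdhtest.io import make_fixtures

    truth = make_fixtures(tmp_path / "fx", seed=7)
    return tmp_path / "fx", truth
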