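import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import snpgsa

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_study():
    """The deterministic small study bundle."""
    return snpgsa.small_fixture()


@pytest.fixture(scope="session")
def fixture_results(fixture_study):
    """QC, mapping and associations of the small fixture, computed once."""
    fx = fixture_study
    retained, decisions = snpgsa.filter_snps(fx.study)
    mapping = snpgsa.map_snps_to_genes(fx.snps, fx.genes).restrict_snps(retained)
    assoc = snpgsa.associate_all(fx.study, sorted(mapping.snp_to_genes), n_perm=999, seed=1)
    return {"retained": retained, "decisions": decisions, "mapping": mapping, "assoc": assoc}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
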