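import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from generank.core import GeneRecord, GeneUniverse

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def universe():
    """Three genes on two chromosomes with all three nomenclatures."""
    return GeneUniverse(
        [
            GeneRecord(
                "G1", "chr1", 100, 1000,
                {"ensembl": "ENSG000001", "symbol": "ALPHA", "entrez": "7157"},
            ),
            GeneRecord(
                "G2", "chr1", 5000, 9000,
                {"ensembl": "ENSG000002", "symbol": "Beta1", "entrez": "672"},
            ),
            GeneRecord(
                "G3", "chr2", 200, 800,
                {"ensembl": "ENSG000003", "symbol": "GAMMA", "entrez": "1956"},
            ),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
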