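import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from chlorotune.synthetic_data import (
    GeneratorConfig,
    cluster_selection_map,
    make_pigment_cluster,
    reference_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    return reference_fixtures()


@pytest.fixture()
def dimer_cluster(tmp_path):
    """Two idealized chlorin rings 8 A apart, written to PDB."""
    path = tmp_path / "dimer.pdb"
    cfg = GeneratorConfig(seed=7, n_pigments=2)
    pigments, _ = make_pigment_cluster(cfg, path)
    return pigments, path, cluster_selection_map(2)
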