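import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import betaqtl as bq


@pytest.fixture(scope="session")
def small_bc_cross():
    """Backcross: 2 chromosomes x 6 markers @ 10 cM, one QTL, n=120."""
    gmap = bq.sim_map(2, 6, 10.0)
    cross = bq.sim_cross(gmap, 120, "bc", seed=11)
    return bq.sim_phenotype(
        cross, [bq.QTLSpec("1", 20.0, 1.5)], 0.5, seed=12
    )


@pytest.fixture(scope="session")
def small_f2_cross():
    """Intercross: 2 chromosomes x 6 markers @ 10 cM, one QTL with dominance."""
    gmap = bq.sim_map(2, 6, 10.0)
    cross = bq.sim_cross(gmap, 150, "f2", seed=21)
    return bq.sim_phenotype(
        cross,
        [bq.QTLSpec("1", 20.0, 1.0, dominance_effect=0.5)],
        0.5,
        seed=22,
    )


@pytest.fixture(scope="session")
def bc_fit_fixture(small_bc_cross):
    """(Y, X, probs, D) at the QTL position of the small backcross."""
    cross = small_bc_cross
    probs = bq.interval_qtl_probs(cross, "1", 15.0)  # interval midpoint
    D = bq.design_matrix("bc", 1)
    X = np.ones((cross.n, 1))
    return cross.phenotype, X, probs, D
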