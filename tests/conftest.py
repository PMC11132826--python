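import numpy as np
import pytest

import braingsa as bg
from braingsa.association import correlate
from braingsa.core import RegionGeometry


@pytest.fixture(scope="session")
def geometry34():
    return bg.generate_geometry(34, seed=1)


@pytest.fixture(scope="session")
def collinear3():
    """Three collinear centroids at unit spacing (hand-computable weights)."""
    return RegionGeometry(["a", "b", "c"], [[0, 0, 0], [1, 0, 0], [2, 0, 0]])


@pytest.fixture(scope="session")
def flat_expr(geometry34):
    """Independent-gene expression (no co-expression structure)."""
    spec = bg.SyntheticSpec(n_genes=600, n_parcels=34, loading_scale=0.0, seed=7)
    return bg.generate_expression(spec, geometry34)


@pytest.fixture(scope="session")
def structured_expr(geometry34):
    """Expression with a strong latent factor (high attainable co-expression)."""
    spec = bg.SyntheticSpec(
        n_genes=800, n_parcels=34, n_latent=2, loading_scale=2.0, noise_sd=1.0,
        seed=11,
    )
    return bg.generate_expression(spec, geometry34)


@pytest.fixture(scope="session")
def maps34(geometry34):
    return bg.simulate_maps(geometry34, 0.03, 20, pool_size=20000, seed=3)


@pytest.fixture(scope="session")
def profile(maps34, flat_expr):
    return correlate(maps34[0], flat_expr)
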