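import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import omvscreen as o

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_library() -> o.TrueLibrary:
    """Two-plate library with planted effects and defectives."""
    return o.generate_library(n_genes=192, seed=7)


@pytest.fixture(scope="session")
def null_library() -> o.TrueLibrary:
    """One-plate library with no planted effects of any kind."""
    return o.generate_library(n_genes=96, frac_over=0.0, frac_under=0.0,
                              frac_growth_defective=0.0, seed=3)


@pytest.fixture()
def blot_frame() -> pd.DataFrame:
    """Hand-built blot table: strain A has normalized replicates
    (0.8, 1.2), strain B the mirror (1.2, 0.8)."""
    return pd.DataFrame({
        "strain": ["A", "B", "A", "B"],
        "membrane_id": ["M1", "M1", "M2", "M2"],
        "replicate": [1, 1, 2, 2],
        "raw_intensity": [0.8, 1.2, 1.2, 0.8],
    })
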