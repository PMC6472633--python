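import numpy as np
import pandas as pd
import pytest

from traitclust import SyntheticConfig, TraitMatrix, generate_dataset
from traitclust.matrix import AggregationSpec


def matrix_from_array(x, species=None, traits=None) -> TraitMatrix:
    """Build a TraitMatrix directly from an array (identity scaling metadata).

    Handy for toy examples where the standardization pipeline is not the
    thing under test.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    n, p = x.shape
    species = species or [f"sp{i}" for i in range(n)]
    traits = traits or [f"trait{j}" for j in range(p)]
    values = pd.DataFrame(x, index=species, columns=traits)
    scaling = {t: {"log_base": 10.0, "location": 0.0, "scale": 1.0} for t in traits}
    return TraitMatrix(values=values, scaling=scaling, aggregation=AggregationSpec())


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study: 4 groups x 12 species, mild noise."""
    cfg = SyntheticConfig(
        species_per_group=12,
        missing_fraction=0.05,
        records_per_species=(2, 6),
        n_sites=3,
        plots_per_site=4,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The full-size default configuration (~295 complete-case species)."""
    return generate_dataset(SyntheticConfig(seed=7))
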