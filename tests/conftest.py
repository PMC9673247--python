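import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_metadata(
    species=("sp",),
    fruit_types=None,
    stages=(("2", 2.0), ("3", 3.0), ("Tr", 4.0)),
    replicates=3,
):
    """Sample metadata for a balanced multi-species stage design."""
    if fruit_types is None:
        fruit_types = ["fleshy"] * len(species)
    rows = []
    for sp, ft in zip(species, fruit_types):
        for lab, t in stages:
            for r in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{sp}_{lab}_r{r}",
                        "species": sp,
                        "fruit_type": ft,
                        "stage_label": lab,
                        "time": float(t),
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def meta_one_species():
    return make_metadata()


@pytest.fixture
def meta_two_fruit_types():
    return make_metadata(
        species=("dryland", "berry"), fruit_types=("dry", "fleshy"), replicates=3
    )


def nb_counts(rng, mu, alpha, size):
    """NB draws via the gamma-Poisson mixture (matches the generator)."""
    mu = np.broadcast_to(mu, size).astype(float)
    if np.isscalar(alpha) and alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / alpha, alpha * mu)
    return rng.poisson(lam)
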