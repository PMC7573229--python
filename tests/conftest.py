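import numpy as np
import pandas as pd
import pytest

import ktscreen as kt


@pytest.fixture(scope="session")
def reference_ionome() -> pd.DataFrame:
    return kt.load_reference_ionome()


@pytest.fixture(scope="session")
def small_panel():
    """A 60-genotype panel with a strong latent-tolerance signal."""
    spec = kt.TraitGenSpec(
        n_genotypes=60, n_replicates=3, tolerance_loading=0.9, noise_sd=0.05, seed=42
    )
    return kt.generate_trait_panel(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
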