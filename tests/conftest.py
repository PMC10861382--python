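import numpy as np
import pytest

import twinaxe as tx
from twinaxe.simulate import default_item_bank, hyperactivity_truth


@pytest.fixture(scope="session")
def small_bank():
    """Three 4-category items for fast joint-model smoke tests."""
    return tx.ItemBank(
        alphas=np.array([1.0, 0.9, 1.1]),
        thresholds=[
            np.array([0.0, -1.0, 0.0, 1.0]),
            np.array([0.0, -0.8, 0.2, 1.2]),
            np.array([0.0, -1.2, -0.2, 0.8]),
        ],
    )


@pytest.fixture(scope="session")
def bank9():
    return default_item_bank()


@pytest.fixture(scope="session")
def hyper_truth():
    return hyperactivity_truth()


@pytest.fixture(scope="session")
def small_cohort(small_bank):
    """60 MZ + 80 DZ pairs, 3 items, a little missingness."""
    params = tx.GeneticParams(
        model="AE", interaction=True, sigma2_a=0.3,
        beta0=float(np.log(0.25)), beta1=1.5,
    )
    design = tx.CohortDesign(
        n_mz=60, n_dz=80, n_categories=small_bank.n_categories,
        missingness_spec=((0.9, 0), (0.1, 1)),
    )
    table, latents = tx.simulate_cohort(params, design, small_bank, seed=101)
    return table, latents, params
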