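import numpy as np
import pytest

from epitensor.synthetic import generate_tensor
from epitensor.training import TrainingConfig


@pytest.fixture(scope="session")
def small_tensor():
    """A small noisy low-rank tensor shared by read-only tests."""
    tensor, truth = generate_tensor(
        J=8, K=5, I=120, L_true=2, sigma=0.05,
        observed_fraction=0.7, min_support=2, seed=7,
    )
    return tensor, truth


def tiny_config(**overrides) -> TrainingConfig:
    """A configuration scaled for second-long training runs."""
    base = dict(
        latent_factors=4,
        partition_size=40,
        local_iters=300,
        burnin_loci=200,
        training_locus_fraction=1.0,
        mse_record_every=3,
        min_rounds=9,
        window_records=3,
        line_search_len=1,
        max_rounds=60,
        n_folds=2,
        lam_C=0.5,
        lam_A=0.5,
        lam_G=0.5,
        lam_G2=0.5,
        seed=0,
    )
    base.update(overrides)
    return TrainingConfig(**base)
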