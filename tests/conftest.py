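import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "plantmir",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("plantmir")


@pytest.fixture(scope="session")
def small_benchmark():
    """A 40/80 synthetic benchmark shared across tests (seed 7)."""
    from plantmir import SimulatorConfig, generate_benchmark

    cfg = SimulatorConfig(seed=7, n_positives=40, n_negatives=80)
    dataset, records, ests = generate_benchmark(cfg)
    return dataset, records, ests


@pytest.fixture(scope="session")
def small_model(small_benchmark):
    """A boosted model trained on the 40/80 benchmark."""
    from plantmir import boost, dataset_to_matrix

    dataset, _records, _ests = small_benchmark
    X, y, _ids = dataset_to_matrix(dataset.vectors)
    return boost(X, y, trials=10, seed=7)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
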