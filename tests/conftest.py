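import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_matrix(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    """A random 0/1 matrix with a randomly drawn density."""
    return (rng.random((n, m)) < rng.random()).astype(np.uint8)


@pytest.fixture(scope="session")
def family():
    """The full-scale synthetic genome family shared by the heavyweight
    end-to-end checks: 5 classes x 10 genomes x 20 kb, k = 63, sentinel
    wrapped.  Built once per session."""
    from cdbganno import synth_eval as se

    spec = se.SyntheticFamilySpec(seed=1)
    records = se.generate_family(spec)
    g, a = se.family_graph(records, k=63, add_sentinels=True)
    return records, g, a


@pytest.fixture()
def small_family():
    """A miniature family for fast end-to-end tests: 2 classes x 3 genomes,
    800 bp, k = 21."""
    from cdbganno import synth_eval as se

    spec = se.SyntheticFamilySpec(
        n_classes=2, genomes_per_class=3, genome_length=800, seed=9
    )
    records = se.generate_family(spec)
    g, a = se.family_graph(records, k=21, add_sentinels=True)
    return records, g, a
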