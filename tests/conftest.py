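import pytest
from hypothesis import settings

from progeval import SyntheticConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def corpus():
    """Hierarchical 7-label synthetic corpus (1 root, 2 internal, 4 leaves)."""
    config = SyntheticConfig(seed=1)
    return generate_dataset(config, 400)


@pytest.fixture(scope="session")
def flat3():
    """Flat 3-label corpus with fixed length 48 and strong motif signal."""
    config = SyntheticConfig(
        dag_shape=(3,),
        include_root_label=False,
        length_mean=48,
        length_sd=0,
        length_min=48,
        length_max=48,
        signal=0.5,
        multilabel_rate=0.0,
        seed=11,
    )
    return generate_dataset(config, 600)
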