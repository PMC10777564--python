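import numpy as np
import pytest

from gkmgraph.encoding import EncoderConfig
from gkmgraph.model import ModelConfig, ModelParams, TrainConfig, encode_dataset
from gkmgraph.sequence_io import Dataset, LabeledSequence
from gkmgraph.simulate import GeneratorConfig, generate_dataset


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_dataset():
    """Six hand-written records, three per class."""
    return Dataset(
        records=[
            LabeledSequence("p1", "GTACTAGTAC", 1),
            LabeledSequence("p2", "ACGTACGTAC", 1),
            LabeledSequence("p3", "TTACGGATCC", 1),
            LabeledSequence("n1", "AAAACCCCGG", 0),
            LabeledSequence("n2", "GGGGTTTTAA", 0),
            LabeledSequence("n3", "CCCCAAAATT", 0),
        ],
        name="tiny",
    )


@pytest.fixture
def small_model_config():
    """Deliberately narrow architecture for fast exact checks."""
    return ModelConfig(
        n_gcn_layers=1,
        gcn_hidden_dims=(4,),
        conv_channels=(3, 4, 3),
        conv_kernel_size=3,
        fc_hidden_dim=8,
        seed=7,
    )


@pytest.fixture
def micro_batch(small_model_config):
    """Three encoded sequences (k=2) with labels and matching parameters."""
    ds = generate_dataset(GeneratorConfig(n_per_class=2, length=40, seed=3))
    enc = EncoderConfig(k=2, d=2)
    graphs = encode_dataset(ds, enc)[:3]
    labels = ds.labels[:3]
    params = ModelParams.initialize(small_model_config, k=2)
    return graphs, labels, params


@pytest.fixture
def signal_dataset():
    """Synthetic set with the default planted order-2 signal."""
    return generate_dataset(GeneratorConfig(n_per_class=60, length=200, seed=5))


def default_train_config(**overrides):
    base = dict(learning_rate=0.01, epochs=5, batch_size=16, seed=1)
    base.update(overrides)
    return TrainConfig(**base)
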