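import numpy as np
import pytest

from mfpinc.data_io import LabeledDataset, SequenceRecord
from mfpinc.deep_features import ExtractorConfig
from mfpinc.model import PipelineConfig, fusion_ablation, run_training_pipeline
from mfpinc.synthetic import GeneratorParams


@pytest.fixture
def tiny_dataset():
    """Ten labeled records, five per class."""
    recs = [SequenceRecord(f"nc{i}", "ACGTACGTAC" * (i + 2), "ncRNA") for i in range(5)]
    recs += [SequenceRecord(f"m{i}", "ATGAAATAGC" * (i + 2), "mRNA") for i in range(5)]
    return LabeledDataset(recs)


@pytest.fixture
def small_extractor_config():
    """A scaled-down extractor for fast training tests."""
    return ExtractorConfig(seq_length=60, embedding_dim=8, hidden_units=10,
                           pool1_size=5, pool2_size=2, batch_size=8,
                           epochs=5, seed=7)


def make_motif_data(n: int, length: int, seed: int, shuffle_labels: bool = False):
    """Separable synthetic encodings: positives start with ATGATGATG."""
    from mfpinc.encoding import encode_indices_batch

    rng = np.random.default_rng(seed)
    seqs, labels = [], []
    bases = np.array(list("ACGT"))
    for i in range(n):
        positive = i % 2 == 0
        body = "".join(rng.choice(bases, size=length))
        seqs.append(("ATGATGATG" + body[9:]) if positive else body)
        labels.append(1.0 if positive else 0.0)
    y = np.array(labels)
    if shuffle_labels:
        y = rng.permutation(y)
    return encode_indices_batch(seqs, length), y


@pytest.fixture(scope="session")
def pipeline_run():
    """The full training pipeline on the default synthetic study conditions
    (200 records per class, seed 42), shared across tests."""
    config = PipelineConfig(
        synthetic=GeneratorParams(n_per_class=200, seed=42),
        extractor=ExtractorConfig(seed=42),
        seed=42,
    )
    result = run_training_pipeline(config)
    ablation = fusion_ablation(result, seed=42)
    return result, ablation
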