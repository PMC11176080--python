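import numpy as np
import pytest

from chromsites import sequence_model as sm
from chromsites import synthetic_data as syn


@pytest.fixture(scope="session")
def small_genome():
    """Compact genome with 60 planted sites for fast unit tests."""
    cfg = syn.SyntheticConfig(
        seed=11,
        n_sites=60,
        genome_length=400_000,
        chrom_names=("chr1", "chr2"),
        read_depth=200_000,
    )
    genome, truth = syn.simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def small_trained_cnn():
    """CNN trained on a small planted-signal problem, shared by the
    attribution unit tests (training once keeps the suite fast)."""
    cfg = syn.SyntheticConfig(
        seed=21,
        n_sites=1600,
        genome_length=3_200_000,
        chrom_names=("chr1", "chr2", "chr3", "chr4"),
    )
    genome, truth = syn.simulate_genome(cfg)
    delta, _ = syn.simulate_binding_response(truth.sites, a=0.5, b=0.8, noise_sd=0.2, seed=21)
    seqs = syn.site_sequences(genome, truth.sites)
    spec = sm.ModelSpec(max_epochs=18)
    split = sm.SplitSpec(holdout_chroms=("chr4",))
    model, report, test_mask = sm.train_model(
        seqs, delta, truth.sites["chrom"], split=split, spec=spec, seed=2
    )
    test_seqs = [s for s, m in zip(seqs, test_mask) if m]
    return model, report, test_seqs
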