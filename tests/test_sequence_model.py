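"""One-hot encoding, architecture audit, dinucleotide shuffling,
training protocol and attribution."""

import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr

from chromsites import synthetic_data as syn
from chromsites.sequence_model import (
    CNNRegressor,
    ModelSpec,
    SplitSpec,
    attribute,
    contribution_weight_matrix,
    cwm_mass_fraction,
    dinucleotide_shuffle,
    encode_batch,
    load_model,
    m2_site_scan,
    one_hot,
    one_hot_decode,
    per_position_scores,
    save_model,
    train_model,
    _ism_attribution,
)


# ---------------------------------------------------------------------------
# Encoding


def test_one_hot_all_a():
    x = one_hot("A" * 150)
    assert x.shape == (150, 4)
    np.testing.assert_array_equal(x[:, 0], 1.0)
    assert x[:, 1:].sum() == 0


def test_n_column_is_all_zero():
    x = one_hot("N" * 75 + "C" * 75)
    assert x[:75].sum() == 0
    np.testing.assert_array_equal(x[75:, 1], 1.0)


def test_one_hot_round_trip():
    rng = np.random.default_rng(0)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        assert one_hot_decode(one_hot(seq)) == seq


def test_wrong_length_rejected():
    with pytest.raises(ValueError, match="length"):
        one_hot("ACGT")


# ---------------------------------------------------------------------------
# Architecture audit


def test_parameter_shapes_match_spec():
    model = CNNRegressor(ModelSpec(), seed=0)
    got = model.parameter_shapes()
    expected = [
        ("Conv1D", "W", (5, 4, 128)), ("Conv1D", "b", (128,)),
        ("Conv1D", "W", (3, 128, 128)), ("Conv1D", "b", (128,)),
        ("Conv1D", "W", (5, 128, 128)), ("Conv1D", "b", (128,)),
        ("Conv1D", "W", (3, 128, 64)), ("Conv1D", "b", (64,)),
        ("Dense", "W", (576, 128)), ("Dense", "b", (128,)),
        ("Dense", "W", (128, 64)), ("Dense", "b", (64,)),
        ("Dense", "W", (64, 1)), ("Dense", "b", (1,)),
    ]
    assert got == expected
    # pooling shrinks 150 -> 75 -> 37 -> 18 -> 9
    assert model.flat_dim == 9 * 64


def test_forward_shapes_and_determinism():
    model = CNNRegressor(seed=1)
    x = encode_batch(["ACGT" * 37 + "AC"] * 3)
    y1 = model.predict(x)
    y2 = model.predict(x)
    assert y1.shape == (3,)
    np.testing.assert_array_equal(y1, y2)


def test_input_gradients_match_finite_differences():
    model = CNNRegressor(seed=2)
    rng = np.random.default_rng(3)
    x = rng.random((1, 150, 4)).astype(np.float32)
    g = model.input_gradients(x)[0]
    eps = 1e-3
    for p, b in [(0, 0), (75, 2), (149, 3), (40, 1)]:
        xp = x.copy()
        xp[0, p, b] += eps
        xm = x.copy()
        xm[0, p, b] -= eps
        fd = (model.predict(xp)[0] - model.predict(xm)[0]) / (2 * eps)
        assert g[p, b] == pytest.approx(fd, abs=2e-2)


# ---------------------------------------------------------------------------
# Dinucleotide shuffling


def dinuc_counts(seq):
    from collections import Counter

    return Counter(zip(seq, seq[1:]))


def test_shuffle_preserves_dinucleotide_counts():
    for seq in ("ACACAC", "AAACCCGGGTTTACGT", "TGACGTCATG" * 5):
        for sh in dinucleotide_shuffle(seq, n_shuffles=20, seed=1):
            assert dinuc_counts(sh) == dinuc_counts(seq)
            assert sh[0] == seq[0] and sh[-1] == seq[-1]


def test_shuffle_preserves_mononucleotide_counts():
    seq = "AAACCCGGGTTTACGTACGT"
    for sh in dinucleotide_shuffle(seq, n_shuffles=10, seed=2):
        assert sorted(sh) == sorted(seq)


def test_n_segments_shuffled_independently():
    seq = "ACGTACGTNNACGTACGT"
    for sh in dinucleotide_shuffle(seq, n_shuffles=5, seed=3):
        assert sh[8:10] == "NN"
        assert dinuc_counts(sh[:8]) == dinuc_counts(seq[:8])


def exhaustive_euler_paths(seq):
    """All orderings with the same dinucleotide multiset, start and end."""
    results = set()
    edges = list(zip(seq, seq[1:]))

    def rec(v, remaining, acc):
        if not remaining:
            results.add("".join(acc))
            return
        seen = set()
        for i, (a, b) in enumerate(remaining):
            if a != v or (a, b) in seen:
                continue
            seen.add((a, b))
            rec(b, remaining[:i] + remaining[i + 1 :], acc + [b])

    rec(seq[0], edges, [seq[0]])
    return results


def test_shuffle_distribution_matches_enumeration():
    from scipy.stats import chisquare

    seq = "ACGTAGCTAC"  # 10-mer with several valid Euler paths
    valid = exhaustive_euler_paths(seq)
    assert len(valid) > 1
    draws = dinucleotide_shuffle(seq, n_shuffles=10_000, seed=7)
    counts = {v: 0 for v in valid}
    for d in draws:
        assert d in valid
        counts[d] += 1
    stat, p = chisquare(list(counts.values()))
    assert p > 1e-3  # uniform over valid shuffles


# ---------------------------------------------------------------------------
# Training protocol


def test_split_integrity(small_trained_cnn):
    # holdout sites never appear in training: checked structurally by
    # train_model's masking; re-verify the mask here on a fresh call
    cfg = syn.SyntheticConfig(seed=41, n_sites=30, genome_length=200_000,
                              chrom_names=("chr1", "chr2"))
    genome, truth = syn.simulate_genome(cfg)
    chroms = truth.sites["chrom"].to_numpy()
    test_mask = np.isin(chroms, ["chr2"])
    assert test_mask.any() and not np.all(test_mask)
    assert not set(np.flatnonzero(test_mask)) & set(np.flatnonzero(~test_mask))


def test_constant_labels_predict_constant():
    cfg = syn.SyntheticConfig(seed=42, n_sites=200, genome_length=600_000,
                              chrom_names=("chr1", "chr2"))
    genome, truth = syn.simulate_genome(cfg)
    seqs = syn.site_sequences(genome, truth.sites)
    labels = np.zeros(len(seqs))
    spec = ModelSpec(max_epochs=8)
    model, report, _ = train_model(
        seqs, labels, truth.sites["chrom"], split=SplitSpec(holdout_chroms=("chr2",)),
        spec=spec, seed=0,
    )
    assert report.zero_label_variance
    assert report.test_mse < 0.01


def test_holdout_must_be_nonempty():
    with pytest.raises(ValueError, match="holdout"):
        train_model(["A" * 150], [0.0], ["chr1"], split=SplitSpec(holdout_chroms=("chrX",)))


def test_permuted_labels_have_no_test_signal():
    cfg = syn.SyntheticConfig(seed=43, n_sites=2000, genome_length=6_000_000,
                              chrom_names=("chr1", "chr2", "chr3", "chr4"))
    genome, truth = syn.simulate_genome(cfg)
    delta, _ = syn.simulate_binding_response(truth.sites, seed=43)
    rng = np.random.default_rng(99)
    permuted = rng.permutation(delta)
    seqs = syn.site_sequences(genome, truth.sites)
    spec = ModelSpec(max_epochs=5)
    model, report, test_mask = train_model(
        seqs, permuted, truth.sites["chrom"],
        split=SplitSpec(holdout_chroms=("chr4",)), spec=spec, seed=0,
    )
    assert test_mask.sum() >= 450
    assert abs(report.test_pearson_r) <= 0.1


# ---------------------------------------------------------------------------
# Attribution


class LinearStub:
    """Analytic linear model f(x) = sum(w * x[p0]) for attribution tests."""

    def __init__(self, p0=30, w=(1.0, -2.0, 0.5, 3.0)):
        self.spec = ModelSpec()
        self.trained = True
        self.p0 = p0
        self.w = np.asarray(w, dtype=np.float32)

    def predict(self, X, batch_size=256):
        X = np.asarray(X, dtype=np.float32)
        return X[:, self.p0, :] @ self.w

    def input_gradients(self, X, batch_size=256):
        X = np.asarray(X, dtype=np.float32)
        g = np.zeros_like(X)
        g[:, self.p0, :] = self.w
        return g


def test_constant_model_has_zero_attributions():
    model = CNNRegressor(seed=5)
    # zero the output layer: f(x) = bias, gradient identically zero
    model.out_layer.W[...] = 0.0
    model.out_layer.b[...] = 1.5
    model.trained = True
    seqs = ["ACGT" * 37 + "GG"]
    eg = attribute(model, seqs, n_references=5, seed=0)
    np.testing.assert_allclose(eg, 0.0, atol=1e-6)
    ism = _ism_attribution(model, seqs)
    np.testing.assert_allclose(ism, 0.0, atol=1e-6)


def test_linear_model_attribution_is_local():
    rng = np.random.default_rng(12)
    seq = "".join(rng.choice(list("ACGT"), size=150))
    stub = LinearStub(p0=30)
    eg = attribute(stub, [seq], n_references=20, seed=1)
    mass = np.abs(eg[0]).sum(axis=1)
    assert mass[30] > 0
    np.testing.assert_allclose(np.delete(mass, 30), 0.0, atol=1e-7)
    # for a linear model EG completeness is exact
    x = encode_batch([seq])
    refs = encode_batch(dinucleotide_shuffle(seq, 20, seed=1 + 1))
    gap = stub.predict(x)[0] - stub.predict(refs).mean()
    assert eg[0].sum() == pytest.approx(gap, abs=1e-5)


def test_attribution_requires_trained_model():
    model = CNNRegressor(seed=0)
    with pytest.raises(RuntimeError, match="untrained"):
        attribute(model, ["A" * 150])


def test_eg_matches_ism_on_trained_model(small_trained_cnn):
    model, report, test_seqs = small_trained_cnn
    sub = test_seqs[:10]
    eg = attribute(model, sub, n_references=50, seed=3)
    ism = _ism_attribution(model, sub)
    r = pearsonr(
        per_position_scores(eg, sub).ravel(),
        per_position_scores(ism, sub).ravel(),
    )[0]
    assert r >= 0.7


def test_cwm_of_single_sequence_scatters_its_profile():
    rng = np.random.default_rng(14)
    seq = "".join(rng.choice(list("ACGT"), size=150))
    tensors = rng.normal(size=(1, 150, 4))
    cwm = contribution_weight_matrix(tensors, [seq])
    for p, base in enumerate(seq):
        j = "ACGT".index(base)
        assert cwm[j, p] == tensors[0, p, j]
        for other in range(4):
            if other != j:
                assert np.isnan(cwm[other, p])


def test_all_zero_tensors_give_zero_cwm():
    seqs = ["ACGT" * 37 + "AA", "TTTT" * 37 + "CC"]
    cwm = contribution_weight_matrix(np.zeros((2, 150, 4)), seqs)
    observed = ~np.isnan(cwm)
    assert np.all(cwm[observed] == 0)
    assert cwm_mass_fraction(np.nan_to_num(cwm), [(0, 150)]) == 0.0


def test_m2_scan_flags_planted_and_rejects_background(small_genome):
    cfg, genome, truth = small_genome
    seqs = syn.site_sequences(genome, truth.sites)
    flags, offsets = m2_site_scan(seqs, syn.default_m2_pfm())
    has = truth.sites["has_m2"].to_numpy()
    assert ((flags == has).mean()) >= 0.95
    for f, o, h in zip(flags, offsets, has):
        if f and h:
            assert o == 21
    # background-only windows almost never fire
    rng = np.random.default_rng(15)
    bg = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(200)]
    bg_flags, _ = m2_site_scan(bg, syn.default_m2_pfm())
    assert bg_flags.mean() <= 0.01


def test_save_and_load_round_trip(tmp_path, small_trained_cnn):
    model, _, test_seqs = small_trained_cnn
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    x = encode_batch(test_seqs[:5])
    np.testing.assert_allclose(back.predict(x), model.predict(x), rtol=1e-6)
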