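"""O/E normalization, pileups, insulation statistics and TADs."""

import numpy as np
import pytest

from chromsites.hic_pileup import (
    ContactMatrix,
    PileupResult,
    build_tads,
    diamond_insulation,
    expected_by_distance,
    insulation_strength,
    observed_over_expected,
    pileup,
    pileup_ratio,
    read_contact_matrix,
    write_contact_matrix,
)
from chromsites import synthetic_data as syn


def toeplitz_matrix(n=100, resolution=10_000, exponent=-1.0):
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    m = (1.0 + d) ** exponent
    return ContactMatrix(chrom="chr1", resolution=resolution, matrix=m)


def test_self_expected_gives_all_ones():
    cm = toeplitz_matrix()
    oe = observed_over_expected(cm)
    np.testing.assert_allclose(oe.matrix, 1.0)
    assert oe.is_oe


def test_oe_is_idempotent_up_to_renormalization():
    # a structureless noiseless matrix: one O/E flattens it to all ones,
    # and a second O/E leaves it there
    cfg = syn.SyntheticConfig(seed=7, boundary_strength=1.0)
    cm, _ = syn.simulate_contact_matrix(cfg, noiseless=True)
    oe = observed_over_expected(cm)
    np.testing.assert_allclose(oe.matrix, 1.0)
    oe2 = observed_over_expected(oe)
    np.testing.assert_allclose(oe2.matrix, 1.0)
    # in general the second pass renormalizes each diagonal of the first
    cmp_, _ = syn.simulate_contact_matrix(syn.SyntheticConfig(seed=7))
    o1 = observed_over_expected(cmp_)
    o2 = observed_over_expected(o1)
    d1 = expected_by_distance(o1)
    n = o1.n_bins
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    manual = o1.matrix / d1[idx]
    finite = np.isfinite(o2.matrix) & np.isfinite(manual)
    np.testing.assert_allclose(o2.matrix[finite], manual[finite])


def test_oe_preserves_symmetry():
    cfg = syn.SyntheticConfig(seed=8)
    cm, _ = syn.simulate_contact_matrix(cfg)
    oe = observed_over_expected(cm)
    np.testing.assert_allclose(oe.matrix, oe.matrix.T, equal_nan=True)


def test_planted_blocks_polarize_oe():
    cfg = syn.SyntheticConfig(seed=9, boundary_strength=3.0)
    cm, truth = syn.simulate_contact_matrix(cfg, noiseless=True)
    oe = observed_over_expected(cm)  # empirical expected mixes blocks
    b = cfg.tad_boundaries[0]
    # within-TAD cell vs cross-boundary cell at the same distance
    assert oe.matrix[b - 5, b - 1] > oe.matrix[b - 2, b + 2]


def test_single_anchor_pileup_is_the_submatrix():
    cfg = syn.SyntheticConfig(seed=10)
    cm, truth = syn.simulate_contact_matrix(cfg)
    oe = observed_over_expected(cm)
    p = pileup(oe, [100], pad=50_000)
    size = 2 * (50_000 // cfg.hic_resolution) + 1
    np.testing.assert_allclose(p.window, oe.matrix[95:106, 95:106])
    assert p.window.shape == (size, size)


def test_pileup_flip_involution_and_skips():
    cfg = syn.SyntheticConfig(seed=11)
    cm, _ = syn.simulate_contact_matrix(cfg)
    oe = observed_over_expected(cm)
    anchors = [50, 100, 2]  # last anchor too close to the edge
    plus = pileup(oe, anchors, pad=300_000, anchor_strands=["+", "+", "+"])
    flipped_twice = pileup(oe, anchors, pad=300_000, anchor_strands=["+", "+", "+"])
    np.testing.assert_allclose(plus.window, flipped_twice.window)
    minus = pileup(oe, [50], pad=300_000, anchor_strands=["-"])
    fwd = pileup(oe, [50], pad=300_000, anchor_strands=["+"])
    np.testing.assert_allclose(minus.window, fwd.window[::-1, ::-1])
    assert plus.n_skipped == 1 and plus.n_anchors == 2


def test_uniform_window_insulation_is_one():
    p = PileupResult(window=np.ones((61, 61)), pad=300_000, resolution=10_000, n_anchors=1)
    assert insulation_strength(p) == pytest.approx(1.0)


@pytest.mark.parametrize("strength", [1.0, 1.5, 2.0, 4.0])
def test_noiseless_boundary_strength_recovered_exactly(strength):
    cfg = syn.SyntheticConfig(seed=12, boundary_strength=strength)
    cm, truth = syn.simulate_contact_matrix(cfg, noiseless=True)
    oe = observed_over_expected(cm, expected=truth.expected_decay)
    p = pileup(oe, list(cfg.tad_boundaries), pad=300_000)
    assert insulation_strength(p) == pytest.approx(strength, abs=1e-9)


def test_insulation_invariant_under_scaling():
    cfg = syn.SyntheticConfig(seed=13, boundary_strength=2.0)
    cm, truth = syn.simulate_contact_matrix(cfg, noiseless=True)
    oe = observed_over_expected(cm, expected=truth.expected_decay)
    p = pileup(oe, list(cfg.tad_boundaries), pad=300_000)
    scaled = PileupResult(window=p.window * 7.3, pad=p.pad,
                          resolution=p.resolution, n_anchors=p.n_anchors)
    assert insulation_strength(scaled) == pytest.approx(insulation_strength(p))


def test_pileup_ratio_identities():
    cfg = syn.SyntheticConfig(seed=14)
    cm, truth = syn.simulate_contact_matrix(cfg, noiseless=True)
    oe = observed_over_expected(cm, expected=truth.expected_decay)
    p = pileup(oe, list(cfg.tad_boundaries), pad=100_000)
    np.testing.assert_allclose(pileup_ratio(p, p), 1.0)
    doubled = PileupResult(window=p.window * 2, pad=p.pad,
                           resolution=p.resolution, n_anchors=p.n_anchors)
    np.testing.assert_allclose(pileup_ratio(doubled, p), 2.0)


def test_replicate_ratio_is_flat():
    # depth chosen so the far-diagonal Poisson noise of the averaged
    # pileup stays within the +/-0.1 log2 band (per-cell mean counts of
    # a few hundred at the window edge)
    cfg1 = syn.SyntheticConfig(seed=101, boundary_strength=2.0, hic_depth=200_000_000)
    cfg2 = syn.SyntheticConfig(seed=202, boundary_strength=2.0, hic_depth=200_000_000)
    piles = []
    for cfg in (cfg1, cfg2):
        cm, truth = syn.simulate_contact_matrix(cfg)
        oe = observed_over_expected(cm, expected=truth.expected_decay)
        piles.append(pileup(oe, list(cfg.tad_boundaries), pad=300_000))
    r = pileup_ratio(piles[0], piles[1])
    assert np.nanmax(np.abs(np.log2(r))) <= 0.1


def test_flat_matrix_has_flat_insulation():
    cm = toeplitz_matrix(n=120)
    track, bnd, _ = diamond_insulation(cm, window=100_000)
    finite = np.isfinite(track)
    np.testing.assert_allclose(track[finite], 0.0, atol=1e-9)


def test_planted_boundary_is_a_local_minimum():
    cfg = syn.SyntheticConfig(seed=15, boundary_strength=3.0)
    cm, _ = syn.simulate_contact_matrix(cfg)
    track, bnd, strengths = diamond_insulation(cm)
    for true_b in cfg.tad_boundaries:
        assert np.min(np.abs(bnd - true_b)) <= 1
        lo = max(true_b - 10, 0)
        hi = true_b + 10
        assert np.nanargmin(track[lo:hi]) + lo in range(true_b - 1, true_b + 2)


def brute_force_diamond(m, w):
    n = m.shape[0]
    out = np.full(n, np.nan)
    for b in range(n):
        if b - w < 0 or b + w >= n:
            continue
        vals = [m[i, j] for i in range(b - w, b) for j in range(b + 1, b + w + 1)]
        out[b] = float(np.mean(vals))
    return out


def test_diamond_matches_brute_force():
    cfg = syn.SyntheticConfig(seed=16, hic_n_bins=200, tad_boundaries=(60, 130))
    cm, _ = syn.simulate_contact_matrix(cfg)
    w = 100_000 // cfg.hic_resolution
    raw = brute_force_diamond(cm.matrix, w)
    track, _, _ = diamond_insulation(cm, window=100_000)
    finite = np.isfinite(raw) & (raw > 0)
    np.testing.assert_allclose(
        track[finite], np.log2(raw[finite] / raw[finite].mean()), atol=1e-9
    )


def test_tad_construction_rules():
    res = 10_000
    # boundaries at 0, 1 Mb, 3 Mb -> keep [0, 1 Mb], drop the 2 Mb TAD
    tads = build_tads([0, 100, 300], resolution=res)
    assert tads == [(0, 100)]
    assert build_tads([40], resolution=res) == []
    b = [0, 30, 60, 90]
    assert len(build_tads(b, resolution=res)) == 3


def test_matrix_round_trip(tmp_path):
    cfg = syn.SyntheticConfig(seed=17, hic_n_bins=80, tad_boundaries=(25, 50))
    cm, _ = syn.simulate_contact_matrix(cfg)
    write_contact_matrix(cm, tmp_path / "bins.tsv", tmp_path / "trip.tsv")
    back = read_contact_matrix(tmp_path / "bins.tsv", tmp_path / "trip.tsv")
    assert back.resolution == cm.resolution and back.chrom == cm.chrom
    np.testing.assert_allclose(back.matrix, cm.matrix)
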