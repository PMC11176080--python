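"""Fragment I/O, anchored profiles and the profile normalizations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromsites.core_signal import (
    FragmentTable,
    GenomicInterval,
    anchored_profile,
    count_in_windows,
    downsample_to_min,
    normalize_profile,
    read_fragments,
    smooth_running_mean,
    write_fragments,
)


def make_table(rows, label="s"):
    rec = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return FragmentTable(rec, sample_label=label)


# ---------------------------------------------------------------------------
# I/O


def test_read_bed_fragments(tmp_path):
    p = tmp_path / "frags.bed"
    p.write_text("chr1\t10\t60\nchr1\t100\t148\t.\t0\t-\nchr2\t5\t25\n")
    t = read_fragments(p)
    assert len(t.records) == 3
    assert t.library_size == 3
    assert list(t.records["strand"]) == [".", "-", "."]


def test_read_bed_rejects_inverted_interval_with_line_number(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t10\t60\nchr1\t100\t90\n")
    with pytest.raises(ValueError, match="line 2"):
        read_fragments(p)


def test_fragment_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    starts = rng.integers(0, 10_000, size=50)
    rows = [
        ("chr%d" % rng.integers(1, 3), s, s + int(rng.integers(20, 300)),
         "+" if rng.random() < 0.5 else "-")
        for s in starts
    ]
    t = make_table(rows)
    p = tmp_path / "rt.bed"
    write_fragments(t, p)
    back = read_fragments(p)
    pd.testing.assert_frame_equal(
        t.records.astype({"start": np.int64, "end": np.int64}),
        back.records.astype({"start": np.int64, "end": np.int64}),
    )


def test_read_sam_collapses_proper_pairs(tmp_path):
    sam = tmp_path / "pairs.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "r1\t99\tchr1\t101\t60\t50M\t=\t201\t150\t" + "A" * 50 + "\t*\n"
        "r1\t147\tchr1\t201\t60\t50M\t=\t101\t-150\t" + "A" * 50 + "\t*\n"
    )
    t = read_fragments(sam, format="bam")
    assert len(t.records) == 1
    row = t.records.iloc[0]
    assert (row.start, row.end) == (100, 250)  # 1-based SAM -> 0-based half-open


# ---------------------------------------------------------------------------
# Anchored profiles


def test_midpoint_alignment_identity():
    # fragment [100,148): midpoint 124; anchor centered at 124
    t = make_table([("chr1", 100, 148, "+")])
    anchor = GenomicInterval("chr1", 124, 125, "+")
    prof = anchored_profile(t, [anchor], window=200)
    assert prof.values.sum() == 1
    assert prof.values[0, np.flatnonzero(prof.positions == 0)[0]] == 1


def test_midpoint_center_fixed_under_strand_flip():
    t = make_table([("chr1", 100, 148, "+")])
    minus = GenomicInterval("chr1", 124, 125, "-")
    prof = anchored_profile(t, [minus], window=200)
    assert prof.values[0, np.flatnonzero(prof.positions == 0)[0]] == 1


def brute_force_profile(table, anchors, window, mode):
    """Independent per-site counter used as the orientation oracle."""
    half = window // 2
    out = np.zeros((len(anchors), window))
    for ai, anchor in enumerate(anchors):
        center = anchor.start + (anchor.end - anchor.start) // 2
        for row in table.records.itertuples():
            if row.chrom != anchor.chrom:
                continue
            if mode == "midpoint":
                points = [row.start + (row.end - row.start) // 2]
            elif mode == "five_prime":
                points = [row.end - 1 if row.strand == "-" else row.start]
            else:
                points = range(row.start, row.end)
            for pos in points:
                rel = center - pos if anchor.strand == "-" else pos - center
                if -half <= rel < half:
                    out[ai, rel + half] += 1
    return out


@pytest.mark.parametrize("mode", ["midpoint", "five_prime", "full_cover"])
def test_profile_matches_brute_force(mode):
    rng = np.random.default_rng(42)
    for trial in range(10):
        rows = []
        for _ in range(rng.integers(5, 50)):
            s = int(rng.integers(0, 3000))
            rows.append(
                ("chr1", s, s + int(rng.integers(1, 300)),
                 "+" if rng.random() < 0.5 else "-")
            )
        t = make_table(rows)
        anchors = []
        for _ in range(int(rng.integers(1, 5))):
            a_start = int(rng.integers(500, 2500))
            anchors.append(
                GenomicInterval(
                    "chr1", a_start, a_start + 19, "+" if rng.random() < 0.5 else "-"
                )
            )
        prof = anchored_profile(t, anchors, window=200, mode=mode)
        expected = brute_force_profile(t, anchors, 200, mode)
        np.testing.assert_array_equal(prof.values, expected)


def test_flip_involution():
    rng = np.random.default_rng(7)
    rows = [("chr1", int(s), int(s) + 40, "+") for s in rng.integers(0, 2000, 30)]
    t = make_table(rows)
    plus = [GenomicInterval("chr1", 1000, 1019, "+")]
    flipped_twice = [GenomicInterval("chr1", 1000, 1019, "+")]
    p1 = anchored_profile(t, plus, window=400)
    p2 = anchored_profile(t, flipped_twice, window=400)
    np.testing.assert_array_equal(p1.values, p2.values)
    # and a single flip reverses the position axis of a symmetric query
    minus = [GenomicInterval("chr1", 1000, 1019, "-")]
    pm = anchored_profile(t, minus, window=400)
    center = 1000 + 9
    # midpoint at rel r on + strand appears at -r on - strand
    mids = (np.array([r[1] for r in rows]) + 20)
    for r_plus, v in zip(p1.positions, p1.values[0]):
        if v:
            r_minus = -r_plus
            if -200 <= r_minus < 200:
                assert pm.values[0, r_minus + 200] == v


def test_count_conservation_disjoint_anchors():
    rng = np.random.default_rng(3)
    rows = [("chr1", int(s), int(s) + 50, "+") for s in rng.integers(0, 10_000, 200)]
    t = make_table(rows)
    anchors = [GenomicInterval("chr1", c, c + 1, "+") for c in (1000, 3000, 5000)]
    prof = anchored_profile(t, anchors, window=1000)
    mids = t.midpoints()["pos"].to_numpy()
    n_in = sum(
        ((mids >= a.center - 500) & (mids < a.center + 500)).sum() for a in anchors
    )
    assert prof.values.sum() == n_in


def test_edge_anchor_skipped_and_counted():
    t = make_table([("chr1", 100, 150, "+")])
    anchors = [GenomicInterval("chr1", 50, 51, "+"), GenomicInterval("chr1", 5000, 5001, "+")]
    prof = anchored_profile(t, anchors, window=2000, chrom_sizes={"chr1": 10_000})
    assert prof.skipped_sites == 1
    assert len(prof.site_ids) == 1


# ---------------------------------------------------------------------------
# Smoothing


def test_smoothing_preserves_constants():
    x = np.full(100, 3.7)
    for w in (1, 21, 51):
        np.testing.assert_allclose(smooth_running_mean(x, w), x)


def test_smoothing_impulse_response():
    x = np.zeros(101)
    x[50] = 1.0
    s = smooth_running_mean(x, 21)
    np.testing.assert_allclose(s[40:61], np.full(21, 1 / 21))
    assert s[39] == 0 and s[61] == 0


def test_smoothing_rejects_even_window():
    with pytest.raises(ValueError, match="odd"):
        smooth_running_mean(np.arange(10.0), 4)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=5, max_size=80))
def test_smoothing_matches_brute_force(values):
    x = np.array(values)
    w = 51
    got = smooth_running_mean(x, w)
    expected = np.array(
        [x[max(0, i - 25): i + 26].mean() for i in range(len(x))]
    )
    np.testing.assert_allclose(got, expected, atol=1e-9)


# ---------------------------------------------------------------------------
# Normalization


def _profile_of(values):
    from chromsites.core_signal import SignalProfileMatrix

    values = np.asarray(values, dtype=float)
    return SignalProfileMatrix(
        site_ids=list(range(values.shape[0])),
        positions=np.arange(values.shape[1]),
        values=values,
    )


def test_mnase_median_single_sample_identity():
    p = _profile_of(np.random.default_rng(1).random((4, 50)) + 0.5)
    out = normalize_profile(p, "mnase_median")
    np.testing.assert_allclose(out.values, p.values)


def test_atac_x100_exact():
    p = _profile_of([[2.0, 4.0, 0.0]])
    out = normalize_profile(p, "atac_x100", library_sizes=200)
    np.testing.assert_allclose(out.values, [[1.0, 2.0, 0.0]])


def test_mnase_median_two_samples_share_median():
    rng = np.random.default_rng(5)
    a = _profile_of(rng.random((3, 101)) + 1.0)
    b = _profile_of(rng.random((3, 101)) * 3 + 2.0)
    out_a, out_b = normalize_profile([a, b], "mnase_median")
    m_a = np.median(out_a.mean_profile())
    m_b = np.median(out_b.mean_profile())
    np.testing.assert_allclose(m_a, m_b)
    expect = np.median(
        [np.median(a.mean_profile()), np.median(b.mean_profile())]
    )
    np.testing.assert_allclose(m_a, expect)


def test_mnase_median_rejects_zero_median():
    p = _profile_of(np.zeros((2, 11)))
    with pytest.raises(ValueError, match="median"):
        normalize_profile(p, "mnase_median")


# ---------------------------------------------------------------------------
# Window counting and downsampling


def test_pseudocount_floor_no_fragments():
    t = make_table([("chr9", 0, 10, "+")])  # fragments elsewhere
    ivs = [GenomicInterval("chr1", 1000, 1001)]
    vals = count_in_windows(t, ivs, width=250, pseudo_log=True)
    np.testing.assert_allclose(vals, [3.0])  # log2(8)


def test_identical_sample_and_control_null_enrichment():
    rng = np.random.default_rng(2)
    rows = [("chr1", int(s), int(s) + 100, "+") for s in rng.integers(0, 5000, 100)]
    t = make_table(rows)
    ivs = [GenomicInterval("chr1", c, c + 1) for c in (500, 2500, 4500)]
    a = count_in_windows(t, ivs, pseudo_log=True, median_library_size=100)
    b = count_in_windows(t, ivs, pseudo_log=True, median_library_size=100)
    np.testing.assert_allclose(a - b, 0.0)


def test_manual_window_tally():
    # five fragments, two 250-bp windows centered at 200 and 1000
    t = make_table(
        [
            ("chr1", 100, 200, "+"),   # midpoint 150 -> window 1
            ("chr1", 180, 260, "+"),   # midpoint 220 -> window 1
            ("chr1", 300, 340, "+"),   # midpoint 320 -> window 1 edge: [75,325) yes
            ("chr1", 900, 1000, "+"),  # midpoint 950 -> window 2
            ("chr1", 2000, 2100, "+"), # midpoint 2050 -> none
        ]
    )
    ivs = [GenomicInterval("chr1", 200, 201), GenomicInterval("chr1", 1000, 1001)]
    vals = count_in_windows(t, ivs, width=250, pseudo_log=False)
    np.testing.assert_array_equal(vals, [3, 1])


def test_downsample_noop_when_equal():
    rng = np.random.default_rng(0)
    rows = [("chr1", int(s), int(s) + 10, "+") for s in rng.integers(0, 100, 10)]
    a, b = make_table(rows, "a"), make_table(rows, "b")
    out = downsample_to_min([a, b], seed=1)
    assert [t.library_size for t in out] == [10, 10]
    pd.testing.assert_frame_equal(out[0].records, a.records)


def test_downsample_to_smallest_and_deterministic():
    rng = np.random.default_rng(0)
    rows_big = [("chr1", int(s), int(s) + 10, "+") for s in rng.integers(0, 1000, 100)]
    rows_small = rows_big[:40]
    a, b = make_table(rows_big, "a"), make_table(rows_small, "b")
    out1 = downsample_to_min([a, b], seed=7)
    out2 = downsample_to_min([a, b], seed=7)
    assert [t.library_size for t in out1] == [40, 40]
    pd.testing.assert_frame_equal(out1[0].records, out2[0].records)
    # subsample is a subset of the original
    orig = set(map(tuple, a.records.to_numpy()))
    assert all(tuple(r) in orig for r in out1[0].records.to_numpy())
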