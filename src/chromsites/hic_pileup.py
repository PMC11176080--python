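"""Hi-C observed/expected normalization, anchored pileups, insulation
statistics and TAD interval construction.

Matrices are dense, symmetric, single-chromosome and binned at a fixed
resolution (10 kb by default).  The quadrant insulation strength of a
pileup window is the mean of the two same-side quadrants (upper-left,
lower-right: contacts not crossing the central bin) over the mean of the
two crossing quadrants (upper-right, lower-left), ignoring cells within
the first two diagonals of the main diagonal where ligation artifacts
dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact matrix."""

    chrom: str
    resolution: int
    matrix: np.ndarray  # (n_bins, n_bins), NaN = missing
    weights: np.ndarray | None = None  # balancing weights, positive where defined
    is_oe: bool = False
    start: int = 0  # genomic coordinate of bin 0

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.weights is not None and np.any(
            self.weights[np.isfinite(self.weights)] <= 0
        ):
            raise ValueError("balancing weights must be positive where defined")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def balanced(self) -> np.ndarray:
        if self.weights is None:
            return self.matrix.astype(float)
        w = self.weights
        return self.matrix * np.outer(w, w)


@dataclass
class PileupResult:
    window: np.ndarray  # (2*pad_bins+1)^2 average O/E window
    pad: int  # bp
    resolution: int
    n_anchors: int
    n_skipped: int = 0
    counts: np.ndarray | None = None  # per-cell contributing anchors


# ---------------------------------------------------------------------------
# I/O: bin table + upper-triangle triplet text


def write_contact_matrix(cm: ContactMatrix, bins_path, triplets_path) -> None:
    n = cm.n_bins
    starts = cm.start + np.arange(n) * cm.resolution
    pd.DataFrame(
        {"chrom": cm.chrom, "start": starts, "end": starts + cm.resolution}
    ).to_csv(bins_path, sep="\t", index=False)
    iu = np.triu_indices(n)
    vals = cm.matrix[iu]
    keep = np.isfinite(vals) & (vals != 0)
    pd.DataFrame(
        {"bin1": iu[0][keep], "bin2": iu[1][keep], "count": vals[keep]}
    ).to_csv(triplets_path, sep="\t", index=False)


def read_contact_matrix(bins_path, triplets_path) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t")
    trip = pd.read_csv(triplets_path, sep="\t")
    n = len(bins)
    chrom = str(bins["chrom"].iloc[0])
    resolution = int(bins["end"].iloc[0] - bins["start"].iloc[0])
    m = np.zeros((n, n))
    i = trip["bin1"].to_numpy(int)
    j = trip["bin2"].to_numpy(int)
    v = trip["count"].to_numpy(float)
    m[i, j] = v
    m[j, i] = v
    return ContactMatrix(
        chrom=chrom, resolution=resolution, matrix=m, start=int(bins["start"].iloc[0])
    )


# ---------------------------------------------------------------------------
# Observed / expected


def expected_by_distance(cm: ContactMatrix) -> np.ndarray:
    """Mean finite balanced value on each diagonal d = 0..n-1."""
    m = cm.balanced()
    n = cm.n_bins
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(m, offset=d)
        finite = np.isfinite(diag)
        if finite.any():
            exp[d] = diag[finite].mean()
    return exp


def observed_over_expected(
    cm: ContactMatrix, expected: np.ndarray | None = None
) -> ContactMatrix:
    """Divide each cell by the expected value at its genomic distance.

    ``expected`` defaults to the empirical per-diagonal mean; a known
    analytic decay (e.g. a simulation's generating law) may be supplied
    instead.  Zero or missing expected values propagate missing cells.
    """
    if expected is None:
        expected = expected_by_distance(cm)
    n = cm.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    exp_mat = np.asarray(expected, dtype=float)[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = cm.balanced() / exp_mat
    oe[~np.isfinite(oe)] = np.nan
    return replace(cm, matrix=oe, weights=None, is_oe=True)


# ---------------------------------------------------------------------------
# Pileups


def pileup(
    cm: ContactMatrix,
    anchors,
    pad: int = 300_000,
    anchor_strands=None,
) -> PileupResult:
    """Average O/E submatrices centered on anchor bins.

    ``anchors`` are bin indices (local pileup) or (bin_i, bin_j) pairs
    (distal pileup over anchor-pair rectangles).  Minus-strand local
    anchors are flipped (both axes reversed) before averaging so motif
    orientation is consistent.  Anchors within ``pad`` of the chromosome
    edge are skipped and counted.  Missing cells are excluded per cell,
    with the per-cell contributing counts retained.
    """
    if pad % cm.resolution != 0:
        raise ValueError("pad must be a multiple of the resolution")
    p = pad // cm.resolution
    size = 2 * p + 1
    total = np.zeros((size, size))
    counts = np.zeros((size, size))
    n_used = 0
    n_skipped = 0
    n = cm.n_bins
    m = cm.matrix
    for k, anchor in enumerate(anchors):
        if np.isscalar(anchor) or isinstance(anchor, (int, np.integer)):
            bi = bj = int(anchor)
        else:
            bi, bj = int(anchor[0]), int(anchor[1])
        if bi - p < 0 or bi + p >= n or bj - p < 0 or bj + p >= n:
            n_skipped += 1
            continue
        sub = m[bi - p : bi + p + 1, bj - p : bj + p + 1]
        if anchor_strands is not None and anchor_strands[k] == "-":
            sub = sub[::-1, ::-1]
        finite = np.isfinite(sub)
        total[finite] += sub[finite]
        counts += finite
        n_used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        window = total / counts
    window[counts == 0] = np.nan
    return PileupResult(
        window=window,
        pad=pad,
        resolution=cm.resolution,
        n_anchors=n_used,
        n_skipped=n_skipped,
        counts=counts,
    )


def insulation_strength(pile: PileupResult, ignore_diags: int = 2) -> float:
    """Quadrant ratio: mean(UL, LR) / mean(UR, LL), central row/column
    excluded, cells within ``ignore_diags`` of the main diagonal masked."""
    w = pile.window
    size = w.shape[0]
    if w.shape[0] != w.shape[1] or size % 2 == 0:
        raise ValueError("pileup window must be square with odd size")
    c = size // 2
    idx = np.arange(size)
    dist = np.abs(np.subtract.outer(idx, idx))
    mask = dist >= ignore_diags
    rows = idx[:, None] * np.ones(size, dtype=int)
    cols = np.ones((size, 1), dtype=int) * idx
    ul = (rows < c) & (cols < c)
    lr = (rows > c) & (cols > c)
    ur = (rows < c) & (cols > c)
    ll = (rows > c) & (cols < c)
    same = (ul | lr) & mask & np.isfinite(w)
    cross = (ur | ll) & mask & np.isfinite(w)
    if not same.any() or not cross.any():
        raise ValueError("empty quadrant after masking")
    return float(w[same].mean() / w[cross].mean())


def pileup_ratio(a: PileupResult, b: PileupResult) -> np.ndarray:
    """Elementwise ratio of two pileup windows, missing values propagating."""
    if a.window.shape != b.window.shape:
        raise ValueError("pileup windows have different shapes")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = a.window / b.window
    r[~np.isfinite(r)] = np.nan
    return r


# ---------------------------------------------------------------------------
# Diamond insulation and TADs


def diamond_insulation(
    cm: ContactMatrix, window: int = 100_000, boundary_prominence: float | None = None
):
    """Per-bin diamond insulation track and boundary candidates.

    For bin b the insulation is the mean balanced contact value over the
    (window/res)^2 cells linking the ``w`` bins upstream of b to the
    ``w`` bins downstream.  The track is reported as log2(value / chromosome
    mean).  Local minima are boundary candidates; each carries a boundary
    strength (prominence of the minimum on the log2 track).  When
    ``boundary_prominence`` is None, a threshold is chosen by Li's
    iterative histogram method over the candidate strengths.

    Returns (track, boundaries, strengths): track is per-bin log2 values
    with NaN within ``window`` of the edges.
    """
    if window % cm.resolution != 0:
        raise ValueError("window must be a multiple of the resolution")
    w = window // cm.resolution
    m = cm.balanced()
    n = cm.n_bins
    raw = np.full(n, np.nan)
    for b in range(w, n - w):
        sub = m[b - w : b, b + 1 : b + w + 1]
        finite = np.isfinite(sub)
        if finite.any():
            raw[b] = sub[finite].mean()
    finite = np.isfinite(raw) & (raw > 0)
    if not finite.any():
        warnings.warn("insulation track is empty")
        return raw, np.array([], dtype=int), np.array([])
    track = np.full(n, np.nan)
    track[finite] = np.log2(raw[finite] / raw[finite].mean())

    from scipy.signal import find_peaks

    filled = np.where(np.isfinite(track), track, np.nanmax(track))
    minima, props = find_peaks(-filled, prominence=0.0)
    strengths = props["prominences"]
    if len(minima) == 0:
        return track, minima, strengths
    thr = boundary_prominence if boundary_prominence is not None else _li_threshold(strengths)
    keep = strengths >= thr
    return track, minima[keep], strengths[keep]


def _li_threshold(values: np.ndarray) -> float:
    """Li's iterative minimum cross-entropy threshold on a 1D sample."""
    v = values[np.isfinite(values)]
    if len(v) == 0:
        return 0.0
    v = v[v > 0]
    if len(v) == 0:
        return 0.0
    t = v.mean()
    for _ in range(100):
        lo = v[v <= t]
        hi = v[v > t]
        if len(lo) == 0 or len(hi) == 0:
            break
        m0, m1 = lo.mean(), hi.mean()
        if m0 <= 0:
            m0 = np.nextafter(0, 1)
        new_t = (m1 - m0) / (np.log(m1) - np.log(m0))
        if abs(new_t - t) < 1e-9:
            t = new_t
            break
        t = new_t
    return float(t)


def build_tads(
    boundaries, resolution: int, max_length: int = 1_500_000
) -> list[tuple[int, int]]:
    """Combine neighboring boundary bins into candidate TAD intervals,
    dropping intervals longer than ``max_length``; returns bin ranges."""
    b = sorted(int(x) for x in boundaries)
    tads = []
    for lo, hi in zip(b, b[1:]):
        if (hi - lo) * resolution <= max_length:
            tads.append((lo, hi))
    return tads


def write_insulation_bedgraph(cm: ContactMatrix, track: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track):
            if not np.isfinite(v):
                continue
            s = cm.start + i * cm.resolution
            fh.write(f"{cm.chrom}\t{s}\t{s + cm.resolution}\t{v:.6g}\n")
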