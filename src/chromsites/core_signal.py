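"""Coordinate types, fragment I/O and motif-anchored signal profiles.

All coordinates are 0-based half-open (BED native); 1-based formats are
converted at the I/O boundary.  The midpoint of a fragment ``[start, end)``
is ``start + (end - start) // 2`` — for even lengths this is the
right-of-center base, a convention that is documented here and frozen in
the tests.

An anchored profile is the sites x positions matrix of signal in a window
centered on an oriented anchor (typically a transcription-factor motif).
Minus-strand anchors have their position axis reversed so that +x always
points 3' of the motif.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """Strand-aware 0-based half-open genomic region."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentTable:
    """Aligned sequencing fragments for one sample.

    ``records`` holds columns chrom, start, end, strand; ``library_size``
    always equals the number of records and is the N used in depth
    normalizations.
    """

    records: pd.DataFrame
    sample_label: str = ""

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        rec = self.records
        bad = rec["end"] <= rec["start"]
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"fragment with end <= start at row {idx}")

    @property
    def library_size(self) -> int:
        return len(self.records)

    def midpoints(self) -> pd.DataFrame:
        """Per-fragment midpoint positions (right-of-center for even lengths)."""
        rec = self.records
        mid = rec["start"] + (rec["end"] - rec["start"]) // 2
        return pd.DataFrame(
            {"chrom": rec["chrom"], "pos": mid, "strand": rec["strand"]}
        )

    def five_prime_ends(self) -> pd.DataFrame:
        rec = self.records
        pos = np.where(rec["strand"].to_numpy() == "-", rec["end"] - 1, rec["start"])
        return pd.DataFrame(
            {"chrom": rec["chrom"], "pos": pos, "strand": rec["strand"]}
        )


@dataclass
class SignalProfileMatrix:
    """Sites x positions matrix of anchored, oriented signal."""

    site_ids: list
    positions: np.ndarray  # relative bp, + is 3' of the motif
    values: np.ndarray  # (n_sites, n_positions)
    normalization: str = "raw"
    smoothing_window: int = 0
    skipped_sites: int = 0

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0) if len(self.values) else np.zeros(0)


# ---------------------------------------------------------------------------
# I/O


def read_fragments(path, format: str = "bed_tsv", sample_label: str = "") -> FragmentTable:
    """Read aligned fragments from a BED-like TSV or a SAM/BAM file.

    BED input needs at least chrom/start/end; a 6th column supplies strand
    (default '.').  SAM/BAM input collapses each properly paired read pair
    to a single fragment (leftmost mate start to rightmost mate end).
    Malformed BED lines raise with their line number.
    """
    if format == "bed_tsv":
        return _read_fragments_bed(path, sample_label)
    if format == "bam":
        return _read_fragments_bam(path, sample_label)
    raise ValueError(f"unknown fragment format {format!r}")


def _read_fragments_bed(path, sample_label: str) -> FragmentTable:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from err
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            strand = parts[5] if len(parts) >= 6 and parts[5] in STRANDS else "."
            rows.append((parts[0], start, end, strand))
    if not rows:
        warnings.warn(f"{path}: empty fragment file")
        rec = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        return FragmentTable(rec, sample_label=sample_label)
    rec = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return FragmentTable(rec, sample_label=sample_label)


def _read_fragments_bam(path, sample_label: str) -> FragmentTable:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path)) as af:
        for read in af:
            # one fragment per proper pair, taken from the leftmost mate
            if not read.is_proper_pair or read.is_unmapped:
                continue
            if read.template_length <= 0:
                continue
            start = read.reference_start
            end = start + read.template_length
            strand = "-" if read.is_reverse else "+"
            rows.append((read.reference_name, start, end, strand))
    rec = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return FragmentTable(rec, sample_label=sample_label)


def write_fragments(table: FragmentTable, path) -> None:
    table.records[["chrom", "start", "end", "strand"]].assign(
        name=".", score=0
    )[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            p = line.split("\t")
            strand = p[5] if len(p) >= 6 else "."
            out.append(GenomicInterval(p[0], int(p[1]), int(p[2]), strand))
    return out


def write_bed(intervals, path, names=None, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def write_bedgraph(chrom: str, start: int, values, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            fh.write(f"{chrom}\t{start + i}\t{start + i + 1}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Profiles


def _anchor_center(anchor: GenomicInterval) -> int:
    return anchor.center


def anchored_profile(
    fragments: FragmentTable,
    anchors,
    window: int = 2000,
    mode: str = "midpoint",
    chrom_sizes: dict | None = None,
) -> SignalProfileMatrix:
    """Per-anchor signal in a ``window`` bp window centered on each anchor.

    mode='midpoint' counts each fragment once at its midpoint,
    'five_prime' at its strand-aware 5' end, 'full_cover' increments every
    covered position.  A window of 2000 spans relative positions
    -1000..+999 around the anchor center; minus-strand anchors are flipped
    so +x is 3' of the motif.  Anchors whose window exceeds the chromosome
    bounds (when ``chrom_sizes`` is given) are dropped and counted in
    ``skipped_sites``.
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    positions = np.arange(-half, half)

    if mode == "midpoint":
        pts = fragments.midpoints()
    elif mode == "five_prime":
        pts = fragments.five_prime_ends()
    elif mode == "full_cover":
        pts = None
    else:
        raise ValueError(f"unknown profile mode {mode!r}")

    if pts is not None:
        by_chrom = {
            chrom: np.sort(sub["pos"].to_numpy())
            for chrom, sub in pts.groupby("chrom", sort=False)
        }
    else:
        by_chrom = {
            chrom: (np.sort(sub["start"].to_numpy()), sub.sort_values("start"))
            for chrom, sub in fragments.records.groupby("chrom", sort=False)
        }

    rows = []
    kept_ids = []
    skipped = 0
    for sid, anchor in enumerate(anchors):
        center = _anchor_center(anchor)
        lo, hi = center - half, center + half
        if chrom_sizes is not None:
            size = chrom_sizes.get(anchor.chrom)
            if size is None or lo < 0 or hi > size:
                skipped += 1
                continue
        row = np.zeros(window)
        if pts is not None:
            arr = by_chrom.get(anchor.chrom)
            if arr is not None and len(arr):
                # flip: rel = pos - center (+), center - pos (-)
                if anchor.strand == "-":
                    sel_lo, sel_hi = center - half + 1, center + half + 1
                else:
                    sel_lo, sel_hi = lo, hi
                i0 = np.searchsorted(arr, sel_lo, side="left")
                i1 = np.searchsorted(arr, sel_hi, side="left")
                pos = arr[i0:i1]
                rel = (center - pos) if anchor.strand == "-" else (pos - center)
                np.add.at(row, rel + half, 1.0)
        else:
            chrom_data = by_chrom.get(anchor.chrom)
            if chrom_data is not None:
                _, sub = chrom_data
                starts = sub["start"].to_numpy()
                ends = sub["end"].to_numpy()
                span_lo = center - half if anchor.strand != "-" else center - half + 1
                span_hi = span_lo + window
                s = np.clip(starts, span_lo, span_hi)
                e = np.clip(ends, span_lo, span_hi)
                diff = np.zeros(window + 1)
                ok = e > s
                np.add.at(diff, s[ok] - span_lo, 1.0)
                np.add.at(diff, e[ok] - span_lo, -1.0)
                cov = np.cumsum(diff[:-1])
                row = cov[::-1].copy() if anchor.strand == "-" else cov
        rows.append(row)
        kept_ids.append(sid)

    values = np.array(rows) if rows else np.zeros((0, window))
    return SignalProfileMatrix(
        site_ids=kept_ids,
        positions=positions,
        values=values,
        normalization="raw",
        skipped_sites=skipped,
    )


def smooth_running_mean(values: np.ndarray, w: int) -> np.ndarray:
    """Centered running mean of odd width ``w``; edge windows are truncated."""
    if w < 1 or w % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        half = w // 2
        n = len(values)
        csum = np.concatenate([[0.0], np.cumsum(values)])
        lo = np.clip(np.arange(n) - half, 0, n)
        hi = np.clip(np.arange(n) + half + 1, 0, n)
        return (csum[hi] - csum[lo]) / (hi - lo)
    return np.apply_along_axis(smooth_running_mean, -1, values, w)


def smooth_profile(profile: SignalProfileMatrix, w: int) -> SignalProfileMatrix:
    return replace(
        profile, values=smooth_running_mean(profile.values, w), smoothing_window=w
    )


def normalize_profile(
    profiles,
    scheme: str,
    library_sizes=None,
):
    """Apply one of the study's three profile normalizations.

    atac_x100:           counts / library size * 100 (per sample)
    chip_per_site_x1000: counts / library size / n_sites * 1000
    mnase_median:        each sample's profile divided by its own median,
                         then all samples multiplied by the median of the
                         per-sample medians (co-normalization; pass all
                         samples together)

    ``profiles`` is a single SignalProfileMatrix for the first two schemes
    or a list for mnase_median; returns the same shape of object(s).
    """
    if scheme == "mnase_median":
        if not isinstance(profiles, (list, tuple)):
            profiles = [profiles]
        medians = []
        for p in profiles:
            m = float(np.median(p.mean_profile()))
            if m == 0:
                raise ValueError("mnase_median: degenerate profile with median 0")
            medians.append(m)
        grand = float(np.median(medians))
        out = [
            replace(p, values=p.values / m * grand, normalization="mnase_median")
            for p, m in zip(profiles, medians)
        ]
        return out if len(out) > 1 else out[0]

    if scheme == "atac_x100":
        if library_sizes is None:
            raise ValueError("atac_x100 requires library_sizes")
        n = float(library_sizes)
        return replace(
            profiles, values=profiles.values / n * 100.0, normalization="atac_x100"
        )

    if scheme == "chip_per_site_x1000":
        if library_sizes is None:
            raise ValueError("chip_per_site_x1000 requires library_sizes")
        n = float(library_sizes)
        n_sites = max(len(profiles.site_ids), 1)
        return replace(
            profiles,
            values=profiles.values / n / n_sites * 1000.0,
            normalization="chip_per_site_x1000",
        )

    raise ValueError(f"unknown normalization scheme {scheme!r}")


def count_in_windows(
    fragments: FragmentTable,
    intervals,
    width: int = 250,
    shift_half_insert: bool = True,
    pseudo_log: bool = False,
    median_library_size: float | None = None,
    pseudocount: float = 8.0,
) -> np.ndarray:
    """Fragment counts in fixed-width windows centered on each interval.

    With ``shift_half_insert`` each fragment is counted once at its
    midpoint (the half-insert shift); otherwise at its 5' end.  With
    ``pseudo_log`` returns log2(n_norm + pseudocount) where n_norm is the
    count scaled to ``median_library_size`` (the median across co-analyzed
    samples; defaults to this sample's own size).  Enrichment over a
    control is the difference of two pseudo_log values.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    pts = fragments.midpoints() if shift_half_insert else fragments.five_prime_ends()
    by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in pts.groupby("chrom", sort=False)
    }
    half = width // 2
    counts = np.zeros(len(intervals))
    for i, iv in enumerate(intervals):
        arr = by_chrom.get(iv.chrom)
        if arr is None:
            continue
        center = iv.center
        lo = center - half
        hi = lo + width
        counts[i] = np.searchsorted(arr, hi, side="left") - np.searchsorted(
            arr, lo, side="left"
        )
    if not pseudo_log:
        return counts
    n = fragments.library_size
    med = float(median_library_size) if median_library_size is not None else float(n)
    scale = med / n if n > 0 else 0.0
    return np.log2(counts * scale + pseudocount)


def downsample_to_min(samples, seed: int):
    """Subsample every table, without replacement, to the smallest library."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to co-downsample")
    sizes = [s.library_size for s in samples]
    if min(sizes) == 0:
        raise ValueError("cannot downsample: a sample is empty")
    target = min(sizes)
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        if s.library_size == target:
            out.append(FragmentTable(s.records.copy(), sample_label=s.sample_label))
        else:
            idx = np.sort(rng.choice(s.library_size, size=target, replace=False))
            out.append(
                FragmentTable(
                    s.records.iloc[idx].reset_index(drop=True),
                    sample_label=s.sample_label,
                )
            )
    return out
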