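"""ChIP enrichment scoring, PWM scanning and bound-site calling.

The enrichment of a region in an immunoprecipitated sample i over a
reference sample j (input, or another IP for between-condition changes)
is

    e_i = log2( (n_i / N_i * median(N) + c) / (n_j / N_j * median(N) + c) )

with n the window count, N the library size, median(N) the median library
size over all co-analyzed samples, and c a pseudocount (default 8) that
damps noise at low counts.  A motif is called bound when its IP-over-input
enrichment in a 251-bp window centered on the motif is at least 1.0
(twofold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_signal import FragmentTable, GenomicInterval, count_in_windows

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class EnrichmentModel:
    """Parameters of the enrichment equation and the bound-site call."""

    pseudocount: float = 8.0
    window: int = 251
    bound_threshold: float = 1.0
    median_library_size: float | None = None

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")


@dataclass
class MotifSiteSet:
    """Motif matches with per-site scores, flags and response values.

    ``table`` columns: chrom, start, end, strand, pwm_score and, once
    computed, bound / enrichment_* / delta_* columns.
    """

    table: pd.DataFrame
    pwm_name: str = ""

    def __len__(self) -> int:
        return len(self.table)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in self.table.itertuples()
        ]


def chip_enrichment(n_i, N_i, n_j, N_j, median_N, pseudocount: float = 8.0):
    """log2 ChIP enrichment of sample i over sample j (vectorized)."""
    N_i = np.asarray(N_i, dtype=float)
    N_j = np.asarray(N_j, dtype=float)
    if np.any(N_i <= 0) or np.any(N_j <= 0):
        raise ValueError("library sizes must be positive")
    n_i = np.asarray(n_i, dtype=float)
    n_j = np.asarray(n_j, dtype=float)
    c = float(pseudocount)
    num = n_i / N_i * median_N + c
    den = n_j / N_j * median_N + c
    return np.log2(num / den)


# ---------------------------------------------------------------------------
# PWMs


def read_jaspar_pfm(path) -> tuple[str, np.ndarray]:
    """Read a JASPAR-format position frequency matrix (4 x width counts)."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    return motif.matrix_id or motif.name, counts


def pwm_log_odds(pfm: np.ndarray, background: float = 0.25, pseudo: float = 0.01) -> np.ndarray:
    """log2-odds matrix vs a uniform background, with a +0.01 probability
    pseudo-term per cell to keep zeros finite."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.shape[0] != 4 or np.any(pfm.sum(axis=0) <= 0):
        raise ValueError("PFM must be 4 x width with positive column sums")
    probs = pfm / pfm.sum(axis=0, keepdims=True)
    probs = (probs + pseudo) / (1 + 4 * pseudo)
    return np.log2(probs / background)


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else to 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _scan_scores(encoded: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position; windows containing non-ACGT
    bases score -inf."""
    width = lom.shape[1]
    n = len(encoded) - width + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    padded = np.vstack([lom, np.zeros(width)])  # row 4: N placeholder
    for k in range(width):
        col = encoded[k : k + n]
        scores += padded[col, k]
        valid &= col < 4
    scores[~valid] = -np.inf
    return scores


def scan_pwm(
    genome: dict[str, str] | str,
    pfm: np.ndarray,
    score_threshold: float | None = None,
    threshold_fraction: float = 0.8,
    pwm_name: str = "",
    resolve_overlaps: bool = True,
) -> MotifSiteSet:
    """Scan both strands of a genome for PWM matches.

    ``score_threshold`` is a minimum log2-odds score; when None, the
    threshold is ``threshold_fraction`` of the maximal achievable score.
    Overlapping same-strand hits are resolved greedily, keeping the higher
    score.  Orientation is recorded; a minus-strand hit covers the same
    forward-strand interval, scored on the reverse complement.
    """
    if isinstance(genome, str):
        genome = {"chr1": genome}
    lom = pwm_log_odds(pfm)
    width = lom.shape[1]
    if score_threshold is None:
        score_threshold = threshold_fraction * float(lom.max(axis=0).sum())

    rows = []
    for chrom, seq in genome.items():
        if width > len(seq):
            import warnings

            warnings.warn(f"{chrom}: PWM wider than sequence; no hits")
            continue
        enc_fwd = encode_sequence(seq)
        enc_rev = encode_sequence(reverse_complement(seq))
        L = len(seq)
        for strand, enc in (("+", enc_fwd), ("-", enc_rev)):
            scores = _scan_scores(enc, lom)
            hits = np.flatnonzero(scores >= score_threshold)
            for h in hits:
                start = int(h) if strand == "+" else L - width - int(h)
                rows.append((chrom, start, start + width, strand, float(scores[h])))

    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "pwm_score"])
    if resolve_overlaps:
        table = _resolve_overlaps(table)
    table = table.sort_values(["chrom", "start", "strand"], kind="stable")
    return MotifSiteSet(table.reset_index(drop=True), pwm_name=pwm_name)


def _resolve_overlaps(table: pd.DataFrame) -> pd.DataFrame:
    """Greedy per-strand resolution: keep the best-scoring hit among
    overlapping same-strand hits (ties broken by position)."""
    if table.empty:
        return table
    keep = []
    for (_, _), sub in table.groupby(["chrom", "strand"], sort=False):
        sub = sub.sort_values(["pwm_score", "start"], ascending=[False, True])
        taken: list[tuple[int, int]] = []
        for row in sub.itertuples():
            if any(row.start < e and s < row.end for s, e in taken):
                continue
            taken.append((row.start, row.end))
            keep.append(row.Index)
    return table.loc[sorted(keep)]


# ---------------------------------------------------------------------------
# Bound-site calling and responses


def _site_window_counts(
    sites: MotifSiteSet, fragments: FragmentTable, window: int
) -> np.ndarray:
    return count_in_windows(
        fragments, sites.intervals(), width=window, shift_half_insert=True
    )


def call_bound(
    sites: MotifSiteSet,
    ip: FragmentTable,
    input_: FragmentTable,
    model: EnrichmentModel | None = None,
) -> MotifSiteSet:
    """Flag motifs whose IP-over-input enrichment meets the bound threshold.

    Fragments are assigned to the window by midpoint; enrichment values are
    retained per site.  The threshold is inclusive ("at least").
    """
    model = model or EnrichmentModel()
    med = model.median_library_size
    if med is None:
        med = float(np.median([ip.library_size, input_.library_size]))
    n_ip = _site_window_counts(sites, ip, model.window)
    n_in = _site_window_counts(sites, input_, model.window)
    enr = chip_enrichment(
        n_ip, ip.library_size, n_in, input_.library_size, med, model.pseudocount
    )
    table = sites.table.copy()
    table["enrichment"] = enr
    table["bound"] = enr >= model.bound_threshold
    return MotifSiteSet(table, pwm_name=sites.pwm_name)


def response_scores(
    sites: MotifSiteSet,
    ip_mut: FragmentTable,
    ip_wt: FragmentTable,
    atac_mut: FragmentTable,
    atac_wt: FragmentTable,
    model: EnrichmentModel | None = None,
) -> MotifSiteSet:
    """Per-site log2 fold changes of binding (ChIP) and accessibility (ATAC)
    in a mutant versus wild type, via the same pseudocount equation."""
    model = model or EnrichmentModel()
    for name, tab in (
        ("ip_mut", ip_mut),
        ("ip_wt", ip_wt),
        ("atac_mut", atac_mut),
        ("atac_wt", atac_wt),
    ):
        if tab is None:
            raise ValueError(f"missing sample {name}")
    sizes = [t.library_size for t in (ip_mut, ip_wt, atac_mut, atac_wt)]
    med = model.median_library_size or float(np.median(sizes))
    table = sites.table.copy()
    n_mut = _site_window_counts(sites, ip_mut, model.window)
    n_wt = _site_window_counts(sites, ip_wt, model.window)
    table["delta_chip"] = chip_enrichment(
        n_mut, ip_mut.library_size, n_wt, ip_wt.library_size, med, model.pseudocount
    )
    a_mut = _site_window_counts(sites, atac_mut, model.window)
    a_wt = _site_window_counts(sites, atac_wt, model.window)
    table["delta_atac"] = chip_enrichment(
        a_mut, atac_mut.library_size, a_wt, atac_wt.library_size, med, model.pseudocount
    )
    return MotifSiteSet(table, pwm_name=sites.pwm_name)


def write_sites_bed(sites: MotifSiteSet, path) -> None:
    """BED6+ with pwm_score, bound and enrichment/response columns."""
    tab = sites.table
    extra = [c for c in ("bound", "enrichment", "delta_chip", "delta_atac") if c in tab]
    with open(path, "w") as fh:
        for i, row in enumerate(tab.itertuples()):
            score = int(round(row.pwm_score * 100))
            fields = [
                row.chrom,
                str(row.start),
                str(row.end),
                f"site{i}",
                str(score),
                row.strand,
            ] + [f"{getattr(row, c)}" for c in extra]
            fh.write("\t".join(fields) + "\n")
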