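"""Single-molecule footprinting (SMF) quantification.

An exogenous GpC methyltransferase marks accessible DNA; cytosines in a
GpC context that stay unmethylated sit under a bound protein or a
nucleosome.  The footprint signal at a position is therefore
1 - (GpC methylation rate).  Cytosines in GCG/CCG contexts cannot be
attributed unambiguously to the exogenous (GpC) versus endogenous (CpG)
pathway and are removed before any rate is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SMFMatrix:
    """Per-molecule methylation calls over an amplicon.

    ``calls`` is molecules x positions with values 1 (methylated),
    0 (unmethylated) and NaN (missing).  Only positions whose context is
    unambiguous GpC are retained; excluded positions and their contexts
    are kept for reporting.
    """

    amplicon_chrom: str
    amplicon_start: int
    amplicon_end: int
    positions: np.ndarray  # genomic bp of retained GpC cytosines
    calls: np.ndarray  # (n_molecules, n_positions) float with NaN = missing
    molecule_ids: np.ndarray
    contexts: np.ndarray  # per retained position, always "GpC"
    excluded_positions: np.ndarray | None = None
    excluded_contexts: np.ndarray | None = None

    @property
    def coverage(self) -> np.ndarray:
        return np.sum(~np.isnan(self.calls), axis=0)


def classify_contexts(genome: dict[str, str] | str, positions, chrom: str | None = None):
    """Classify cytosine positions by trinucleotide context.

    Returns one label per position: "GpC" (HpGpC-like: G before, not G
    after... concretely: preceded by G, not followed by G), "CpG"
    (followed by G, not preceded by G), "GCG"/"CCG" (ambiguous, preceded
    by G / any and followed by G in the overlapping patterns; excluded
    from both sets), "other_C", or "not_C" with the offending base.

    Positions are forward-strand coordinates; cytosines on the minus
    strand (a G on the forward strand) are classified on the reverse
    complement.
    """
    if isinstance(genome, str):
        seq = genome
    else:
        if chrom is None:
            if len(genome) != 1:
                raise ValueError("multi-chromosome genome requires chrom")
            chrom = next(iter(genome))
        seq = genome[chrom]
    labels = []
    n = len(seq)
    for pos in positions:
        base = seq[pos].upper()
        if base == "C":
            prev = seq[pos - 1].upper() if pos > 0 else "N"
            nxt = seq[pos + 1].upper() if pos < n - 1 else "N"
        elif base == "G":
            # minus-strand cytosine: read context on the reverse complement
            prev = seq[pos + 1].upper().translate(_COMPLEMENT) if pos < n - 1 else "N"
            nxt = seq[pos - 1].upper().translate(_COMPLEMENT) if pos > 0 else "N"
        else:
            labels.append(f"not_C:{base}")
            continue
        if prev == "G" and nxt == "G":
            labels.append("GCG")
        elif nxt == "G" and prev == "C":
            labels.append("CCG")
        elif nxt == "G":
            labels.append("CpG")
        elif prev == "G":
            labels.append("GpC")
        else:
            labels.append("other_C")
    return labels


def find_gpc_positions(genome, chrom: str, start: int, end: int) -> np.ndarray:
    """Forward-strand cytosines of GpC dinucleotides in [start, end), with
    ambiguous GCG/CCG contexts removed."""
    seq = genome[chrom] if not isinstance(genome, str) else genome
    pos = [
        p
        for p in range(max(start, 1), min(end, len(seq) - 1))
        if seq[p].upper() == "C" and seq[p - 1].upper() == "G"
    ]
    labels = classify_contexts(seq, pos)
    return np.array([p for p, lab in zip(pos, labels) if lab == "GpC"], dtype=int)


def build_smf_matrix(
    calls: pd.DataFrame,
    genome,
    amplicon,
    pool_strands: bool = True,
) -> SMFMatrix:
    """Assemble a molecules x GpC-positions matrix from a tidy call table.

    ``calls`` columns: molecule_id, position, is_methylated (0/1) and
    optionally context.  Context is (re)derived from the genome; GCG and
    CCG positions are excluded.  With ``pool_strands`` calls from both
    strands of a GpC are pooled per cytosine position.
    """
    chrom, start, end = amplicon.chrom, amplicon.start, amplicon.end
    seq = genome[chrom] if not isinstance(genome, str) else genome
    in_amp = calls[(calls["position"] >= start) & (calls["position"] < end)].copy()
    all_pos = np.array(sorted(in_amp["position"].unique()), dtype=int)
    labels = classify_contexts(seq, all_pos)
    keep = np.array([lab == "GpC" for lab in labels])
    if not pool_strands:
        keep = keep  # per-strand mode filters identically; strands kept apart upstream
    retained = all_pos[keep]
    excluded = all_pos[~keep]
    excl_ctx = np.array([lab for lab, k in zip(labels, keep) if not k])
    if len(retained) == 0:
        warnings.warn("amplicon has no unambiguous GpC positions; empty matrix")
    mol_ids = np.array(sorted(in_amp["molecule_id"].unique()))
    mol_index = {m: i for i, m in enumerate(mol_ids)}
    pos_index = {p: i for i, p in enumerate(retained)}
    mat = np.full((len(mol_ids), len(retained)), np.nan)
    for row in in_amp.itertuples():
        j = pos_index.get(int(row.position))
        if j is None:
            continue
        mat[mol_index[row.molecule_id], j] = float(row.is_methylated)
    return SMFMatrix(
        amplicon_chrom=chrom,
        amplicon_start=start,
        amplicon_end=end,
        positions=retained,
        calls=mat,
        molecule_ids=mol_ids,
        contexts=np.array(["GpC"] * len(retained)),
        excluded_positions=excluded,
        excluded_contexts=excl_ctx,
    )


def footprint_profile(matrices, min_coverage: int = 1):
    """Per-position footprint = 1 - methylation rate, averaged over replicates.

    ``matrices`` is a single SMFMatrix or a list of replicate matrices
    over the same amplicon.  Positions with fewer informative calls than
    ``min_coverage`` are NaN (missing, never zero).  Returns
    (positions, mean_footprint, sd_across_replicates, per_replicate).
    """
    if isinstance(matrices, SMFMatrix):
        matrices = [matrices]
    positions = matrices[0].positions
    per_rep = []
    for m in matrices:
        if not np.array_equal(m.positions, positions):
            raise ValueError("replicates must share GpC positions")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            meth = np.nanmean(m.calls, axis=0)
        cov = m.coverage
        fp = 1.0 - meth
        fp[cov < min_coverage] = np.nan
        per_rep.append(fp)
    per_rep = np.array(per_rep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_fp = np.nanmean(per_rep, axis=0)
        sd_fp = np.nanstd(per_rep, axis=0, ddof=1) if len(per_rep) > 1 else np.zeros_like(mean_fp)
    return positions, mean_fp, sd_fp, per_rep


def molecule_sort(matrix: SMFMatrix, site_window, threshold: float = 0.5):
    """Order molecules by mean methylation inside ``site_window`` and
    partition them into bound-like (low methylation) and accessible-like.

    ``site_window`` is (start, end) in genomic coordinates.  Returns
    (order, labels) where order is a stable permutation of molecule
    indices (ascending window methylation, ties broken by molecule id)
    and labels is "bound_like" where window methylation < threshold.
    Molecules with no informative call in the window sort last and are
    labeled "uninformative".
    """
    lo, hi = site_window
    mask = (matrix.positions >= lo) & (matrix.positions < hi)
    if not mask.any():
        raise ValueError("site window contains no retained GpC positions")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        win_meth = np.nanmean(matrix.calls[:, mask], axis=1)
    sort_key = np.where(np.isnan(win_meth), np.inf, win_meth)
    order = np.lexsort((matrix.molecule_ids, sort_key))
    labels = np.where(
        np.isnan(win_meth),
        "uninformative",
        np.where(win_meth < threshold, "bound_like", "accessible_like"),
    )
    return order, labels


def write_footprint_bedgraph(chrom, positions, values, path) -> None:
    with open(path, "w") as fh:
        for p, v in zip(positions, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{p}\t{p + 1}\t{v:.6g}\n")
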