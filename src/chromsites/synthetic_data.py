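"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the assays the pipeline consumes — motif-anchored
binding (ChIP IP/input fragment enrichment), phased nucleosome arrays
(MNase fragments), single-molecule GpC footprints, and distance-decay
contact matrices with insulated TAD boundaries — with every generating
parameter recorded, so each downstream module can be tested by recovering
the parameter that produced its input.

The shipped M1 (19-column) and M2 (9-column) PWMs are synthetic
placeholder consensus matrices, clearly non-canonical: scanning and
recovery behaviour depends only on having *a* motif of the right width,
never on the canonical CTCF letters.  Real JASPAR matrices may be passed
in wherever a PFM argument is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_signal import FragmentTable, GenomicInterval
from .enrichment_binding import BASES, pwm_log_odds, reverse_complement
from .hic_pileup import ContactMatrix

# Placeholder consensus motifs (synthetic, non-canonical).
_M1_CONSENSUS = "TGACGTCATCGATGGCATG"  # 19 nt
_M2_CONSENSUS = "ATCGGTACG"  # 9 nt


def _consensus_pfm(consensus: str, dominant: float = 0.85) -> np.ndarray:
    """PFM with ``dominant`` probability on the consensus base per column."""
    pfm = np.full((4, len(consensus)), (1 - dominant) / 3)
    for j, base in enumerate(consensus):
        pfm[BASES.index(base), j] = dominant
    return pfm * 100  # counts-like scale


def default_m1_pfm() -> np.ndarray:
    return _consensus_pfm(_M1_CONSENSUS)


def default_m2_pfm() -> np.ndarray:
    return _consensus_pfm(_M2_CONSENSUS)


@dataclass
class SyntheticConfig:
    """Simulation knobs standing in for the study's cellular conditions."""

    genome_length: int = 4_000_000
    chrom_names: tuple = ("chr1", "chr2", "chr3", "chr4")
    gc_content: float = 0.42
    seed: int = 0
    # motif sites
    n_sites: int = 600
    bound_fraction: float = 0.5
    m2_fraction: float = 0.5
    m2_offset: int = 21  # bp downstream (3') of the M1 center
    # nucleosome arrays
    nrl: int = 182
    dyad_jitter_sd: float = 10.0
    n_arrays_per_boundary: int = 10
    n_cells: int = 50
    nucleosome_background: float = 0.1  # background fragments per array fragment
    # ChIP IP / input
    read_depth: int = 1_000_000
    enrichment_factor: float = 8.0
    # SMF
    footprint_halfwidth: int = 15
    p_meth_accessible: float = 0.8
    p_meth_protected: float = 0.1
    p_meth_cpg: float = 0.7
    smf_occupancy: float = 1.0
    n_molecules: int = 500
    amplicon_halfwidth: int = 150
    # Hi-C
    hic_resolution: int = 10_000
    hic_n_bins: int = 400
    hic_depth: int = 1_000_000
    ps_exponent: float = -1.0
    tad_boundaries: tuple = (60, 130, 200, 270, 340)
    boundary_strength: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gc_content", "bound_fraction", "m2_fraction",
                     "p_meth_accessible", "p_meth_protected", "p_meth_cpg",
                     "smf_occupancy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.m2_offset <= 0:
            raise ValueError("m2_offset must be positive")
        if self.nrl <= 146:
            raise ValueError("nrl must exceed the nucleosome core (146 bp)")
        if self.dyad_jitter_sd < 0:
            raise ValueError("dyad_jitter_sd must be non-negative")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.ps_exponent >= 0:
            raise ValueError("ps_exponent must be negative")
        if self.boundary_strength <= 0:
            raise ValueError("boundary_strength must be positive")
        if list(self.tad_boundaries) != sorted(self.tad_boundaries):
            raise ValueError("tad_boundaries must be sorted")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per generator."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """Planted parameters for recovery tests."""

    sites: pd.DataFrame | None = None  # chrom,start,end,strand,m1_score,has_m2,bound
    dyad_positions: list | None = None  # per cell
    true_nrl: float | None = None
    true_delta_binding: np.ndarray | None = None
    delta_coefficients: tuple | None = None  # (a, b, noise_sd)
    molecule_occupancy: np.ndarray | None = None
    tad_intervals: list | None = None
    expected_decay: np.ndarray | None = None


class CapacityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genome with planted motif sites


def simulate_genome(
    config: SyntheticConfig,
    m1_pfm: np.ndarray | None = None,
    m2_pfm: np.ndarray | None = None,
):
    """Random genome with non-overlapping planted M1 (+ optional M2) sites.

    Background is i.i.d. per base at the configured GC content.  Each site
    draws its M1 sequence column-wise from the PFM (so motif-match scores
    are graded), has a random orientation, and — for ``m2_fraction`` of
    sites — carries an M2 match whose start sits ``m2_offset`` bp 3' of
    the M1 center in motif orientation.  Returns (genome dict, GroundTruth
    with the site table).
    """
    m1_pfm = default_m1_pfm() if m1_pfm is None else np.asarray(m1_pfm, float)
    m2_pfm = default_m2_pfm() if m2_pfm is None else np.asarray(m2_pfm, float)
    if m1_pfm.shape[0] != 4 or m2_pfm.shape[0] != 4:
        raise ValueError("PFMs must be 4 x width")
    m1_w = m1_pfm.shape[1]
    m2_w = m2_pfm.shape[1]
    m1_half = m1_w // 2

    rng = config.rng(1)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)

    n_chroms = len(config.chrom_names)
    chrom_len = config.genome_length // n_chroms
    genome = {}
    for chrom in config.chrom_names:
        draws = rng.choice(4, size=chrom_len, p=probs)
        genome[chrom] = base_arr[draws].tobytes().decode()

    # capacity: reserve non-overlapping slots with clearance for the
    # cassette plus the widest downstream window (251 bp enrichment)
    slot = 500
    per_chrom = _split_counts(config.n_sites, n_chroms, rng)
    margin = 1200  # keep 2-kb profile windows inside the chromosome
    m1_probs = m1_pfm / m1_pfm.sum(axis=0, keepdims=True)
    m2_probs = m2_pfm / m2_pfm.sum(axis=0, keepdims=True)
    m1_lom = pwm_log_odds(m1_pfm)

    rows = []
    for chrom, n_here in zip(config.chrom_names, per_chrom):
        usable = chrom_len - 2 * margin
        n_slots = usable // slot
        if n_here > n_slots:
            raise CapacityError(
                f"{chrom}: cannot place {n_here} non-overlapping sites "
                f"({n_slots} slots of {slot} bp available)"
            )
        chosen = rng.choice(n_slots, size=n_here, replace=False)
        centers = margin + chosen * slot + slot // 2
        seq = np.frombuffer(genome[chrom].encode(), dtype=np.uint8).copy()
        for center in np.sort(centers):
            strand = "+" if rng.random() < 0.5 else "-"
            m1_idx = np.array([rng.choice(4, p=m1_probs[:, j]) for j in range(m1_w)])
            m1_seq = base_arr[m1_idx].tobytes().decode()
            m1_score = float(m1_lom[m1_idx, np.arange(m1_w)].sum())
            has_m2 = bool(rng.random() < config.m2_fraction)
            cassette = {}
            for o, b in zip(range(-m1_half, -m1_half + m1_w), m1_seq):
                cassette[o] = b
            if has_m2:
                # M1 strength is graded (sampled from the PFM) because the
                # binding labels regress on it; M2 is a binary presence
                # flag, so the consensus is planted verbatim
                m2_idx = np.argmax(m2_probs, axis=0)
                m2_seq = base_arr[m2_idx].tobytes().decode()
                for o, b in zip(range(config.m2_offset, config.m2_offset + m2_w), m2_seq):
                    cassette[o] = b
            for o, b in cassette.items():
                if strand == "+":
                    seq[center + o] = ord(b)
                else:
                    seq[center - o] = ord(reverse_complement(b))
            rows.append(
                (
                    chrom,
                    int(center - m1_half),
                    int(center - m1_half + m1_w),
                    strand,
                    m1_score,
                    has_m2,
                )
            )
        genome[chrom] = seq.tobytes().decode()

    sites = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "m1_score", "has_m2"]
    )
    # exact bound/decoy split
    n_bound = int(round(config.n_sites * config.bound_fraction))
    order = rng.permutation(len(sites))
    bound = np.zeros(len(sites), dtype=bool)
    bound[order[:n_bound]] = True
    sites["bound"] = bound
    return genome, GroundTruth(sites=sites)


def _split_counts(total: int, k: int, rng) -> np.ndarray:
    base = np.full(k, total // k)
    base[: total % k] += 1
    return base


def site_center(row) -> int:
    return int(row.start) + (int(row.end) - int(row.start)) // 2


# ---------------------------------------------------------------------------
# Nucleosome arrays


def simulate_nucleosome_fragments(
    genome_length: int,
    anchors,
    config: SyntheticConfig,
    chrom: str = "chr1",
):
    """MNase-like fragments from phased nucleosome arrays around anchors.

    Per cell, dyads sit at anchor +/- k*nrl + Normal(0, jitter) for
    k = 1..n_arrays_per_boundary on both sides of each anchor (the anchor
    itself is nucleosome-free).  Each dyad emits one fragment of length
    ~Normal(147, 10) centered on the dyad, strand Bernoulli(1/2).
    Uniform background fragments are added at ``nucleosome_background``
    per array fragment.  Returns (FragmentTable, GroundTruth).
    """
    if config.dyad_jitter_sd < 0:
        raise ValueError("dyad_jitter_sd must be non-negative")
    rng = config.rng(2)
    anchors = np.asarray(anchors, dtype=int)
    k = np.arange(1, config.n_arrays_per_boundary + 1)
    offsets = np.concatenate([-k[::-1], k]) * config.nrl

    dyads_per_cell = []
    all_dyads = []
    for _ in range(config.n_cells):
        lattice = (anchors[:, None] + offsets[None, :]).ravel().astype(float)
        if config.dyad_jitter_sd > 0:
            lattice = lattice + rng.normal(0, config.dyad_jitter_sd, size=lattice.shape)
        dyads = np.rint(lattice).astype(int)
        dyads = dyads[(dyads >= 100) & (dyads < genome_length - 100)]
        dyads_per_cell.append(dyads)
        all_dyads.append(dyads)
    dyads = np.concatenate(all_dyads)

    lengths = np.clip(np.rint(rng.normal(147, 10, size=len(dyads))), 50, None).astype(int)
    starts = dyads - lengths // 2
    ends = starts + lengths
    strands = np.where(rng.random(len(dyads)) < 0.5, "+", "-")

    n_bg = int(round(config.nucleosome_background * len(dyads)))
    if n_bg:
        bg_len = np.clip(np.rint(rng.normal(147, 10, size=n_bg)), 50, None).astype(int)
        bg_start = rng.integers(0, genome_length - bg_len.max() - 1, size=n_bg)
        starts = np.concatenate([starts, bg_start])
        ends = np.concatenate([ends, bg_start + bg_len])
        strands = np.concatenate([strands, np.where(rng.random(n_bg) < 0.5, "+", "-")])

    keep = (starts >= 0) & (ends <= genome_length)
    rec = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts[keep],
            "end": ends[keep],
            "strand": strands[keep],
        }
    )
    truth = GroundTruth(dyad_positions=dyads_per_cell, true_nrl=float(config.nrl))
    return FragmentTable(rec, sample_label="mnase_sim"), truth


# ---------------------------------------------------------------------------
# ChIP IP / input fragments


def simulate_ip_fragments(sites: pd.DataFrame, config: SyntheticConfig, genome=None):
    """Paired IP and input fragment tables with planted site enrichment.

    Input fragments are uniform.  IP fragments are a mixture of uniform
    background and bound-site-centered fragments (midpoints uniform in
    the 251-bp calling window), mixed so the expected IP/input density
    ratio in that window is ``enrichment_factor`` at bound sites and 1
    at decoys.  Exactly ``read_depth`` fragments per table.
    """
    rng = config.rng(3)
    window = 251
    if genome is not None:
        chrom_lens = {c: len(s) for c, s in genome.items()}
    else:
        n_chroms = len(config.chrom_names)
        chrom_lens = {c: config.genome_length // n_chroms for c in config.chrom_names}
    chroms = list(chrom_lens)
    lens = np.array([chrom_lens[c] for c in chroms], dtype=float)
    G = lens.sum()
    depth = int(config.read_depth)

    def uniform_fragments(n):
        ci = rng.choice(len(chroms), size=n, p=lens / G)
        frag_len = np.clip(np.rint(rng.normal(200, 20, size=n)), 50, None).astype(int)
        mid = (rng.random(n) * (lens[ci] - 300) + 150).astype(int)
        start = mid - frag_len // 2
        return (
            np.array(chroms, dtype=object)[ci],
            start,
            start + frag_len,
            np.where(rng.random(n) < 0.5, "+", "-"),
        )

    inp = uniform_fragments(depth)
    input_table = FragmentTable(
        pd.DataFrame(
            {"chrom": inp[0], "start": inp[1], "end": inp[2], "strand": inp[3]}
        ),
        sample_label="input_sim",
    )

    bound = sites[sites["bound"]].reset_index(drop=True)
    E = config.enrichment_factor
    if len(bound) == 0 or E == 1.0:
        p_site = 0.0
    else:
        ratio = G / (len(bound) * window)
        if ratio <= E:
            raise CapacityError(
                "genome too small relative to bound sites for the requested "
                f"enrichment factor (density ratio {ratio:.1f} <= {E})"
            )
        p_site = (E - 1.0) / (ratio - 1.0)
    n_site = rng.binomial(depth, p_site) if p_site > 0 else 0
    n_bg = depth - n_site
    bg = uniform_fragments(n_bg)
    if n_site:
        si = rng.integers(0, len(bound), size=n_site)
        centers = bound["start"].to_numpy()[si] + (
            bound["end"].to_numpy()[si] - bound["start"].to_numpy()[si]
        ) // 2
        # midpoints uniform across the 251-bp calling window
        mid = centers - window // 2 + rng.integers(0, window, size=n_site)
        frag_len = np.clip(np.rint(rng.normal(200, 20, size=n_site)), 50, None).astype(int)
        start = mid - frag_len // 2
        chrom_col = np.concatenate([bg[0], bound["chrom"].to_numpy()[si]])
        start_col = np.concatenate([bg[1], start])
        end_col = np.concatenate([bg[2], start + frag_len])
        strand_col = np.concatenate(
            [bg[3], np.where(rng.random(n_site) < 0.5, "+", "-")]
        )
    else:
        chrom_col, start_col, end_col, strand_col = bg
    ip_table = FragmentTable(
        pd.DataFrame(
            {
                "chrom": chrom_col,
                "start": start_col,
                "end": end_col,
                "strand": strand_col,
            }
        ),
        sample_label="ip_sim",
    )
    if depth == 0:
        ip_table.sample_label += ":empty"
        input_table.sample_label += ":empty"
    return ip_table, input_table


# ---------------------------------------------------------------------------
# SMF molecules


def simulate_smf_molecules(genome, site_row, config: SyntheticConfig):
    """Per-molecule methylation calls over an amplicon around one site.

    Each molecule is occupied with probability ``smf_occupancy``.  Every
    cytosine in a GpC-family context (including the ambiguous GCG/CCG
    ones, which the analysis must remove) is methylated with
    ``p_meth_protected`` when within ``footprint_halfwidth`` of the site
    center on an occupied molecule, else ``p_meth_accessible``.
    Cytosines in a pure CpG context carry endogenous methylation at
    ``p_meth_cpg`` independent of occupancy.  Returns (calls DataFrame,
    GroundTruth with occupancy labels).
    """
    if config.footprint_halfwidth <= 0:
        raise ValueError("footprint_halfwidth must be positive")
    rng = config.rng(4)
    chrom = site_row.chrom
    seq = genome[chrom]
    center = site_center(site_row)
    lo = center - config.amplicon_halfwidth
    hi = center + config.amplicon_halfwidth

    from .smf_footprint import classify_contexts

    positions, contexts = [], []
    for p in range(max(lo, 1), min(hi, len(seq) - 1)):
        base = seq[p].upper()
        if base not in "CG":
            continue
        lab = classify_contexts(seq, [p])[0]
        if lab in ("GpC", "GCG", "CCG", "CpG"):
            positions.append(p)
            contexts.append(lab)
    positions = np.array(positions, dtype=int)
    contexts = np.array(contexts)
    if len(positions) == 0:
        import warnings

        warnings.warn("amplicon contains no GpC/CpG cytosines; empty call table")
        empty = pd.DataFrame(columns=["molecule_id", "position", "is_methylated", "context"])
        return empty, GroundTruth(molecule_occupancy=np.zeros(0, dtype=bool))

    occupied = rng.random(config.n_molecules) < config.smf_occupancy
    in_fp = np.abs(positions - center) <= config.footprint_halfwidth
    gpc_like = np.isin(contexts, ["GpC", "GCG", "CCG"])

    frames = []
    for m in range(config.n_molecules):
        p_meth = np.where(
            gpc_like,
            np.where(
                in_fp & occupied[m], config.p_meth_protected, config.p_meth_accessible
            ),
            config.p_meth_cpg,
        )
        calls = (rng.random(len(positions)) < p_meth).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": f"mol{m:05d}",
                    "position": positions,
                    "is_methylated": calls,
                    "context": contexts,
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    return calls, GroundTruth(molecule_occupancy=occupied)


# ---------------------------------------------------------------------------
# Hi-C contact matrix


def simulate_contact_matrix(config: SyntheticConfig, noiseless: bool = False):
    """Distance-decay contact matrix with insulated TAD boundaries.

    Expected counts follow C * (1 + |i-j|)^ps_exponent, divided by
    ``boundary_strength`` once per TAD boundary the cell straddles; C is
    set so the expected upper-triangle total is ``hic_depth``.  With
    ``noiseless`` the expected values are returned; otherwise each cell
    is Poisson-sampled (symmetrically).  Returns (ContactMatrix,
    GroundTruth with TAD intervals and the generating decay).
    """
    rng = config.rng(5)
    n = config.hic_n_bins
    idx = np.arange(n)
    d = np.abs(np.subtract.outer(idx, idx))
    decay = (1.0 + np.arange(n)) ** config.ps_exponent
    expected = decay[d].astype(float)
    for b in config.tad_boundaries:
        if not 0 < b < n:
            raise ValueError(f"tad boundary {b} outside matrix of {n} bins")
        crosses = (np.minimum.outer(idx, idx) < b) & (np.maximum.outer(idx, idx) >= b)
        expected[crosses] /= config.boundary_strength
    triu_total = np.triu(expected).sum()
    scale = config.hic_depth / triu_total
    expected *= scale
    decay_scaled = decay * scale

    if noiseless:
        matrix = expected
    else:
        upper = rng.poisson(np.triu(expected))
        matrix = upper + np.triu(upper, 1).T
        matrix = matrix.astype(float)

    cm = ContactMatrix(
        chrom="chr1", resolution=config.hic_resolution, matrix=matrix
    )
    bounds = [0, *config.tad_boundaries, n]
    tads = list(zip(bounds[:-1], bounds[1:]))
    truth = GroundTruth(tad_intervals=tads, expected_decay=decay_scaled)
    return cm, truth


# ---------------------------------------------------------------------------
# Binding-response labels


def simulate_binding_response(
    sites: pd.DataFrame,
    a: float = 0.5,
    b: float = 0.8,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Per-site change-in-binding labels for the sequence model.

    delta = a * standardize(m1_score) + b * 1[has_m2] + Normal(0, noise_sd).
    Returns (labels array, GroundTruth with the coefficients).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    score = sites["m1_score"].to_numpy(float)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    delta = a * z + b * sites["has_m2"].to_numpy(float)
    if noise_sd > 0:
        delta = delta + rng.normal(0, noise_sd, size=len(delta))
    if not np.all(np.isfinite(delta)):
        raise ValueError("non-finite binding labels")
    return delta, GroundTruth(true_delta_binding=delta, delta_coefficients=(a, b, noise_sd))


# ---------------------------------------------------------------------------
# Writers


def write_fasta(genome: dict[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_sites_bed(sites: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(sites.itertuples()):
            score = int(round(row.m1_score * 100))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tsite{i}\t{score}\t{row.strand}\n"
            )


def write_config(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        for key, value in asdict(config).items():
            if isinstance(value, tuple):
                value = ",".join(map(str, value))
            fh.write(f"{key}={value}\n")


def site_sequences(genome, sites: pd.DataFrame, length: int = 150) -> list[str]:
    """Oriented ``length``-bp sequences centered on each site's M1 center."""
    half = length // 2
    out = []
    for row in sites.itertuples():
        seq = genome[row.chrom]
        center = site_center(row)
        if row.strand == "-":
            # shift by one so the M1 center lands on index `half` after
            # reverse complementing, as it does for plus-strand sites
            window = reverse_complement(seq[center - half + 1 : center + half + 1])
        else:
            window = seq[center - half : center + half]
        out.append(window)
    return out
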