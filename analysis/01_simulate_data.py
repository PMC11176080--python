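#!/usr/bin/env python
"""Generate the synthetic study system: a genome with planted CTCF
M1/M2 sites, matched IP/input fragment libraries, and a contact matrix
with insulated TAD boundaries.  Writes the site table and summary
counts; downstream scripts regenerate what they need from the same
seeds, so no large intermediates are stored."""

from pathlib import Path

import numpy as np

from chromsites import synthetic_data as syn

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def main():
    OUT.mkdir(exist_ok=True)
    cfg = syn.SyntheticConfig(seed=SEED)
    genome, truth = syn.simulate_genome(cfg)
    sites = truth.sites

    syn.write_sites_bed(sites, OUT / "01_planted_sites.bed")
    syn.write_config(cfg, OUT / "01_config.txt")

    gc = np.mean([
        sum(seq.count(b) for b in "GC") / len(seq) for seq in genome.values()
    ])
    print(f"genome: {len(genome)} chromosomes x {cfg.genome_length // len(genome):,} bp, GC {gc:.3f}")
    print(f"planted sites: {len(sites)} ({int(sites.bound.sum())} bound, "
          f"{int(sites.has_m2.sum())} with M2 at +{cfg.m2_offset} bp)")
    print(f"M1 log-odds score range: {sites.m1_score.min():.1f} .. {sites.m1_score.max():.1f}")

    cm, hic_truth = syn.simulate_contact_matrix(cfg)
    from chromsites.hic_pileup import write_contact_matrix

    write_contact_matrix(cm, OUT / "01_hic_bins.tsv", OUT / "01_hic_triplets.tsv")
    print(f"contact matrix: {cm.n_bins} bins at {cm.resolution // 1000} kb, "
          f"{int(np.triu(cm.matrix).sum()):,} contacts, "
          f"boundaries at bins {cfg.tad_boundaries}")


if __name__ == "__main__":
    main()
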