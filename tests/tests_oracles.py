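"""Independent brute-force reference implementations.

These are deliberately naive (nested loops, O(n^2) pair counting,
per-window rescans) and share no code with the package; the oracle
equivalence tests hold the fast implementations to them exactly.
"""

import numpy as np

from chromsites.enrichment_binding import reverse_complement


def brute_profile(table, anchors, window, mode):
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


def brute_phasogram(points, max_distance):
    counts = np.zeros(max_distance)
    for (_, _), sub in points.groupby(["chrom", "strand"]):
        pos = sub["pos"].to_numpy()
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = abs(int(pos[i]) - int(pos[j]))
                if 1 <= d <= max_distance:
                    counts[d - 1] += 1
    return counts


def brute_diamond(matrix, w):
    n = matrix.shape[0]
    out = np.full(n, np.nan)
    for b in range(n):
        if b - w < 0 or b + w >= n:
            continue
        vals = [
            matrix[i, j]
            for i in range(b - w, b)
            for j in range(b + 1, b + w + 1)
        ]
        out[b] = float(np.mean(vals))
    return out


def brute_pwm_scan(seq, lom, threshold):
    hits = []
    width = lom.shape[1]
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for i in range(len(s) - width + 1):
            window = s[i : i + width]
            if any(b not in "ACGT" for b in window):
                continue
            score = sum(lom["ACGT".index(b), k] for k, b in enumerate(window))
            if score >= threshold:
                start = i if strand == "+" else len(seq) - width - i
                hits.append((start, strand, round(score, 9)))
    return sorted(hits)
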