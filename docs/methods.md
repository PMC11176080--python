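# Methods

This note records the models behind each module, the conventions and
numerical choices a maintainer would need, what the synthetic generators
do and do not emulate, and the problem sizes the test suite runs at.

## Coordinates and counting conventions

All coordinates are 0-based half-open; BED is the native interchange and
1-based formats (SAM) are converted at the boundary. The midpoint of a
fragment `[start, end)` is `start + length // 2` — the right-of-center
base for even lengths. A motif's center is `start + width // 2`
(position 9 of a 19-mer); anchored windows of 2000 bp span relative
positions −1000..+999, and minus-strand anchors have the axis reversed
so +x is always 3′ of the motif. The involution property (flipping a
strand twice restores the profile) and agreement with a per-site
brute-force counter are enforced by tests. Overlapping anchors each
receive counts independently; fragments are assigned to fixed windows by
midpoint (the half-insert shift), including the 251-bp enrichment
window, where the overlap rule is a convention that the tests freeze.

Profile normalizations (recorded as provenance tags on the matrix):
`atac_x100` = counts / library size × 100; `chip_per_site_x1000` =
counts / library size / n_sites × 1000; `mnase_median` divides each
co-normalized sample by its own median profile value and rescales all by
the median of those medians, so a single sample is returned unchanged
and co-normalized samples share a common median. These multiplicative
constants are display scalings with no statistical content.

## Enrichment model

Window counts are converted to a log2 enrichment with
`e = log2((n_i/N_i·medN + c) / (n_j/N_j·medN + c))`, pseudocount `c = 8`
counts at the median library size. The pseudocount bounds the score for
empty windows (e = 0 when both counts are 0) and shrinks low-count
ratios toward zero; at planted 8× enrichment and 10⁶ fragments on a
4-Mb genome the expected window count is ≈ 63, so the shrinkage costs
about 0.15 log2 units — visible in the recovery numbers, which sit near
2.85 rather than 3.0, still far above the twofold calling threshold.
The threshold "at least 1.0" is inclusive. `median(N)` is the median
over whatever sample set is co-loaded; when only IP and input are
supplied it is the median of those two.

PWM scores are log2 odds against a uniform background with a +0.01
probability pseudo-term per cell; the default scan threshold is 80 % of
the maximal achievable score (no threshold is canonical for motif
prediction, so it is explicit and configurable). Overlapping same-strand
hits are resolved greedily by score, ties by position; the raw
(unresolved) hit set is available and is what the exhaustive-scan oracle
checks.

## Phasogram NRL estimation

The phasogram counts ordered pairs of same-chromosome, same-strand
fragment 5′-start positions at each distance 1..max (default 3000 bp),
computed as the autocorrelation of the per-strand position histogram via
FFT and checked against an O(n²) all-pairs loop. 5′ starts, not
midpoints, are used — phase peaks need only a consistent per-fragment
reference point, and starts avoid coupling the spectrum to the
fragment-length distribution. Estimation: smooth with a 31-bp running
mean, detrend by subtracting a 301-bp running mean, take local maxima
above zero with ≥ 100 bp separation inside the 100–3000 bp fit range,
and regress peak position on peak index (OLS; slope = NRL, with its
standard error and R²). These defaults resolve repeat lengths in the
150–250 bp range; they are declared parameters, frozen in tests, and no
claim of numerical parity with any external phasogram implementation is
made — correctness is defined by planted-truth recovery (±3 bp at NRL
182 with 10-bp dyad jitter, 200 anchors × 50 cells).

## Single-molecule footprints

Cytosine context is the trinucleotide around the C (read on the reverse
complement for minus-strand cytosines): GCG and CCG are ambiguous
between the exogenous GpC and endogenous CpG pathways and are excluded
from both sets before any rate is computed; the filter is verified
against an exhaustive 64-trinucleotide truth table. The footprint at a
position is 1 − (methylated / informative) calls; positions below the
coverage floor are missing, never zero. GpC calls from both strands are
pooled per cytosine by default (a per-strand path exists, since the
convention differs between pipelines). Replicates are averaged with the
per-replicate profiles and their s.d. retained; with equal molecule
counts the replicate mean equals the pooled mean exactly.

## Site classes

Clustering uses Lloyd's k-means with k-means++ initialization, best of
25 restarts by WCSS, on unscaled (ΔATAC, ΔChIP) log2 fold changes —
already commensurate units, so no z-scoring by default. Cluster labels
are renumbered by decreasing mean ΔATAC, which makes the numbering a
function of the partition alone. The persistence filter takes sites with
linear binding fold change 2^ΔChIP in the closed interval [0.8, 1.2]
(the log-scale asymmetry of that window is accepted as-is, since the
definition is a percentage); the endpoints carry a 1e−9 relative
tolerance so values stored in log2 and converted back still count.
Persistent sites are ranked by ΔATAC and cut into rank quantiles of
equal size ±1 (group 1 = least accessibility loss); fixed cut-points
would be an alternative reading and remain available by passing explicit
boundaries to the caller's own binning. State annotation applies the
documented state mergers first, then the priority order ActivePromoter >
BivalentChromatin > Enhancer > RepressedChromatin > Insulator, with
Intergenic as the no-overlap fallback.

## Sequence model

Architecture (fixed): four 1D convolutions with 128/128/128/64 filters
of widths 5/3/5/3 ('same' padding), each followed by ReLU and max-pool
of 2 (valid, floor division: 150 → 75 → 37 → 18 → 9), then dense layers
of 128 and 64 units with ReLU and dropout 0.4 after each, and one linear
output. Loss is MSE; the optimizer is Adam at learning rate 10⁻³
(β₁ = 0.9, β₂ = 0.999), batch 64; 20 % of the training sites form the
validation split; early stopping restores the best validation weights
with patience 15 and an epoch cap of 30 — on the planted-signal task the
validation loss bottoms out near epoch 10–15, and the cap keeps a
single training run around two minutes on one CPU core. The
implementation is plain NumPy (float32, im2col convolutions as BLAS
matrix products, hand-written backward pass); training is exactly
reproducible given the seed, and the backward pass exposes input
gradients. Labels are used unstandardized.

Evaluation holds out whole chromosomes (no test-chromosome site enters
training or validation). On labels Δ = 0.5·z(M1 score) + 0.8·1[M2] +
N(0, 0.3) with a 0.5 M2 fraction, the generative signal fraction is
R² = 0.41/0.50 ≈ 0.82 (attainable r ≈ 0.91); the acceptance bar of
r ≥ 0.69 corresponds to the model capturing ≈ 0.8 of attainable
correlation, and trained runs typically reach r ≈ 0.85.

Attribution: expected gradients — for each sequence, average
(x − ref)·∇f over 100 dinucleotide-shuffled references with stratified
interpolation coefficients covering [0, 1); `n_steps` adds interpolation
points per reference when tight completeness is needed (at 8 steps the
contribution sum matches f(x) − E[f(ref)] within 5 % wherever that gap
exceeds 0.5 — below that the 5 % band is smaller than the estimator's
Monte-Carlo noise). In-silico mutagenesis (f(original) − mean over the
three substitutions per position) is the model-agnostic oracle; the two
per-position profiles correlate at r ≥ 0.7 on trained models. The
dinucleotide shuffle is the Euler-path (last-exit arborescence)
algorithm, preserving the exact dinucleotide multiset and the terminal
bases; uniformity over valid shuffles is χ²-tested against exhaustive
enumeration on a 10-mer. The CWM averages the signed contribution of the
observed base per position over aligned oriented sequences (an
absolute-value variant can be obtained by passing |tensors|); cells for
never-observed bases are missing, not zero.

## Hi-C statistics

Matrices are dense, symmetric, single-chromosome, 10-kb bins by default;
balancing is accepted as precomputed weights (iterative correction
itself is out of scope — delegated upstream). Observed/expected divides
each cell by the mean finite value of its diagonal; a known analytic
decay can be supplied instead, which the simulation tests use so the
quadrant statistic has an exact closed form (empirical per-diagonal
means mix boundary-depleted and normal cells, biasing the statistic
slightly for few-boundary toy matrices). Local pileups average O/E
submatrices over anchors (minus-strand anchors rotated 180°), skipping
and counting anchors within the pad of an edge; missing cells are
excluded per cell with counts retained. The quadrant insulation
strength is mean(UL ∪ LR)/mean(UR ∪ LL) with the central row/column in
no quadrant and cells within two diagonals of the main diagonal masked
(the short-range ligation-artifact band). On noiseless block matrices
the statistic equals the planted boundary strength exactly for strengths
1–4; Poisson-sampled at 10⁶ contacts it is within ±10 %.

Diamond insulation for bin b is the mean contact over the w × w cells
linking the w bins upstream to the w bins downstream (w = window /
resolution, default 100 kb / 10 kb), reported as log2 of the value over
the chromosome mean; boundary candidates are local minima with their
prominence as boundary strength, thresholded by Li's iterative
cross-entropy method by default — a reimplementation choice, stated as
such, with the threshold always overridable. TADs are consecutive
boundary pairs, dropping intervals above 1.5 Mb.

## What the generators emulate — and what they do not

Backgrounds are i.i.d. bases at a set GC content: no repeats, no
composition domains, no real motif lexicon. M1 sites are drawn
column-wise from the PFM so match scores are graded; M2 is planted as
the exact consensus because downstream models use it only as a binary
indicator. Fragment strands are Bernoulli(½) independent of position
(phasograms use same-strand distances, so balance matters and phase does
not). IP libraries mix uniform background with site-centered fragments
so the expected IP/input density ratio in the 251-bp window equals the
configured enrichment factor exactly at bound sites and 1 at decoys;
bookkeeping is exact (each table holds precisely `read_depth`
fragments). SMF molecules methylate every GpC-family cytosine
independently given occupancy — no methyltransferase processivity, no
conversion errors. Contact matrices are Poisson draws around
C·(1+d)^α with a per-boundary depletion factor; a `noiseless` flag
emits expectations for analytic tests. None of the generators model
sequencing error, PCR duplication, mappability or inter-chromosomal
contacts, so passing tests demonstrate correctness of the computations
and estimator calibration under clean sampling noise — not robustness to
real-data artifacts.

The SMF amplicon length is not a fixed constant of the assay; the
generator exposes it (default ±150 bp around the site center).

## Problem sizes and runtime choices

The default test-suite conditions: NRL recovery at 200 anchors × 50
cells on a 20-Mb coordinate space; bound calling at 300 bound + 300
decoy sites, depth 10⁶; insulation on 400-bin matrices; the CNN at
5,000 sites across 8 chromosomes (2 held out), three seeds; SMF at 500
molecules; attribution on 200 test sequences (CWM) and 12 (ISM
agreement, completeness). These sizes make the full suite and the
acceptance script each run in minutes on a single CPU core while leaving
every recovery check comfortably determined; they are package
defaults, configurable per call.

## Known limitations

- The CNN is CPU-scale by design (≈ 50 k sequences is the practical
  ceiling); there is no GPU path and no hyperparameter search.
- PWM overlap resolution is greedy, not optimal-weight interval
  scheduling; for motif-density studies use the raw hit set.
- Diamond-insulation boundary calling on shallow matrices is noisy;
  boundary strengths are returned so callers can apply their own
  threshold.
- `mnase_median` normalization requires all co-normalized samples in one
  call; there is no streaming path.
- BAM support covers proper pairs only (the fragment-table TSV is the
  primary format); CRAM and bigWig are out of scope.
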