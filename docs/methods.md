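# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions adopted where the underlying
procedure left a choice open.

## Scanning model

Matrix counts are converted to frequencies after adding a pseudocount of
0.01 to every cell — enough to avoid `ln 0` on zero counts while
perturbing informative columns by well under 1%. The information vector
`I(i) = Σ_b f(i,b) ln(4 f(i,b))` ranges from 0 (uniform column) to
`ln 4` (one-hot column); it weights both the match score and the min/max
normalization, so positions with no preference contribute nothing to the
similarity. The core is fixed at the 5 consecutive positions with the
largest total information, matching the published definition of the MATCH
core. Ties in the core-window argmax resolve to the leftmost window.

Per-matrix thresholds default to core ≥ 0.90 and matrix ≥ 0.85. The
"minimize false positives" threshold profiles shipped with commercial
matrix libraries are proprietary; these defaults are a conservative
stand-in of comparable stringency and can be overridden per matrix via a
sidecar TSV (`matrix_id  core_thr  matrix_thr`). Both strands are
scanned; a minus-strand hit is stored at its forward-strand offset with
the forward subsequence, and consensus building reverse-complements it
back into motif orientation. Windows containing `N` never hit, which also
guarantees that hits never straddle the `N` spacers used to scan many
sites in one concatenated pass.

Degenerate matrices (max attainable score equal to min) produce a warning
and no hits rather than dividing by zero.

## Background construction and the enrichment statistic

Each true site gets one background interval of identical length drawn
from its vicinity: shift magnitude uniform on [1,000, 10,000] bp,
direction fair-coin, candidate redrawn (up to 100 times) if it leaves the
chromosome or overlaps any true site. Sites with no valid placement are
dropped from *both* groups so the two samples stay the same size — the
equal-`n` form of the statistic depends on it. Using real flanking
sequence rather than shuffled sequence keeps local composition in the
null.

Enrichment compares proportions of hit-covered nucleotides with the
pooled two-proportion z:

    z = (p_t − p_b) / sqrt( p̄(1−p̄) · 2/n ),  p̄ = (p_t + p_b)/2.

Coverage uses union footprint semantics: overlapping hits and both-strand
hits over the same bases count once. p-values are two-sided (depletion of
a motif class is as reportable as enrichment and is ranked by magnitude),
Bonferroni-corrected by the library size, and floored at the smallest
positive double; values below the printable range render as
`<1.0e-323`. When `p̄` is 0 or 1 the statistic is undefined and the
result is flagged non-significant rather than propagating a NaN p-value.

**Calibration and its limits.** The z test treats each nucleotide as an
independent Bernoulli trial. Under that sampling model it is accurately
calibrated: with both groups' covered-base counts drawn
Binomial(n, rate), the empirical type-I error over 1,000 replicate
10-matrix libraries sits inside the 95% binomial CI of the nominal 0.05
(the validation suite computes this). On real scans, however, a hit
covers ~L consecutive nucleotides (L = motif length), so covered bases
arrive in clumps: the effective number of independent units is roughly
n/L, the binomial variance understates the truth by a factor of about L,
and |z| is inflated by about √L. The test is therefore anti-conservative
on footprint data — visible in the validation runs as decoy matrices
reaching |z| ≈ 2–5 under a null plant rate. This is a property of the
per-nucleotide statistic itself, not of the implementation; rankings
(which is how the statistic is consumed) are unaffected, but the absolute
p-values of weakly-scoring matrices should be read with this in mind.

## Site geometry and annotation conventions

- Distances are measured from the site's reference point: the recorded
  summit if present (what peak callers report), otherwise the interval
  midpoint.
- Resizing centers a fixed-width window (default 1,000 bp) on the
  reference point; windows running off a chromosome end are shifted
  inward so every output has exactly the target length, preserving the
  equal-`n` premise of the enrichment statistic.
- Signed distance is `refpoint − TSS` for + strand genes and
  `TSS − refpoint` for − strand genes: negative is always upstream in
  transcription orientation.
- The six distance bins partition at ±5 kb and ±50 kb; `d = 0` and exact
  edge ties fall in the nearer/downstream bin (≤ edge counts as
  proximal, matching the "within 5 kb" reading). Percentages are
  `100·count/total` rounded half-up to two decimals.
- Nearest-gene ties (two TSSs exactly equidistant) resolve to the
  lexicographically smaller gene id, deterministically.
- A site is intronic if its reference point lies strictly inside a gap
  between consecutive exons of any gene — point membership, not interval
  overlap, so the flag is unambiguous for kilobase sites spanning
  several features.
- Two-set overlap merges all pairwise intersections into distinct common
  regions; the count and mean length are therefore symmetric in the two
  inputs.

## Expression calling and integration

Fold change is the linear-scale ratio of normalized mean intensities
(treated / control), reported as a signed ratio (`r` if `r ≥ 1`, else
`−1/r`) so thresholds read symmetrically (±1.30 by default, the more
permissive of the two thresholds used in the motivating study; ±1.40 is a
config value away). Absent-flagged genes are excluded before calling;
non-positive intensities are excluded with a warning. Integration
measures, per DE gene, the signed distance from its TSS to the nearest
site reference point, bins it with the same edges, and emits the ≤5 kb
(proximal) and ≤50 kb (associated) gene sets — the latter feeds the
pathway stage.

## Pathway enrichment

Upper-tail hypergeometric per pathway over a TSV catalog
(`pathway_id  name  gene_id`); the universe defaults to all genes with at
least one catalog pathway, and a supplied universe containing
catalog-orphan genes is rejected. FDR is Benjamini–Hochberg (the standard
step-up estimator; isolated behind `bh_fdr` should another estimator be
preferred). Pathways significant in two analyses are combined
conservatively with the larger p and the larger FDR.

## Synthetic data: what it emulates, and what it does not

The generator draws i.i.d. uniform A/C/G/T chromosomes, uniform TSSs with
fair-coin strands and 2–5 downstream exons, non-overlapping kilobase
sites (a configurable fraction tethered near randomly chosen TSSs at
2/20/80 kb to create known distance-bin structure), motif instances
sampled column-wise from the planted matrix (so scanner thresholds are
genuinely exercised — a sampled instance is *not* always detected, by
design), and lognormal two-condition intensities with planted signed fold
changes and multiplicative noise. Each generator uses its own RNG stream
derived from the master seed, so regenerating one artifact never perturbs
another, and all outputs are byte-deterministic under the seed.

Defaults (chosen once as the package's study conditions): 4 chromosomes
of 2/1.5/1/0.5 Mb, 300 genes, 150 sites of 1,000 bp, plant rate 0.3 into
true sites over a clean background, DE fraction 0.1 with |FC| uniform on
[1.5, 3] and ratio noise sd 0.05, 5% absent flags, 30% TSS-tethered
sites.

Not emulated: GC skew and repeat structure (a uniform background makes
chance hit rates lower and more homogeneous than in real genomes),
read-level noise and peak-calling artifacts (sites are exact intervals
with exact summits), probe-level microarray effects (the expression table
is already gene-level and normalized), and correlated gene regulation.
Passing tests therefore demonstrate the correctness and calibration of
the *computations* under their stated models — not robustness to
compositional biases of real genomes, which should be assessed with real
matched backgrounds (the background-from-vicinity design exists precisely
to absorb such biases).

## Validation experiments and problem sizes

The validation suite (also run by `scripts/acceptance.py`) uses: 1,000
replicate 10-matrix libraries at n = 100,000 nucleotides per group for
type-I calibration; 100 seeded simulate→plant→scan→enrich runs of 500
kilobase sites against 10 decoy matrices for planted-motif recovery
(the planted matrix must rank first in ≥95); 1,000 genes for DE recovery
(≥95% sensitivity, ≤5% false calls at ±1.30 with noise sd 0.05); and 500
sampled hits for consensus recovery of the fixed letters of
`G•ACA•••TGT•C` at dominance threshold 0.5 (strict inequality: a modal
base at exactly 50% renders as `•`). These sizes give tight binomial
error bars on every checked rate while keeping the full suite to a few
minutes on one CPU.

## Known limitations

- The per-nucleotide enrichment p-values are anti-conservative on real
  footprint data (see above); interpret rankings, not absolute tail
  probabilities, for marginal matrices.
- Decoy matrices are Dirichlet-sharpened random columns; they bracket
  chance-hit behaviour but are not drawn from real motif databases.
- The gene model is TSS + exon list; UTR/promoter sub-classification
  beyond the intron flag is out of scope.
- Background placement can fail for sites in very crowded or very short
  chromosomes; such sites are excluded (with a warning) rather than
  placed with relaxed constraints.
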