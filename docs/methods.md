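# Methods

This note records the models, conventions, parameter choices, and numerical
decisions behind cistromekit, and what the synthetic-data validation does and
does not demonstrate.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED convention), including every TSS
window: a window of half-width w covers `[tss − w, tss + w)`, so a peak
starting exactly at `tss + w` is outside it. Overlap means sharing ≥1 bp on
the same chromosome; strand is always ignored for overlap and windows.
Counting is peak-anchored: a peak overlapping several partners is one common
peak. These choices match the common defaults of interval tooling and the
counting style of co-binding studies ("peaks overlapping the other set are
counted as common peaks"); no minimum-overlap fraction is imposed because
none is standard for this analysis.

## Peak-set algebra

`intersect_partition` and `classify_dynamics` use a per-chromosome sorted
sweep with a cumulative-maximum end bound, so results are independent of
input order and near-linear for non-pathological peak sets. Both are tested
against O(n²) all-pairs oracles and, for stitching, against graph
connected-components (scipy.sparse.csgraph) as an independent route.

## Occupancy classes and enrichment

Genes are classed `common` / `A_only` / `B_only` / `none` by whether each
factor has ≥1 peak in the ±`occupancy_window_kb` (default 10 kb) TSS window.
"Occupancy" is binary — peak multiplicity inside the window is deliberately
ignored, the standard reading of "genes with peaks in proximity".

`resample_enrichment` draws each null gene set from the universe without
replacement (a random gene *set*, mirroring how query sets arise), with the
window default at 20 kb for this use. The odds ratio is
`observed% / mean(null%)`. Two p-values are reported: the +1-corrected
empirical upper-tail probability (primary — exact under the resampling null
and conservative under ties) and the one-sided one-sample t-test of the null
percentages against the observed value (secondary — a t-test on a bounded
percentage is approximate, but is the convention in the figure style this
reproduces). The universe is canonically ordered by gene_id before drawing,
so the result is invariant to permutations of the universe table and to
chromosome relabeling. Degenerate cases: an all-zero null with a nonzero
observation reports OR = +inf with a warning; all-zero everything reports
OR = 0.

`hypergeom_overlap` computes the upper tail P(X ≥ k) by log-space summation
of scipy's hypergeometric log-pmf. The universe size N is always passed
explicitly by the caller (genes passing the expression filter) — it is never
inferred, because overlap p-values are acutely sensitive to it.

## Regulatory potential and binding association

Each peak within `half_window` (default 100 kb) of a TSS contributes
`exp(−(0.5 + 4Δ))`, `Δ = |center − tss| / half_window`; peak position is the
interval midpoint (summit columns are not assumed). The decay constants and
window follow the established binding-and-expression target analysis tool;
both are exposed as parameters. The per-gene sum uses `math.fsum`
(correctly-rounded summation), which makes the score independent of
accumulation order and lets the vectorized implementation match a naive
per-gene loop bitwise.

For association, genes are ranked by decreasing RP with ties broken by
gene_id (determinism); each expression class's cumulative fraction over the
ranking is reported, and the up (resp. down) class is compared with the
static class by a one-sided two-sample KS test (alternative: the class sits
above the static class in the ranking). The full target-ranking and
permutation machinery of the upstream tool is out of scope; only this
binding-association half is implemented.

## Super-enhancers

Peaks are stitched when the gap (next.start − prev.end) is ≤
`stitch_distance` (default 12,500 bp; a 0 gap, i.e. touching intervals,
always merges). Optional promoter exclusion removes peaks lying fully within
±`tss_exclusion` (default 2,500 bp) of a TSS before stitching; it defaults
off. Regions are ranked by total track signal ascending and unit-scaled
(x = rank/m, y = signal/max). The cutoff is the slope-1 tangent point of
this convex curve — the region maximizing (x − y), i.e. the deepest point
below the diagonal — and super-enhancers are regions with signal strictly
above the cutoff signal. With all signals equal the scaled curve is
degenerate and zero super-enhancers are called, with a warning. No
input/control subtraction is applied by default (an optional control-track
hook exists) because the upstream tracks are assumed depth-normalized.

Per-region condition fold change is `log2((s_b + pc)/(s_a + pc))` with a
caller-chosen pseudocount (default 1.0) guarding empty regions.

## Signal tracks and pileups

Tracks are piecewise-constant runs; uncovered bases read as 0, and
quantification uses an exact antiderivative of the run structure (no
per-base loops). Pileup bins tile `[center − flank, center + flank)`
left-to-right with `center = floor((start + end)/2)`; a bin partially
outside the chromosome averages over its covered bases only and flags the
row, and `mean_profile` excludes flagged rows (erroring only when every row
is truncated). Tracks are consumed as provided — no internal depth
normalization.

bedGraph values are written with shortest round-trip float formatting and
parsed with round-trip precision, so write/read is bit-exact.

## Statistics

Signature scores use per-gene `z = (x − μ)/σ` with σ the sample (n−1)
standard deviation across all samples — "study SD" is not otherwise pinned
down, and n−1 is the safer default on small cohorts. Zero-variance genes are
dropped with a warning; absent genes are skipped, never imputed. Scores sum
to zero across samples by construction, a cheap integrity check. Class
comparisons use scipy's two-sided Wilcoxon rank-sum (exact for small
untied samples) with Benjamini–Hochberg adjustment across the pairs; the
2×2 regulated-gene-ratio test is a chi-squared without continuity
correction, matching the closed form `N(ad−bc)²/(r₁r₂c₁c₂)`.

## Synthetic data: what is planted and what is emulated

The generator plants, by construction rather than sampling:

* exactly `round(ρ·n_B)` B peaks each overlapping a distinct A peak
  (default ρ = 0.25, the shared-site regime of the studies this emulates);
* treatment dynamics of B: the weakest `loss_fraction` (default 0.59) of B
  sites removed and `gain_fraction` (default 0.14) weak new sites added —
  the persistent-sites-are-strongest regime — with shared-peak intensity
  scaled by exactly δ (default 0.5);
* unambiguous occupancy classes: TSSs are spaced ≥ 2× the full ±10 kb
  window and peaks are placed either fully inside a target gene's window or
  ≥ window + max peak width away from every TSS, so the planted per-gene
  class is exact, not approximate;
* expression: `log2FC = e_A·1[A-bound] − e_B·1[B-only] + N(0, σ_e)` with
  defaults e_A = e_B = 1, σ_e = 0.3 (free parameters of the generator — the
  real effect sizes linking binding class to expression are unknown); the
  signature is the `signature_size` B-only genes (ordered by gene_id; all
  B-only genes share the same planted effect);
* tracks: Gaussian bumps (SD = width/4, so ~95% of mass inside the peak;
  evaluated to ±4 SD) on a 10 bp grid over a constant background,
  run-length compressed. The acetylation-like track boosts co-bound sites
  3× (shared sites carry high acetylation) and, in the treated condition,
  attenuates B-only bumps by δ while A and shared-site bumps persist. The
  treated acetylation track deliberately models *attenuation* at all
  vehicle B-only positions rather than deleting bumps at lost binding
  sites: acetylation decays rather than vanishes when an activator leaves,
  and this is what makes the planted log2(δ) recoverable at B-dominated
  stitched regions. The A cistrome is condition-stable (loss/gain and δ are
  parametrized for B only).

Desk-scale defaults: 4 chromosomes × 7.5 Mb, 500 genes, 800 A and 600 B
peaks, 6 samples per condition, peak widths log-normal (median 500 bp,
floored at 100 bp and capped at 2,500 bp so window containment is
guaranteed), background 0.05 with bump amplitudes ~N(20, 5). These sizes
were chosen once to populate every occupancy class robustly (≈80 B-only
genes against a signature of 40) while keeping a full generate–write–analyze
cycle around half a minute.

Randomness: one integer seed; every stage consumes a named SeedSequence
substream (`genome`, `cistromes`, `tracks`, `expression`, `samples`), so
adding a stage never perturbs earlier draws and identical (config, seed)
yield byte-identical files. The manifest records the config, seed, and
SHA-256 of every file; replaying the manifest reproduces the digests.

What the generator does **not** emulate: read-level noise (no FASTQ,
fragment-length or GC models), peak-caller artifacts, copy-number or
mappability structure, correlated biological replicates, diploid genomes,
or realistic gene-density/enhancer clustering. Passing tests therefore
demonstrate the correctness and calibration of the integration arithmetic
under known ground truth — not robustness to upstream noise in real data.

## Validation design

Each operation is checked against an independent oracle: brute-force
all-pairs overlap, graph connected components, per-base pileup averaging,
exhaustive hypergeometric enumeration (universes ≤ 12), exact rank-sum
enumeration, closed-form decay values, and the generator's planted truth.
The resampling enrichment is calibrated under a uniform null (rejection at
p ≤ 0.05 stays near nominal over 2,000 replicates — slightly conservative
because the percentage statistic is discrete) and recovers a planted
five-fold enrichment within its null standard error. The end-to-end run
recovers the planted co-binding fraction exactly, the planted log2(δ) = −1
at B-dominated stitched regions within ±0.1, and a strong up-gene binding
association with no down-gene association — the asymmetry expected when
the profiled factor is a direct activator.

## Known limitations

* The linear sweep in overlap queries degrades toward O(n²) only for deeply
  nested interval piles, which peak calls do not produce.
* The SE cutoff is a geometric elbow; on curves without a clear hockey-stick
  shape the super-enhancer count is sensitive to the curve's tail (the
  all-equal degenerate case is handled explicitly, and the cutoff index is
  exact to ±1 on planted-elbow fixtures).
* The one-sided t-test p-value for enrichment is reported for convention
  but is approximate on a bounded statistic; the empirical p is primary.
* Expression classes for the association stage are thresholded on log2FC
  (defaults ±log2(1.5), static |log2FC| < 0.2); these thresholds are
  configuration, not inference.
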