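# Methods

## Coordinate and tag conventions

All coordinates are 0-based, half-open, in every reader, writer and
computation. Aligned reads are reduced to their 5′ base (interval start on
+, end − 1 on −) with no fragment extension; for MNase-digested
mononucleosome libraries the fragment is the nucleosome, so read-level
resolution is adequate, and an optional fixed shift is exposed for
sonicated material. Duplicate tags are retained.

## Promoter quantification

Each TSS is expanded to a symmetric window of ±`flank` bp (default 2000,
i.e. a 4 kb window). Windows clipped at a chromosome edge are kept and
flagged; their counts are not rescaled for lost width, so a clipped
promoter reads slightly low in both IP and H3, which largely cancels in
the ratio. The enrichment of mark *m* at a gene is

E_m = log2( ((c_m + p) / N_m) / ((c_H3 + p) / N_H3) )

with window counts *c*, library totals *N* and pseudocount *p* = 1 tag.
Design choices here were genuinely open:

* **Pseudocount.** p = 1 on both numerator and denominator keeps E finite
  and symmetric for zero-count windows and vanishes at typical counts
  (tens of tags). It makes enrichment exactly invariant under joint tag
  duplication only if p is scaled with depth; the property tests scale it
  accordingly.
* **Depth scaling.** Library-size division precedes the H3 ratio by
  default (`depth_scale`). The raw-ratio variant is retained behind the
  flag for sensitivity analysis. Note that with depth scaling E is a
  *composition* measure: it shifts by log2(N_H3/N_IP) relative to the raw
  in-window rate ratio, which matters when IP libraries concentrate a
  large fraction of their tags in enriched regions (see the synthetic
  generator below).

## Chromatin states

A promoter is "high" for a mark when E strictly exceeds `high_cut`
(default 2.5 — values exactly at the cut are not high), giving the four
states K4-only / K27-only / bivalent / neither. The alternative
peak-overlap definition calls a mark present when any called domain
overlaps the 4 kb window by at least 1 bp (the usual intersect default; no
minimum-overlap fraction). Scatter/threshold mode and peak-overlap mode
are both exposed, and each StateTable records which produced it. Replicate
tables can be combined by union or intersection of the implied per-mark
presence calls; the package defaults to keeping replicates separate
because the choice is analysis-dependent.

## Domain calling

Each chromosome is tiled in non-overlapping windows of `window_w` bp
(5000 for H3K27me3, 1000 for H3K4me3, matching histone-mode peak sizes; a
trailing partial tile is ignored). The observed window count is tested
against Poisson with mean equal to the flanking-region rate (counts in
±`flank_span` = 10·window_w, excluding the window, scaled to window
width), floored at the genome-average rate so that tag deserts cannot
manufacture fold enrichment. Benjamini–Hochberg control is applied across
all windows genome-wide at `alpha` = 0.001, and windows additionally need
fold ≥ 4 over the floored local mean. Significant windows within
`merge_gap` (= window_w) are merged; count, fold and Poisson p are
recomputed over the merged span, while the reported q is the minimum
member-window q — re-running BH on post-merge spans would change the
multiplicity universe mid-procedure. This caller approximates histone-style
broad-peak callers whose exact internals (clonality handling, input logic)
are not reproduced; it is validated by calibration properties: on uniform
libraries the false-positive window count is consistent with the BH level,
and implanted 10× domains are recovered essentially always.

The open question of whether the H3 control should enter the calling
statistic (rather than only the normalization) is resolved here as: no —
domains are called on the IP alone against its own local background, and
H3 enters through quantification. An input-corrected mode would be a
straightforward extension.

## Dynamics

Transition matrices are plain 4×4 census counts over a shared gene
universe, optionally restricted to a gene set; missing genes are an error
rather than a silent drop. Resolution percentages are reported alongside
their raw counts with nearest-integer (half-up) rounding, which reproduces
all published worked examples of the form "n of d (p%)". "Resolved" means
leaving the bivalent state for any other; "resolved to active" is
bivalent → K4-only specifically; both are exposed. Expression-by-state
comparisons use Welch's *t* by default (group variances differ by
construction in the generator and in real data); the pooled-variance
Student variant sits behind a flag. Outlier values are retained.

## Metaprofiles

Signal around the TSS is the per-gene, per-bin depth-scaled IP/H3 ratio
with the same pseudocount as quantification, averaged across genes
(ratio-then-average). The average-then-ratio alternative is exposed via
`ProfileConfig.ratio_then_average=False`; the two differ when H3 coverage
varies strongly across genes, and ratio-then-average was chosen so that
each gene contributes equally rather than proportionally to its H3 depth.
Default span is ±5 kb in 1 kb bins; a 20 kb preset mirrors wider
histogram-style views. Minus-strand genes are mirrored so upstream is
always left; reversing every strand flips the profile exactly.

## qPCR

Native ChIP plates: ratio Bound/Unbound = 2^(CT_unbound − CT_bound); the
matched IgG ratio is subtracted per target and replicate *before*
replicate averaging (the order is not standardized; per-replicate
subtraction propagates plate-level IgG variation into the SEM, which is
the conservative choice). Negative post-IgG values are clamped to 0 with a
warning. Cross-linked plates: % Input = 100·2^((CT_input −
log2(1/f)) − CT_IP) where *f* is the input fraction (0.10 when 10% of
chromatin is set aside), i.e. the input CT is dilution-adjusted before the
ΔCT. Re-ChIP plates are quantified the same way with the no-antibody
control subtracted like IgG. Amplification efficiency is fixed at 2, as
the ΔCT forms imply; primer-efficiency correction is out of scope.
Replicate aggregation reports mean and SEM = sd/√n (sample sd), with
single-replicate results flagged at SEM 0.

## Synthetic data generator

The generator defines the standard study conditions for all end-to-end
tests. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_genes | 400 | promoters on one chromosome |
| chrom_len | 100 Mb | single synthetic chromosome |
| min_spacing | 8 kb | TSS spacing (4 kb windows cannot overlap) |
| state proportions | 0.45 / 0.05 / 0.16 / 0.34 | K4-only / K27-only / bivalent / neither at t0 |
| lambda_h3 | 30 | mean H3 tags per 4 kb window |
| ip_high / ip_low | 12× / 0.5× | IP window rate as multiple of lambda_h3 |
| background_rate | 0.002 tags/bp | uniform background outside windows |
| expression means | 8 / 4.8 / 5 / 4.5 (sd 1) | per-state log-intensities |

Window counts are Poisson (a negative-binomial shape parameter is exposed
to stress-test overdispersion robustness), tag positions uniform within
their window, and the background uniform over the window complement. The
bivalent proportion of 16% sits in the 15–17% range reported for TSSs in
bipotential supporting cells, and K27-only promoters are rare (5%), as
observed. The two-timepoint mode draws t1 states through a row-stochastic
transition matrix whose default has bivalent promoters resolving
preferentially to K4-only (45%) and non-bivalent states mostly persisting
(≥ 90%).

Two scale choices deserve explanation because they interact with the
normalization. With 12×/0.5× multipliers the *raw* in-window log2 ratio is
log2(361/31) ≈ 3.5 for a marked promoter and ≈ −1 for an unmarked one,
straddling the 2.5 cut. Depth scaling shifts every E by log2(N_H3/N_IP),
and an IP library's total is inflated by its enriched windows; if
promoters occupied a large fraction of the genome this shift would push
marked promoters below the cut. The genome is therefore large relative to
its promoters (400 × 4 kb = 1.6 Mb of 100 Mb) with background dominating
library totals — exactly the regime of real ChIP-seq, where promoters are
a few percent of the genome and a minority of reads fall in peaks. Under
the defaults the shift is ≈ −0.5, marked promoters sit near E ≈ 3.1 with
sd ≈ 0.27, and threshold classification recovers ≥ 95% of true states
(measured: ~99.5%). Second, the in-window tag density (0.09 tags/bp at
marked promoters) stands ~45× above background, so the domain caller's
fold ≥ 4 requirement is attainable at 5 kb and 1 kb tilings alike.

What the generator does **not** emulate: mappability structure and
blacklist artifacts, GC bias, fragment-length effects, replicate batch
effects, overlapping genes (covered instead by dedicated tiny fixtures in
the counting tests), and carrier chromatin, which is an experimental
spike-in that enters no computed quantity. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to every artifact of real libraries.

## Problem sizes and determinism

The test suite and the acceptance script generate all data at run time:
the standard dataset (400 genes, ~1.5 M tags across six libraries) builds
in under a second, domain-caller calibration uses 100 uniform libraries of
10⁴ tags over 1 Mb, and expression power checks use 20 seeded replicates
at 200 genes per state. All randomness flows through numpy Generators
seeded from explicit integers; the same seed reproduces every output
byte-for-byte. The acceptance script derives all sub-seeds from its single
`--seed` argument.

## Known limitations

* The domain caller's q-values after merging are member minima, not a
  re-controlled FDR over merged regions.
* % Input assumes perfect doubling per cycle; primer efficiency and
  melt-curve QC are out of scope.
* Threshold-mode and peak-overlap-mode states agree to ~99% on clean
  synthetic data but will diverge more on real data with broad shallow
  K27me3 domains; the package deliberately reports both rather than
  reconciling them.
* Gene-set resolution denominators in published descriptions of the same
  event sometimes differ; the dynamics module treats each
  numerator/denominator pair as independent arithmetic and does not
  attempt reconciliation.
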