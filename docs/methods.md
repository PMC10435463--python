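# Methods

## Problem setting

Knockout of a transcription factor that drives histone-gene expression can
deplete a core histone (here H2B) and change its genomic occupancy.
Occupancy is measured by CUT&RUN/ChIP coverage in two conditions (Ctrl,
KO), each with replicate tracks. The pipeline asks three questions: which
genomic bins change occupancy, which gene-anchored regions (promoters and
gene bodies) change, and how those losses intersect the transcriptional
response measured by RNA-seq.

## Coordinate frame and annotation

All coordinates are 0-based half-open (BED convention); GTF input is
converted on read. Coverage is held at a fixed 50-bp step rather than per
base to bound memory at genome scale; every downstream mean is
length-weighted, so partial steps, partial bins, and sub-bin boundaries
that do not align to the step are handled exactly.

The promoter is the strand-oriented window TSS ± 2 kb (both extents
configurable); there is no community-universal definition, and this choice
is symmetric and conventional. A genomic point is classified with priority
promoter > exon > intron > intergenic; an interval is classified by its
midpoint. The midpoint rule keeps categories mutually exclusive so
distribution fractions sum to exactly 1, at the cost of ignoring partial
overlaps at bin edges. Three-way reports differ by context: changed-bin
distributions merge exon+intron into "gene body", peak distributions report
promoter/intron/intergenic plus an explicit "other" (exon) residual.

## Bin-level differential occupancy

Bins of 10 kb tile each chromosome (final bin may be short). Replicates
are paired by index: Ctrl rep *i* vs KO rep *i*. Within a pair, a bin is
*filtered* when the average of the two bin means is below 1 (a per-sample
variant is available via `filter_per_sample`); otherwise the KO/Ctrl ratio
is thresholded at 1.5-fold, boundary inclusive — a printed threshold is
treated as attainable. A zero Ctrl mean surviving the filter maps to an
infinite ratio, hence *up*, with a warning rather than an exception.
Consensus requires the same direction in ≥ k of n replicate pairs (default
2 of 3); bins where ≥ k pairs call unchanged and no direction reaches k are
*unchanged*; everything else — conflicts and filter-dominated bins — is
*none*. Inputs are assumed depth-normalised (e.g. CPM-scaled bedGraph);
between-sample normalisation is out of scope.

## Region-level test

For each gene, the promoter and the full gene body are divided evenly into
40 sub-bins (boundaries at start + round(i·len/40)) of length-weighted mean
signal, oriented 5′→3′. Per replicate, the 40 KO means are compared to the
40 Ctrl means with a two-sided Mann–Whitney U test:

- U counts pairs where the first sample exceeds the second, ties ½.
- Pooled size ≤ 12: exact p by enumeration of all C(n₁+n₂, n₁) group
  assignments, P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|). Enumeration is valid
  with ties, so the exact path does not require tie-free input.
- Larger samples (the 40-vs-40 default): normal approximation with
  tie-corrected variance n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5
  continuity correction (switchable). All-tied input returns p = 1 —
  no evidence, by convention.

A replicate calls a region changed only when p < 0.05 **and** the ratio
(mean KO + ε)/(mean Ctrl + ε) crosses 1.5-fold (ε = 10⁻⁶ guards all-zero
regions); the conjunction mirrors the bin rule's two-sided stringency.
Consensus is again ≥ k of n same-direction. No multiple-testing correction
is applied by default — the contract is a raw p cutoff — and the strictness
of the conjunction plus consensus is what controls false positives (see
calibration below). The region fold-change boundary is strict (> 1.5,
< 1/1.5) whereas the bin boundary is inclusive, matching how each rule is
stated.

The TSS metaprofile averages strand-oriented signal over [TSS − 3 kb,
TSS + 3 kb), resampled to 100 points per gene, genes first and then
replicate tracks; windows running past a chromosome end are zero-padded
and the affected gene ids returned as flagged.

## Expression

DEG calling is a pure fold-change rule: log₂((mean_KO + c)/(mean_Ctrl + c))
with strict threshold 2 applied symmetrically, pseudocount c = 0.1 FPKM,
and a low-expression floor of 1 FPKM on max(mean_Ctrl, mean_KO), checked
first. The pseudocount and floor are implementation choices (they prevent
infinite fold changes and spurious calls from near-zero FPKM); both are
configurable and their values are not part of the scientific claim.
Condition means are arithmetic means of FPKM across replicates, not means
of logs.

## Peaks and motif

Peak → gene assignment is nearest TSS from the peak midpoint with a 100-kb
cap and lexicographic tie-break; this is a deliberate, documented
reimplementation choice — nearest-TSS is the simplest defensible rule, so
absolute target-gene counts from other tools are not expected to match.
Motif matching is exact consensus matching (default TGACTCA, both strands,
overlaps reported, N never matches); a PWM interface is a stated extension
point, not implemented, because the canonical site is a single 7-mer. The
enrichment statistic is the number of peak sequences with ≥ 1 hit; the
null shuffles each sequence independently (mononucleotide
composition-preserving; dinucleotide shuffling is a possible extension)
and p = (1 + #{null rounds ≥ observed})/(1 + n_shuffles), so the smallest
attainable p is 1/(1 + n_shuffles).

## Synthetic data generator

The generator plants known truth at realistic scales and is the basis of
every end-to-end test. Defaults: 3 chromosomes × 4 Mb, 1000 non-overlapping
genes of 2–8 kb spaced ≥ one promoter window apart (so affected regions
never bleed into neighbours), 3 replicates per condition.

- **Coverage**: per-step mean 10 over each gene's promoter ∪ gene body and
  10/5 = 2 elsewhere. Values are negative-binomial counts drawn at
  `depth_scale` (5) times the target mean and divided by `depth_scale`,
  the shape depth-normalised coverage takes; with NB size 50 this gives
  CV = √(1/(10·5) + 1/50) = 0.20 at mean 10 — a plain NB at mean 10 cannot
  reach CV 0.2 (its CV² is bounded below by 1/mean = 0.1), which is why
  the depth-normalised form is used. KO multiplies the mean over affected
  genes' spans by `occupancy_effect` (default 0.5, a 2-fold loss).
- **Truth sets** are assigned by exact counts (round(fraction·n)), not
  Bernoulli draws, so recovery metrics have fixed denominators. The
  occupancy-down set (20% of genes) and DEG labels (20% up at log2FC 3,
  5% down) are independent draws, so co-labeled genes exist at the product
  rate — the integration layer's target.
- **Expression**: baseline log₂ FPKM ~ N(4, 1); replicate noise log₂-normal
  with sd 0.25.
- **Peaks**: 200 peaks of 200 bp, 40% centred within ±500 bp of a random
  TSS and the rest uniform; uniform ACGT sequences with one motif instance
  (random strand and offset) planted in 80%.
- **Determinism**: every stream derives from `SeedSequence((seed, *key))`
  with distinct keys per stage and per (condition, replicate); identical
  configs are bit-identical.

What the generator does **not** emulate: fragment-level reads, GC and
mappability bias, unmappable/blacklist regions, overlapping or nested
genes, correlated replicate artefacts, and peak-calling noise. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the stated noise model, not that real datasets are free
of these confounders.

## Calibration and recovery (computed by the test suite and acceptance script)

With no planted effect (occupancy_effect = 1), the conjunction of p < 0.05,
1.5-fold, and 2-of-3 consensus holds both the changed-bin rate and the
consensus-down gene rate at or below 1%. With the default planted effect
(2-fold loss, 200/1000 genes), region-level consensus reaches sensitivity
≥ 0.90 at false-discovery proportion ≤ 0.10, and the recovered
occupancy-down ∩ up-DEG set matches the planted co-labeled set at
Jaccard ≥ 0.85. The motif shuffle test on unplanted sequences rejects at
≈ 5% at α = 0.05. Problem sizes in the suite (genomes of 0.8–12 Mb,
500–1000 genes, 100–1000 shuffle rounds) were chosen so each statistical
check has adequate resolution while the whole suite stays fast.

## Numerical and degenerate-input conventions

- Length-weighted means throughout; sub-bin boundaries by rounding, which
  keeps boundaries strictly increasing whenever region length ≥ n_bins.
- Ratio guards: ε in region ratios; bins handle zero Ctrl as +∞ (up).
- Empty overlap reports, empty changed-bin directions, and zero-DEG
  summaries return empty/None rather than raising.
- Report JSON is written atomically with sorted keys; identical inputs and
  seed give byte-identical output.

## Known limitations

- Counts at genome scale (total peaks, bins, absolute overlap sizes) are
  properties of a real dataset and its upstream alignment/peak calling;
  the pipeline reproduces rules and rates, not those absolute numbers.
- The Mann–Whitney sub-bins of a region are spatially autocorrelated in
  real data (the test treats them as exchangeable units); the consensus
  and fold-change requirements mitigate, but do not remove, this.
- Consensus-based calling has no graded confidence; p-values are per
  replicate and uncorrected by default (a Benjamini–Hochberg helper can be
  layered on the per-replicate p's if desired).
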