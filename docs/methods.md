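# Methods

## Scope and model of the data

The pipeline analyzes a two-genotype (wild type vs. decay-factor mutant)
bulk RNA-seq design over three developmental periods — oogenesis
(stages O1–O4), mature eggs (UNA/ACT/FER), embryogenesis (E1–E4) — with
three replicates per genotype and stage. Because the system is
transcriptionally silent across this window, genotype differences in
transcript abundance are interpreted as differences in RNA decay; genes
up-regulated in the mutant are candidate degradation targets, and the
positional signature of 3′-to-5′ exonucleolytic attack is a relative
enrichment of mutant reads toward transcript 3′ ends.

All internal coordinates are 0-based half-open; conversion happens only
at format boundaries (GTF is 1-based inclusive, BED/bedGraph 0-based
half-open). All region analyses operate in transcript coordinates with
position 0 at the biological 5′ end. Where a gene has several isoforms,
only the longest is used; a length tie is broken by the lexicographically
smallest transcript id so results are deterministic. Transcripts without
an annotated CDS are retained for full-length/metagene analyses but
excluded from region-density and CAI analyses.

## Differential expression

Counts are modeled per gene as negative binomial with
Var = μ + μ²·d (dispersion d ≥ 0). The test is a simplified exact test:
replicate counts are scaled to a common effective library size (the
geometric mean of the library sizes), summed per group, and the wild-type
group sum is compared with its conditional distribution given the total
under the null of a common per-replicate mean — group sums are NB with
per-group dispersion d/n, and the d → 0 limit is the conditional
binomial(total, n_wt/(n_wt+n_mut)) test. The two-sided p-value sums all
outcomes whose probability mass does not exceed that of the observation
(minimum-likelihood rule), which makes swapping the groups preserve p
exactly. This is deliberately simpler than a full edgeR-style moderated
analysis (quantile-adjusted likelihoods, TMM factors, tagwise shrinkage);
externally produced DE tables can be imported through
`decaylens.deg.load_de_table` and drive every downstream module
unchanged.

Choices that matter:

* **Filter** — a gene enters a period's analysis if it has ≥ 10 cpm in
  ≥ 3 of the period's libraries, pooled across genotypes and stages. The
  boundary is inclusive on both counts.
* **Dispersion** — if not supplied, a common dispersion is estimated by
  method of moments as Σ(v−m)/Σm² over within-group means/variances of
  library-scaled counts (ratio of sums for stability at n = 3, floored at
  0). On 5000-gene null simulations at d = 0.05 this yields a realized
  type-I rate near 0.04–0.07 at nominal 0.05.
* **Fold change** — mutant/WT ratio of per-replicate normalized group
  means with a pseudocount of 0.5 on each mean, so zero counts give
  finite log fold changes.
* **Multiple testing** — Benjamini–Hochberg step-up within each stage's
  tested gene set, with enforced monotonicity (FDR ≥ p elementwise).
* **Classes** — up/down require FDR < 0.05 (strict); unchanged requires
  FDR > 0.05 and 0.8 < FC < 1.2 (strict); everything else tested is
  `other`; genes failing the filter are `filtered`. The partition is
  exhaustive and exclusive; a gene at exactly FDR = 0.05 is `other`.
* **PCA** — log₂(cpm+1) on the 1000 most variable genes, centered SVD.
  This transform stands in for a regularized-log transform; the embedding
  is used qualitatively (clustering by factor), and only its linear-algebra
  invariants are asserted. The sign convention (largest-|loading| gene
  positive per component) makes coordinates reproducible.

## Overlap against expression-matched nulls

Sharing between two DEG sets is judged against resampled control sets
drawn from unchanged genes and matched to the DEG set's wild-type
expression distribution: genes are binned into 20 quantile bins of WT
mean TPM computed over DEG ∪ pool, and one control per DEG is drawn
uniformly without replacement from the same bin (an exhausted bin falls
back to the nearest non-empty bin; every such move is recorded, and with
adequately large pools there are none, making the control and DEG bin
histograms exactly equal). Two significance summaries are reported,
since the exact 2×2 construction used historically for this comparison
is a matter of convention: (i) a Yates-corrected Pearson χ² comparing the
observed shared proportion against the rounded mean control proportion,
and (ii) the empirical quantile of the observed count among the control
counts — both a deterministic mid-quantile and a randomized PIT quantile
(exactly uniform under exchangeability), the latter being the one used
in calibration tests. "Shared period DEGs" are genes in the same class
at every stage of a period; cross-period status uses the precedence
DEG-at-any-stage > unchanged-at-any-stage > other, with
filtered-everywhere reported as untested.

## Coverage profiles and region densities

Metagene profiles rescale each transcript's coverage onto 100 equal-width
bins with fractional positions weighted by proportional overlap, so
binning conserves total coverage to machine precision. Each transcript
is first normalized by its own mean depth and the per-gene bin vectors
are averaged unweighted — otherwise a handful of highly expressed genes
dominates the profile. Transcripts shorter than 100 nt or with zero
coverage are excluded (and counted), never zero-filled. Replicate tracks
are averaged at the coverage level before binning.

Region read density is reads per nucleotide of 5′UTR/CDS/3′UTR, a read
being counted once for **every** region it overlaps by ≥ 1 nt. The
3′-bias statistic is the per-gene mutant/WT density ratio per region:
both-zero cases are not considered; WT-zero/mutant-nonzero cases are
likewise excluded (rather than reported as infinite) but tallied under a
separate flag so the choice is auditable. Group-level shifts are tested
with a two-sided unpaired Wilcoxon rank-sum test per region (pairing is
not assumed; the asymptotic normal approximation without continuity
correction is used, and a fully tied comparison is reported as p = 1).

## Transcript features

CAI is the geometric mean, computed in log space, of
w(codon) = f(codon)/max f over its synonymous family, across scored
codons. Stops and the single-codon families ATG (Met) and TGG (Trp) are
excluded — their w is 1 by construction and would only dilute the
index — as are codons containing ambiguous bases; all exclusions are
configurable and counted per gene. A scored codon with zero usage
frequency gets w floored at the equivalent of a half count
(0.5/family-max) and is flagged, keeping ln w finite. Usage tables may
carry counts or per-thousand frequencies; they are normalized internally,
which provably leaves every w (and hence every CAI) unchanged. The
random-sequence background draws as many sequences as the compared group
(500 if the group exceeds 1000), each with the group's mean CDS codon
count, codons sampled proportionally to usage with stops excluded so the
scored length is exact.

Length comparisons (full, 5′UTR, CDS, 3′UTR) and CAI comparisons between
DEG classes use the two-sample two-sided KS test; expression-level
comparisons of DEG classes (up vs. unchanged, down vs. unchanged on WT
TPM) use the Wilcoxon rank-sum test.

## Synthetic-data generator

The generator emulates the study design so the pipeline is testable
without any download. Defaults (chosen once as the conditions the
pipeline is validated under): 2000 genes; log-normal region lengths
(medians ≈ 150 nt 5′UTR, 900 nt CDS, 500 nt 3′UTR); log-normal relative
abundance (σ = 1.2); library sizes log-normal around 10⁶ (σ = 0.15) to
exercise cpm normalization; NB dispersion 0.05 (a typical low-replicate
bulk RNA-seq value); 10% of genes "stabilized", selected with probability
∝ exp(−4·rank/n) of baseline expression so the subset concentrates at
low wild-type expression in a graded way; each stabilized gene gets one
period in which its mutant mean is multiplied by 4; mutant coverage of
stabilized genes in their period places read starts with density
∝ exp(4·x/L); the stabilized subset is simultaneously the rare-codon
subset, its synonymous-codon choice mixed half-way (codon_bias 0.5)
toward an inverted-frequency table while preserving amino-acid
composition; reads are 50 nt, 200,000 per genotype coverage set. One
global seed is split into fixed per-component and per-stage substreams,
so outputs are byte-reproducible and one stage's draws do not perturb
another's. The built-in codon usage table is synthetic (geometrically
graded preferences within each family); any Kazusa-style table can be
supplied.

What the generator does **not** emulate: sequencing error, positional
fragmentation bias beyond the single 3′-shift term, polyA-tail dynamics,
isoform complexity (one transcript per gene), between-stage correlation
of expression, and composition-driven normalization artifacts beyond the
small library-mass shift the stabilized genes induce. Passing
recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the modeled structure, not that the
biological effect sizes of any real dataset are reproduced.

## Numerical choices and degenerate inputs

* Exact-test p-values are computed from the full conditional pmf
  (vectorized over 0..total), so they are reproducible to machine
  precision; both-groups-zero returns (FC = 1, p = 1).
* BH adjustment uses a stable mergesort and enforces monotonicity.
* Binning integrates the piecewise-constant depth via its cumulative sum
  evaluated at fractional bin edges (conservation tolerance 10⁻⁹ in
  tests, typically exact to round-off).
* PCA of fewer genes than requested uses all genes with a warning; two
  identical samples embed at distance zero.
* The matched-control sampler and all simulators accept explicit
  generators or integer seeds; identical seeds give identical outputs.

## Problem sizes used in validation

The shipped test-suite and acceptance runs use 2000-gene simulations for
parameter recovery, a 5000-gene single-stage null for test calibration,
200 seeded runs (40 resamples each) for overlap-quantile uniformity, and
1000 random sequences against an arbitrary-precision oracle for CAI —
sizes at which every calibration band and recovery threshold is met with
margin while a complete run stays in the minutes range on one CPU.

## Known limitations

* The NB exact test is not numerically equivalent to edgeR/DESeq2;
  normalization is library-size only (no TMM/RLE), so strongly
  composition-shifted libraries will bias fold changes.
* The χ² overlap construction compares observed vs. mean-control
  proportions; other historical 2×2 conventions exist, which is why the
  resampling quantile is co-reported.
* Coverage analyses operate purely in transcript coordinates; how reads
  spanning exon junctions were assigned upstream is outside the model.
* CAI exclusions follow the classical definition; other implementations
  differ in their treatment of single-codon families and zero
  frequencies, so absolute CAI values are comparable only within one
  configuration.
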