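# Methods

This note documents the models, estimators and numerical choices behind
`hmcpipe`, and what the built-in synthetic data can and cannot establish.

## 5mC/5hmC estimation from paired BS/oxBS arrays

Bisulfite conversion leaves both 5-methylcytosine (5mC) and
5-hydroxymethylcytosine (5hmC) unconverted, so a BS beta value reads
m + h; oxidative bisulfite first oxidizes 5hmC so an oxBS beta reads m
alone. Per probe and sample:

    h_raw = beta_BS - beta_oxBS      m_hat = beta_oxBS
    h_hat = max(h_raw, 0)

`h_raw` can be negative under technical noise. All delta-beta contrasts
and correlations are computed on the **unclipped** `h_raw`: clipping at
zero would censor the noise distribution asymmetrically and bias
between-group differences toward positive h. The clipped `h_hat` is used
only when a state level is reported. Both are always emitted. Since
`m_hat + h_hat = max(beta_BS, beta_oxBS) <= 1` for in-range betas, the
joint-rescaling guard (divide both by m + h) exists only as a defensive
invariant.

Differential calling uses the strict rule `|delta beta| > threshold`
(default 0.05, the conventional array effect-size floor; a delta exactly
at the threshold is not called). For designs with >= 3 replicates a
per-probe Welch t-test with Benjamini-Hochberg adjustment can be attached
and combined with the threshold; the default duplicate design uses
threshold-only calling. Condition profiles are standardized row-wise with
the sample (n-1) standard deviation; constant rows become zeros and are
flagged.

## Genomic-context annotation and enrichment

Each probe gets exactly one feature class with priority
promoter > enhancer > gene_body > intergenic (promoters are strand-aware
TSS -1000/+500 bp windows) and one CpG-context class from its distance
`d` to the nearest CpG island: island (d = 0), shore (0 < d <= 2000),
shelf (2000 < d <= 4000), open sea (d > 4000); boundary distances fall
into the nearer-island class. Enrichment of a probe or gene selection
against its universe is the exact hypergeometric tail of the 2x2 table,
reported one-sided in both directions with BH adjustment across classes
within each direction; the same routine backs gene-set and motif
enrichment so every Fisher-type p in the package comes from one
implementation.

## eRNA annotation from nascent coverage

Transcribed units are called on coverage pooled across all samples (an
annotation segmented per condition would bias differential tests), then
quantified per sample. Segmentation is a threshold/gap/length scan on
10 bp bins: maximal runs with coverage >= tau, merged across
sub-threshold gaps of <= 200 bp, dropping merged runs shorter than
200 bp. When tau is not supplied it is chosen per pooled track as the
smallest integer >= 2 at which the expected number of bins reaching it
under a Poisson background — rate set to the track's mean bin coverage —
falls below 0.1% of bins. This keeps isolated background reads
sub-threshold at any depth while sitting far below block-like signal; a
fixed quantile of nonzero bins was rejected because in gene-dense tracks
the nonzero-bin distribution is dominated by genic signal, which would
push the threshold above eRNA coverage entirely.

Segmented intervals overlapping any gene padded by 1 kb are genic.
Remaining intergenic intervals on opposite strands whose spans lie within
1 kb merge (transitively) into single bidirectional eRNA units — the
characteristic divergent transcription of active enhancers — spanning the
union of their sources; ids are `chrom:start-end`, so the unit set is
independent of processing order. Genic units are quantified on their own
strand, eRNA units across both strands, by summing bins overlapping the
span.

## Negative-binomial differential expression

Counts K ~ NB(mu, alpha) with Var(K) = mu + alpha mu^2. Normalization is
median-of-ratios size factors (pseudo-reference fallback on counts + 0.5
when no feature is nonzero everywhere). Dispersion is estimated per
feature by method of moments on normalized counts pooled within
conditions, then stabilized in three steps:

1. a parametric trend alpha(mu) = a0 + a1/mu, fitted by least squares in
   *linear* dispersion space (the moment estimates are mean-unbiased;
   fitting their logs would inherit the downward median bias of a skewed
   chi-square statistic), with one outlier-trimming pass;
2. empirical-Bayes shrinkage of log alpha toward the trend with an
   adaptive weight: the sampling variance of a log chi-square at the
   design's residual degrees of freedom divided by the robust (MAD-based)
   residual variance around the trend. Data consistent with the trend
   collapse onto it; genuinely heterogeneous dispersions retain
   per-feature signal. A fixed weight can be supplied instead;
3. median recentering onto the trend, cancelling the remaining median
   bias of the log moment estimator (worst at 2-3 replicates).

The Wald statistic is log(mu2/mu1) over fitted normalized group means with
the delta-method standard error sqrt((1/mu1 + alpha)/n1 +
(1/mu2 + alpha)/n2) and a two-sided normal p-value; group means are
floored at a quarter count so zero groups stay finite and conservative,
and all-zero features are reported with p = 1. Reported log2FC carries a
0.5 pseudo-count; the test does not. BH adjustment is applied within each
feature kind, with default significance at adjusted p < 0.05 for genes
and < 0.1 for eRNAs. Measured on null NB data (5000 features, 3 vs 3,
alpha = 0.05) the raw-p type-I error sits at 0.053-0.065.

## Integration analyses

* **Enhancer-promoter pairing**: every (significant eRNA, significant
  gene) pair with |enhancer midpoint - strand-aware TSS| <= 500 kb,
  optionally requiring direction concordance (the default). Anchor points
  are a package choice; distances are signed (TSS minus midpoint).
* **Overlap test**: upper-tail hypergeometric P(X >= k) for two id sets
  in an explicit universe. The universe is a required parameter because
  overlap significance is undefined without a stated background; the
  pipeline uses all features tested in both contrasts.
* **Preranked GSEA**: weighted Kolmogorov-Smirnov running sum (weight
  p = 1; hits step up by |score|^p normalized, misses down by
  1/(N - n_set)); ES is the extreme of the running sum. Significance by
  gene-label permutation (random same-size sets, default 1000): NES =
  ES / mean |same-sign permuted ES|, p with +1 smoothing so it is never
  zero. Gene-level (not phenotype) permutation is the only option because
  the ranking is precomputed.
* **Methylation retention**: per-probe group-mean delta beta between a
  baseline and a treated sample set; a probe is retained when
  |delta| < 0.05 (the same delta-beta convention as calling). The
  pipeline's "global" comparison set is taken from the BS
  (total-methylation) hyper calls: a 5hmC->5mC exchange leaves the BS
  beta unchanged, so an oxBS-defined set would count such invariant
  probes as spuriously retained.

## Motif analysis

PWMs (simple text format: `>id` plus one row of four probabilities per
position) are scored as log2 odds against the background composition with
pseudocount 0.01; both strands are scanned and a window is a hit at
>= 80% of the maximal achievable score. N bases score zero. Enrichment is
sequence-level presence (the "% of target sequences with motif"
convention) in targets vs background via the shared exact Fisher routine;
when no background is supplied a seeded mononucleotide shuffle of the
targets is used. Benchmarks plant consensus sites: a sampled site with
one low-probability base legitimately scores below the 80% threshold, so
sampled planting would measure site degeneracy rather than scanner
behaviour.

## The synthetic-data generator

The generator emulates the study design this pipeline targets: an
IDH-mutant-like condition (MUT) against wild type (WT) and two inhibitor
timepoints (MUT_T4, MUT_T7), two replicates per condition throughout (the
duplicate design of the emulated assays).

**Genome** (defaults): 4 chromosomes x 6 Mb; 1000 non-overlapping genes of
2-10 kb with >= 2 kb clearance; 300 enhancers (>= 2 kb from genes); 350
CpG islands of 0.5-2 kb; ~19,500 probes placed inside islands, at graded
shore/shelf/open-sea distances, in promoters/gene bodies/enhancers, and
uniformly in intergenic space. Feature placement is rejection sampling
with bounded retries; infeasible geometries raise a placement error
naming the feature class. A contiguous run of 12 chr1 genes forms the
`HLA_like` cluster carrying a dense block of 116 probes (the size of the
HLA class I probe set in the motivating patient analysis).

**Methylome truth**: baseline m from a bimodal beta mixture, baseline h
from Beta(2, 28); planted sets are disjoint. 5hmC loss/gain sites default
to the study's absolute counts 2156/664 (the 3:1 loss skew) and are drawn
with 3x enhancer / 2x open-sea over-representation and promoter/island
under-representation; 5mC hyper/hypo default to 3000/1400, preserving the
~2.2:1 hyper skew at array scale. Each planted probe draws its own effect
from U(0.5, 1.5) x delta_effect (default 0.2). 5hmC changes trade h
against m one-for-one, so anti-correlation of the two marks is a
construction property, and total (BS) methylation at those sites is
invariant. Treatment moves every planted effect back toward WT by the
reversal fraction (0.8 at T4, 0.9 at T7) — except the HLA-like probes,
which stay hypermethylated (the non-responder phenotype). Planted
baselines keep 0.08 headroom from the [0, 1] boundaries (and 5hmC sites
keep m >= 0.08 — 5hmC is oxidized 5mC, so h-positive sites retain some m);
without that headroom the observation clipping piles betas at the
boundary and visibly biases observed deltas.

**Observation noise**: each observed beta is truth plus zero-mean
Gaussian noise truncated to [0, 1], marginal s.d. 0.03. The variance is
split into a component shared between the BS and oxBS measurements of the
same biological replicate (share 0.85; same DNA aliquot, same array
position) and an assay-specific remainder. The shared part cancels in
BS - oxBS — the cancellation that makes paired designs informative about
5hmC at realistic noise levels — leaving an effective h-contrast s.d. of
~0.016 at two replicates. Array heteroscedasticity (variance depending on
beta) and probe-specific effects are *not* modeled; a logit-normal noise
model was rejected as unnecessary at delta-beta scale.

**Transcription**: every gene is a rectangular strand-specific coverage
block on 10 bp bins; 200 of the 300 enhancers are transcribed
bidirectionally (divergent blocks of 300-800 bp with a 0-200 bp gap at
the midpoint). Per-unit counts are gamma-Poisson (NB) draws with
dispersion 0.05, gene means log-uniform on [50, 2000], eRNA strand means
on [40, 200]; reads are scattered multinomially over the unit's bins and
sparse Poisson background noise (0.002 reads/bin/sample) is added.
Planted DE: 60 genes down (including the cluster at log2FC -1.5) and 45
up at |log2FC| in [1, 2.5]; 10 down genes are rescued at T7 (the overlap
analysis analogue); 30/18 eRNAs up/down; 8 enhancer-promoter pairs place
a concordantly de-regulated eRNA within 500 kb of a DE gene's TSS.
Spike-in normalization is not modeled: samples have equal depth up to
size factors. With noise disabled, counts equal rounded means and all
estimators recover truth exactly.

**Seeding**: one seed per stage expands into named substreams via
`SeedSequence.spawn` in a documented order (genome: genes, enhancers,
islands, probes; methylome: baseline, assignment, effects, noise;
transcription: expression, DE assignment, counts, reads, background), so
any stage regenerates independently and identical configs are
byte-identical end to end.

**What passing tests show — and don't.** Recovery and calibration results
on this generator demonstrate internal correctness of the estimators
under the stated noise model at desk scale (single-digit-second runs on
one CPU). They do not establish performance on real arrays (probe-level
heteroscedasticity, detection failures, batch structure), real TT-seq
(non-rectangular coverage, length biases, spliced contamination), or
real genomes (overlapping features, repeat content); headline counts from
the motivating study depend on its deposited data and cohorts and are
mirrored here only qualitatively.

## Benchmark problem sizes

The statistical benchmarks run at: 5000 features for DE calibration
(3 vs 3; power measured on 1500 planted 2-fold features among 5000 —
the planted fraction matters because the BH threshold scales with the
number of discoveries, and 30% planted places the benchmark clearly
inside the detectable regime identified by a power analysis); 1000
random tables for the Fisher and BH oracles; 100 random tracks (<= 10^4
bins) for the segmentation oracle; 1000 permutations for GSEA; 100
target + 1000 background sequences of 500 bp with 10 decoy PWMs for
motif recovery.

## Known limitations

* Threshold-only delta-beta calling has no error-rate control; its FDR is
  a property of the noise level and is reported against truth only on
  synthetic data.
* The Wald test is slightly anticonservative below three replicates;
  duplicate designs should lean on effect-size thresholds as the pipeline
  defaults do.
* The eRNA caller is a deliberate threshold/gap/length stand-in, not an
  HMM segmenter; it has no notion of expression-matched input control.
* `pair_enhancer_promoter` reports all window-concordant pairs; with
  dense gene annotations most enhancers have some gene within 500 kb, so
  pair counts are upper bounds on true regulatory links.
* Single-factor designs only; no batch covariates, no independent
  filtering, no array normalization or detection-p filtering.
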