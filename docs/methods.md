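# Methods

## Scope and model

`splicescape` profiles alternative splicing from transcript-level
quantifications (the Salmon `quant.sf` layer) across groups of samples
("phenotypes", e.g. a tissue and two derived cell lines). It deliberately
works with two complementary descriptions of a splicing landscape:

1. **DAS — degree of alternative splicing.** For gene *g* and sample *s*,
   `DAS(g, s)` is the number of splice variants of *g* detected in *s*
   (TPM strictly above a threshold, default 0). The DAS matrix replaces the
   expression matrix in a two-class gene-set enrichment analysis ("SPEA"),
   so a positive NES for a pathway means its genes carry, on average, more
   detected isoforms in phenotype 1 than in phenotype 2.

2. **τ — graded specificity of single splice variants.** For a feature with
   phenotype-mean abundances c₁..c_N,

       τ = Σᵢ (1 − Xᵢ) / (N − 1),   Xᵢ = cᵢ / maxⱼ cⱼ,

   so τ = 0 for a uniform profile and τ = 1 when expression is confined to
   one phenotype. τ is computed both per splice variant and per gene, the
   gene profile being the component-wise sum of its variants' profiles
   (sum-of-means and mean-of-sums commute for arithmetic means; the code
   uses sum-of-means). Classes: ubiquitous (τ < 0.15), specific (τ > 0.85),
   strict (τ = 1), intermediate otherwise.

Exon-level metrics (PSI, exon usage) are out of scope by design: with
long-read quantification the isoform itself is the observable.

## Numerical choices

* **τ = 1 is exact.** Xᵢ is taken as 0 whenever cᵢ = 0, so a
  single-positive-component profile evaluates to exactly 1.0 in floating
  point and the strict class needs no tolerance. All-zero profiles have no
  defined normalization; their τ is NaN and they are excluded from reports
  rather than forced to 0 or 1. Argmax ties leave the assigned phenotype
  undefined (such features have τ < 1 and can never be strict).
* **Strict selection.** A feature is strictly phenotype-specific when τ = 1
  *and* it is detected in every sample of its argmax phenotype (gene level:
  at least one of its transcripts per sample). Stability for SPEA inputs is
  evaluated per gene over the union of the two compared phenotypes' samples;
  a stricter single-transcript reading is available via `stable_mode`.
* **Rarefaction.** Depth is equalized by a multivariate hypergeometric draw
  per sample (sampling reads without replacement), not binomial thinning, so
  rarefied totals equal the target exactly and cells never exceed their
  original counts. The original study downsampled at the read level and
  re-quantified; rarefying transcript counts directly is a documented
  approximation of that step, and TPM is recomputed from the rarefied counts
  with the effective-length convention (rate = count / effective length,
  scaled to 10⁶ per sample).
* **SPEA ranking.** score(g) = (μ₁ − μ₂) / (σ₁′ + σ₂′) on DAS values with
  the two-class GSEA variance floor σ′ = max(σ, 0.2·|μ|) (σ′ = 0.2 at
  μ = 0); σ is the sample standard deviation (ddof = 1). Ties break
  lexicographically on gene id so runs are bit-reproducible. Groups with a
  single sample need `metric="diff"` (plain mean difference).
* **SPEA null and statistics.** ES is the weighted Kolmogorov–Smirnov
  running-sum statistic (weight 1 by default); the null is gene-set
  permutation — ES of uniformly drawn member sets of the same size, shared
  between sets of equal size, 1000 permutations by default. NES divides ES
  by the mean |null ES| of the same sign; nominal p is the same-sign tail
  with an add-one correction (b+1)/(m+1); FDR q compares the observed NES
  distribution with the pooled sign-normalized null NES distribution per
  side, clipped to [0, 1] (a proportion-ratio estimate above 1 carries no
  information). Significance: |NES| > 1.5, p < 0.05 and q < 0.25.
  The observed ES is computed through the same vectorized candidate
  arithmetic as the null sample: the running sum is piecewise linear between
  hits, so its extremes are evaluated only at hit boundaries, and a single
  summation order avoids sign flips on exact positive/negative ES ties.
* **Known small-set limitation.** Under gene-set permutation the null ES of
  very small sets is inflated (a 2-gene set on a short list has mean null
  |ES| ≈ 0.7, capping attainable |NES| near 1.4). Sets of ≥ ~10 members on
  realistic list lengths behave well; conclusions about 2–3-gene sets
  should not rely on the NES threshold.
* **ORA.** Upper-tail hypergeometric P(X ≥ k) with Benjamini–Hochberg
  correction across the collection. The universe defaults to the genes
  retained in the abundance table (expressed, biotype-filtered), a standard
  guard against expression-background bias.

## Synthetic data generator

The generator emulates the post-quantification layer of a three-phenotype
long-read study and is the substrate for every end-to-end test. Defaults
(one per line, with why):

* design: HepG2 × 5, Huh7 × 3, liver × 3 — the 11-biosample layout of the
  motivating study design.
* `n_genes = 2500`, isoform counts 1..6 with probabilities
  (0.30, 0.25, 0.18, 0.12, 0.09, 0.06) — ≈ 2.6 isoforms/gene, matching the
  ~2 variants/gene ratio typical of transcript-level tables.
* abundance: per-transcript log-normal with `log_mean = 1.5`,
  `log_sd = 1.5` (natural log of an arbitrary expression unit), per-sample
  multiplicative log-normal noise `noise_sd = 0.4`.
* `dropout_tpm = 1.0`: a *hard* threshold on the pre-normalization level —
  below it a transcript is unexpressed in that sample. Hard rather than
  probabilistic dropout keeps the planted ground truth exact.
* `library_size = 120000` (±15% per sample): ≈ 20 reads per transcript on
  average, the shallow-depth regime in which isoform detection genuinely
  fluctuates between samples — the regime that makes DAS a noisy, and
  therefore honestly testable, statistic. Counts invert the TPM formula at
  the sample's library size with stochastic rounding; expressed cells are
  floored at one read so the detection pattern survives the count
  round-trip (a slight upward bias at very low abundance), and TPM is then
  recomputed from counts so the two tables agree.
* planted specific isoforms (15 per phenotype, plus the extra isoforms of
  the DAS-shift sets): expressed strictly above the dropout level in every
  sample of their phenotype and exactly zero elsewhere. Their base level is
  floored at the ~84th percentile of the abundance distribution, mirroring
  the fact that a strict-specificity screen selects stably detected
  variants, not borderline ones.
* planted DAS-shift sets (two sets of 20 genes, +2 isoforms each, targeting
  HepG2 and liver) plus 20 random null sets of 20 genes: the substrate for
  SPEA power and calibration checks.

What the generator does **not** emulate: read-level error profiles,
mapping/quantification ambiguity between similar isoforms, correlated
biological replicates, novel (unannotated) isoforms, and compositional
coupling beyond the TPM closure. Passing tests therefore demonstrate that
the statistics recover their own planted signals under log-normal noise and
hard dropout — not that any particular biological dataset would yield the
same pathway lists.

## Problem sizes used in the test and benchmark suites

Analytic τ checks are closed-form. SPEA oracles run on 6–60-gene lists
where exhaustive subset enumeration is feasible; permutation convergence is
checked at 10 000 permutations against the enumerated tail; calibration
uses 200 random sets at 500 permutations. Planted-signal recovery and the
end-to-end pipeline run the default 2500-gene simulation at 1000
permutations. These sizes were chosen so every suite completes in seconds
while each check retains the statistical resolution it needs.

## Known limitations

* Rarefaction of transcript counts is a proxy for read-level downsampling
  followed by re-quantification; the two differ where quantification is
  ambiguous between isoforms.
* The detection threshold defining "detected" is a free parameter
  (default 0: any positive TPM); DAS values depend on it monotonically.
* FDR q from gene-set permutation is conservative for small collections;
  with a single tested set q degenerates to the pooled-null tail.
* Gene-level τ from summed TPM inherits the compositional closure of TPM;
  comparisons across phenotypes with very different library complexity
  should be interpreted accordingly.
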