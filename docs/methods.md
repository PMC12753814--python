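# Methods

This note documents the models implemented in `cnvdose`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Intensity model and normalisation

Raw probe intensities are summarised as Log-R ratio (LRR, log2 total
intensity relative to a diploid reference) and B-allele frequency (BAF,
relative B-allele intensity in [0, 1]). Two systematic artefacts are
modelled and removed before calling:

* **GC bias** — LRR drifts with local GC content. `gc_correct` fits, per
  sample, an ordinary-least-squares line of LRR on probe GC fraction and
  keeps the residuals (mean zero by construction). A constant GC vector
  makes the fit undefined; the panel then passes through with a warning.
* **Genomic waves** — long-range, slowly varying LRR undulation.
  `wave_correct` fits a localised loess (tricube-weighted local linear
  regression, default span 0.3 of each chromosome's probes) of LRR on
  position, per sample and chromosome, and subtracts the *centred*
  smooth so that the per-sample level is preserved. The fit uses two
  robustifying reweighting iterations: genuine CNV probes are large
  outliers relative to the wave, and an unweighted smooth would absorb —
  and thereby erase — part of their signal. This matters most for
  homozygous deletions (LRR near −4.5).

Order is fixed: GC first, then wave. `gc_correct` is a projection and
hence exactly idempotent. A loess smoother is not a projection, so
`wave_correct` is only approximately idempotent: it is exact on flat
input, and on smooth noise-free waves a second application changes values
by an order of magnitude less than the first. The tests encode exactly
that contract rather than a universal tolerance, which no practical
smoother satisfies on noisy input.

LRR principal components (default 5 when enabled) are computed from the
*corrected* matrix, by SVD of the column-centred LRR, so they capture
residual batch structure rather than artefacts already removed. Sign
convention: the largest-magnitude probe loading of each component is made
positive, so results are machine-independent.

## Copy-number HMM

States are emission clusters whose LRR means default to the platform
calibration values −4.5, −0.3, 0, 0.305, 0.528, 0.702, 0.8434, 0.9848,
1.126, interpreted as total copy numbers 0–8 and collapsed to call
classes 0–4 by `state_map` (copies ≥ 4 map to class 4, matching the
"type 0 … type 4" call taxonomy). The correspondence of the nine
calibration clusters to specific genotype clusters is a documented
assumption of this package.

Emissions are the product of

* a Gaussian LRR density at the cluster mean with a single shared
  variance, constrained to (0, 0.25] — the 0.25 ceiling is the intensity
  variance threshold of the calling configuration; and
* a BAF mixture over the allowed allelic ratios k/c at total copy c
  (e.g. {0, ½, 1} at copy 2, {0, ⅓, ⅔, 1} at copy 3), each component a
  Gaussian truncated to [0, 1] with fixed `baf_sd` (default 0.05),
  equally weighted. Copy 0 carries no allelic information and emits
  uniform BAF (log-density 0). Missing LRR or BAF contributes 0
  (marginalisation).

Equal component weights were chosen over population-BAF-derived
Hardy–Weinberg weights: they keep the emission model free of per-probe
allele-frequency estimates, and none of the implemented behaviour
(posterior symmetry, class separation) depends on the weighting.

Transitions are distance-independent: stay probability 0.999 with the
remaining mass uniform over other states. The matrix is doubly
stochastic, so its stationary distribution — used as the initial
distribution — is uniform. No transition parameters were available to
calibrate against; planted-CNV recovery is the test surface, and an
optional `cnv_open_prob` exposes the diploid-exit rate if needed.

Inference is exact forward–backward and Viterbi in log space (no
underflow at 10^5+ probes), batched across samples. Viterbi ties break
toward the lower copy number; segments are maximal runs of constant call
class per chromosome, reported with 1-based inclusive coordinates
internally and BED-style 0-based half-open on output.

**EM.** The E-step runs forward–backward over all samples with one
shared emission model — the population-level simplification of joint
CNV–haplotype modelling, which is deliberately out of scope. The M-step
re-estimates the shared LRR variance (posterior-weighted residual
variance around the fixed cluster means, floored at 1e−6 with a warning
and capped at 0.25); cluster-mean updating is optional and off by
default, because the means are platform calibration constants. The
log-likelihood trace is non-decreasing (checked to 1e−6). Note the
degenerate corner: on exactly noise-free data the variance MLE is 0,
outside the valid range, so "initialise at truth" is only a fixed point
up to the variance floor.

**Joint multi-cohort calling** intersects probe sets by (chromosome,
position), relabels all cohorts onto the reference cohort's probe ids,
pools the samples into a single EM fit, and returns per-cohort posteriors
on the shared grid. With a single cohort it reduces exactly to `em_fit`.

## Expected genotypes (countAll)

The expected CNV genotype at a probe is the posterior mean copy number
over classes 0–4: `countAll = Σ_k k·P(copy = k)`, e.g. 1·0.8 + 2·0.2 =
1.2, bounded in [0, 4] and linear in the posterior. Deletion-only
(`state0`) and duplication-only (`state2`) variants renormalise the
posterior over {0, 1, 2} and {2, 3, 4} respectively before taking the
expectation; only countAll feeds association. Samples stratify into
deletion carriers (countAll < 1.7), copy-normal, and duplication
carriers (countAll > 2.5), both thresholds strict.

Probes with mean certainty (maximum posterior) below 0.5 are masked from
association. The CNV minor-allele frequency hard-classifies samples by
nearest-integer copy and counts alleles — deletion frequency
(2·n₀ + n₁)/(2n), duplication frequency (2·n₄ + n₃)/(2n) — taking the
larger non-reference frequency folded to ≤ 0.5. Hard classification was
preferred over fractional dosage for reproducible carrier counting.

## Association models

Three linear modes, applicable to countAll or (for replication) to
corrected LRR:

1. **Univariate**: `glm(trait ~ covariates + dosage)`. Gaussian traits
   use exact OLS t inference — identical to the Pearson-correlation t
   test without covariates; binomial/poisson traits use a GLM Wald z
   test (statsmodels). Zero-variance dosage is flagged `monomorphic`,
   perfect separation `separation`, perfect fits `degenerate` with the
   minimum representable p.
2. **Joint (reverse) regression**: Gaussian regression of dosage on all
   traits plus covariates, tested against the covariates-only null.
   The reported statistic is the likelihood-ratio value
   −2(ll₀ − ll₁) = n·log(RSS₀/RSS₁), asymptotically χ² with df = number
   of traits; the p value comes from the exact nested-model F test.
   The F choice is deliberate: t² = F makes the single-Gaussian-trait
   joint p *identical* to the univariate p (the forward/reverse symmetry
   of the correlation test), which a χ² approximation only achieves
   asymptotically, while the null calibration of the rejection rate is
   exact at any n. Collinear traits are dropped with a warning and the
   df reduced.
3. **Backward variable selection**: repeatedly drop the trait with the
   largest per-coefficient Wald p above 0.05 (the step criterion is this
   package's documented choice) and refit; the final retained set is
   tested as in mode 2. An empty final set reports p = 1 by convention
   (with df 0 in that degenerate case).

Missing values are handled by listwise deletion per probe, with the used
sample count reported. Covariates: gender always available; LRR PCs
opt-in per cohort configuration. Reverse regression treats countAll as a
continuous Gaussian response; an ordinal variant on stratified classes is
out of scope.

**cis CNV-QTL**: dosage probes within gene boundary ± 5 kb (1-based
closed intervals; a probe exactly at boundary + window is included) are
tested against each of the gene's expression probes, per region. The
**reciprocal scan** reports gene pairs (A, B) where some A-dosage →
B-expression test and some B-dosage → A-expression test both fall under
a stated threshold, each pair once in lexicographic order with both
directions' minimum p.

## Effective number of tests

For M correlated traits, `M_eff = 1 + (M − 1)(1 − Var(λ)/M)` with λ the
eigenvalues of the trait correlation matrix. Var uses the *sample*
variance (denominator M − 1); this makes both analytic limits exact —
independent traits give Var(λ) = 0 hence M_eff = M, and perfectly
correlated traits give Var(λ) = M hence M_eff = 1. The result is clipped
to [1, M]. The Šidák adjustment `p_adj = 1 − (1 − p)^{M_eff}` is computed
via expm1/log1p so that very small p values survive; genome-wide
correction multiplies M_eff by the number of probes tested. Whether
traits and probes should be corrected jointly was an open design point;
the multiplicative choice is conservative and order-preserving.

## Consensus NMF gene programs

Expression matrices (probe × sample, shifted by the global minimum if
log-scale input contains negatives) are factorised as X ≈ WH by
multiplicative updates minimising Frobenius error (non-increasing by
construction; the error trace is exposed and tested). Per restart, each
probe is hard-assigned to its argmax program in W; across restarts
(default 50, run i seeded base + i) the consensus matrix holds the
fraction of runs two probes co-assign. Final programs are
average-linkage hierarchical clusters of 1 − consensus cut at the rank.
Program labels are aligned across restarts by maximum assignment overlap
(Hungarian matching) before occurrence counting; a probe's relative
importance at a rank is the fraction of runs spent in its modal program.
Derived inputs: `aveALL` (per-probe mean across regions) and the
`full set` (region-tagged column concatenation). Rank selection is not
performed — counts are reported for all ranks in the sweep (default
2–6).

## Methylation summaries

Tracks are (chrom, pos, methylated_count, unmethylated_count, sample)
tables. Region means average counts over positions within 1-based
inclusive intervals, then across samples (positions-then-samples; the
alternative orderings differ only for unbalanced coverage, which the
generator does not produce). Regions with mean methylated count
strictly above 700 reads are flagged, ordered by (chrom, start).

The *wave score* is an exploratory operationalisation of periodic
methylation fluctuation: the single-sample series is interpolated onto a
uniform grid, linearly detrended (hence offset-invariant), and its
autocorrelation computed; the dominant period is the first local
autocorrelation maximum above 0.1, and the amplitude is half the
peak-to-trough range of the quarter-period-smoothed series. Tracks too
short for two periods return no score.

## Synthetic cohorts: what they emulate, and what they do not

`simulate_cohort` draws, per locus, two independent haplotypes per sample
(Hardy–Weinberg, no linkage between loci), sums copies as
2 + duplications − deletions clipped to [0, 4], and emits LRR as
cluster_mean(copy) + gc_slope·gc + wave + Gaussian noise and BAF from the
binomial allelic composition at the probe's population B-allele
frequency with truncated-Gaussian spread (uniform at copy 0). Defaults —
LRR sd 0.15, BAF sd 0.04, GC slope 0.5 LRR/GC-unit, wave amplitude 0.1
LRR over a 1.5 Mb period — were chosen once as values that make the
0.25 emission-variance ceiling meaningful for bead-array-like data; the
noise model of any specific platform was not available to match.
Phenotypes are GLM draws from dosage (Gaussian/logit/log links, optional
correlated Gaussian blocks); expression adds γ·dosage cis effects per
region, including reciprocal pairs; methylation tracks are sinusoidal
read-count means with an optional phase-flipped sample subgroup.

Fixture geometry matters: planted CNVs must be small relative to the
loess window (as real CNVs are relative to genomic waves), otherwise the
wave correction legitimately absorbs part of the CNV shift — an effect
real pipelines share, visible here when a planted locus spans a large
fraction of a short synthetic chromosome.

Not simulated: somatic mosaicism, sex chromosomes, LD/haplotype
structure, probe-specific variances, plate/batch effects beyond the
smooth artefacts above. Passing tests therefore demonstrate correctness
of the inference machinery under the stated generative model, not
robustness to every artefact of real arrays.

## Problem sizes

The test and reference computations use desk-scale cohorts chosen to
keep the full suite fast while leaving each estimate well-powered:
200 × 500 for EM variance recovery, 620 samples × 400 probes for
allele-frequency recovery at a 0.47-frequency deletion, 2,000 replicates
at n = 300 for null calibration, 500 replicates for selection
consistency, 50 restarts for consensus NMF, and 20 seeds for the
reciprocal-QTL scan.

## Known limitations

* No haplotype/phasing information: population awareness enters only
  through shared emission fitting.
* The transition model is uncalibrated (no distance dependence by
  default).
* MAF from hard-classified carriers underestimates the allele frequency
  when calls are uncertain (attenuation is visible at locus edges in the
  worked example).
* The joint model assumes a Gaussian dosage response; heavy-tailed
  dosage distributions are not special-cased.
* The wave score is exploratory and assumes approximately uniform probe
  spacing.
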