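# cnvdose

Population-level copy-number-variant (CNV) calling from SNP-array
intensities, and association of CNV *dosage* with phenotypes and gene
expression.

## The problem

Bead-array genotyping chips report two intensity channels per probe: the
Log-R ratio (LRR), a log2 total-intensity measure that shifts with copy
number, and the B-allele frequency (BAF), whose cluster structure reflects
the allelic composition at each copy number. Most CNV callers segment one
sample at a time; for common CNVs segregating in a cohort this wastes the
population signal. `cnvdose` implements a population-aware stack for
cohort studies (epilepsy clinical trials, brain-expression consortia):

1. **Normalisation** — per-sample OLS regression of LRR on probe GC
   fraction, then removal of long-range "genomic waves" with a robust
   localised loess smooth per chromosome; LRR principal components are
   exported as association covariates.
2. **Calling** — a hidden Markov model over emission clusters with LRR
   means fixed at the platform calibration
   (−4.5, −0.3, 0, 0.305, 0.528, 0.702, 0.8434, 0.9848, 1.126 for total
   copies 0–8, collapsed to call classes 0–4), Gaussian LRR emissions
   with a shared variance capped at 0.25, and a BAF mixture over the
   allelic ratios allowed at each copy number. Emission parameters are
   fitted by EM (default 15 iterations) *jointly across all samples* —
   the population-shared-emission simplification of haplotype-aware
   calling. Multi-cohort joint calling intersects probe grids and pools
   samples into one fit.
3. **Dosage** — the expected CNV genotype per probe,
   `countAll = Σ_k k · P(copy = k) ∈ [0, 4]`
   (a posterior of 0.8 on copy 1 and 0.2 on copy 2 gives 1.2), with
   deletion-only and duplication-only variants, a per-probe certainty
   filter (mean maximum posterior ≥ 0.5) and a folded CNV minor-allele
   frequency from hard-classified carriers.
4. **Association** — the MultiPhen-style model family:
   univariate `glm(phenotype ~ covariates + dosage)`; the joint
   (reverse) regression `dosage ~ phenotypes + covariates` tested
   against the covariates-only null; and the joint model with backward
   variable selection. Raw LRR can replace dosage in all three for
   replication. cis CNV-QTL pairing tests dosage probes against
   expression probes within a ±5 kb window around each gene, and a
   reciprocal scan reports gene pairs with significant dosage→expression
   effects in both directions.
5. **Multiple testing** — the effective number of tests from the trait
   correlation spectrum, `M_eff = 1 + (M − 1)(1 − Var(λ)/M)`, feeding a
   Šidák adjustment `p_adj = 1 − (1 − p)^{M_eff}`.
6. **Gene programs and methylation** — consensus non-negative matrix
   factorisation (50 restarts, ranks 2–6) over exon-level expression with
   per-probe program-occurrence counts, and region summaries plus an
   exploratory wave score for bisulfite methylation tracks.

Real cohort data of this kind are access-restricted, so the package ships
a first-class synthetic-cohort generator (`cnvdose.simulate`) that plants
CNV haplotypes at configurable allele frequencies, emits LRR/BAF with GC
and wave artefacts, and links phenotypes, expression and methylation
tracks to the planted dosage. Every stage is tested against that truth.

## Worked example

```python
import numpy as np
from cnvdose import (make_probe_map, CnvLocus, CohortConfig, simulate_cohort,
                     gc_correct, wave_correct, em_fit, from_posterior,
                     simulate_phenotypes, TraitSpec, univariate, joint_reverse,
                     effective_tests, sidak_adjust, stratify)

pm = make_probe_map(300, seed=0)
locus = CnvLocus("1", int(pm["pos"].iloc[140]), int(pm["pos"].iloc[159]),
                 "deletion", allele_freq=0.30)
cohort = simulate_cohort(CohortConfig(
    n_samples=200, probe_map=pm, loci=[locus],
    lrr_sd=0.15, baf_sd=0.04, gc_slope=0.5,
    wave_amplitude=0.1, wave_period=1_500_000, seed=0))

panel = wave_correct(gc_correct(cohort.intensities), span=0.3)
emission, posterior = em_fit(panel, iters=15)
dm = from_posterior(posterior)

probe = pm["probe_id"].iloc[150]
print(f"fitted LRR variance: {emission.lrr_var:.4f}")
print(f"MAF at planted locus: {dm.maf[probe]:.3f}")

traits = [TraitSpec("seizure_count", beta=0.8), TraitSpec("remission", beta=0.0)]
phen = simulate_phenotypes(dm.count_all[probe].to_numpy(), traits, seed=1)
uni = univariate(phen["seizure_count"], dm.count_all[probe])
joint = joint_reverse(dm.count_all[probe], phen)
eff = effective_tests(np.corrcoef(phen.to_numpy(), rowvar=False))
print(f"univariate p = {uni.p_raw:.3g}; joint LRT = {joint.statistic:.2f} "
      f"(df={joint.df}), p = {joint.p_raw:.3g}")
print(f"M_effective = {eff.m_effective:.3f}; adjusted joint p = "
      f"{sidak_adjust(joint.p_raw, eff.m_effective):.3g}")
```

Output:

```
fitted LRR variance: 0.0240
MAF at planted locus: 0.223
univariate p = 1.6e-12; joint LRT = 50.63 (df=2), p = 1.48e-11
M_effective = 1.962; adjusted joint p = 2.91e-11
```

The fitted emission variance (0.0240) recovers the generating noise
(0.15² = 0.0225); the probe's folded MAF of 0.223 estimates the realised
deletion allele frequency in this draw (0.2625, planted at 0.30). The
dosage-linked trait is detected by both directions of regression; with
one null trait alongside, the effective number of tests is just under 2,
so the Šidák-adjusted joint p is roughly doubled.

The same flow is available as CLI verbs
(`cnvdose simulate | preprocess | call | dose | assoc | qtl | nmf |
methyl | run`), each reading and writing GenomeStudio-style final-report
TSVs, dosage TSVs and BED-like segment files.

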