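"""Synthetic cohort generation with known CNV truth.

Every downstream stage of the pipeline (intensity normalisation, HMM
calling, dosage, association, NMF, methylation summaries) is exercised on
cohorts produced here, so the generator plants all the structure those
stages are meant to recover:

* CNV haplotypes drawn under Hardy-Weinberg at configurable allele
  frequencies (no linkage between loci), copy number capped to {0..4};
* LRR emitted around per-copy cluster means, with a GC-slope artefact, a
  per-chromosome sinusoidal genomic wave, and Gaussian noise;
* BAF drawn from the allelic-composition mixture for each (copy, genotype);
* dosage-linked quantitative/binary/count phenotypes, cis-regulated
  expression per brain region (including reciprocal gene pairs), and
  periodic methylation read-count tracks with optional phase-flipped
  sample groups.

All randomness flows through one ``numpy`` Generator seeded from the
config, so a fixed seed yields bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import IntensityPanel, validate_probe_map

#: LRR cluster means for total copy numbers 0..4 (first five emission
#: clusters of the default platform calibration in :mod:`cnvdose.hmm`).
COPY_LRR_MEANS = np.array([-4.5, -0.3, 0.0, 0.305, 0.528])

MAX_COPY = 4


@dataclass(frozen=True)
class CnvLocus:
    """A planted CNV allele segregating in the population.

    Coordinates are 1-based inclusive. ``allele_type`` is ``"deletion"``
    (carrier haplotype loses one copy) or ``"duplication"`` (gains one).
    """

    chrom: str
    start: int
    end: int
    allele_type: str = "deletion"
    allele_freq: float = 0.1
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.label}: start > end")
        if not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(f"locus {self.label}: allele_freq must lie in [0, 1]")
        if self.allele_type not in ("deletion", "duplication"):
            raise ValueError(f"locus {self.label}: unknown allele_type {self.allele_type!r}")

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class CohortConfig:
    n_samples: int
    probe_map: pd.DataFrame
    loci: Sequence[CnvLocus] = ()
    lrr_sd: float = 0.15
    baf_sd: float = 0.04
    gc_slope: float = 0.0
    wave_amplitude: float = 0.0
    wave_period: float = 1_500_000.0
    seed: int = 0
    cohort_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.wave_period <= 0:
            raise ValueError("wave_period must be > 0")
        self.probe_map = validate_probe_map(self.probe_map)


@dataclass
class SyntheticCohort:
    """A simulated cohort together with its planted truth."""

    intensities: IntensityPanel
    true_copy_numbers: pd.DataFrame  # sample x probe integers in {0..4}
    locus_allele_counts: dict[str, int] = field(default_factory=dict)
    config: CohortConfig | None = None
    phenotypes: pd.DataFrame | None = None
    expression: dict[str, pd.DataFrame] | None = None
    methylation: pd.DataFrame | None = None

    def realized_allele_freq(self, locus: CnvLocus | str) -> float:
        """Non-reference allele frequency realised among 2n haplotypes."""
        label = locus.label if isinstance(locus, CnvLocus) else locus
        n = self.true_copy_numbers.shape[0]
        return self.locus_allele_counts[label] / (2 * n)


def make_probe_map(
    n_probes: int,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 2_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Build an evenly spaced probe map with smoothly varying GC content."""
    rng = np.random.default_rng(seed)
    pos = start + spacing * np.arange(n_probes, dtype=np.int64)
    # GC varies smoothly along the chromosome, as on real arrays.
    t = np.linspace(0, 4 * np.pi, n_probes)
    gc = np.clip(0.45 + 0.08 * np.sin(t) + rng.normal(0, 0.02, n_probes), 0.0, 1.0)
    pbaf = np.clip(rng.beta(2.0, 2.0, n_probes), 0.01, 0.99)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:06d}" for i in range(n_probes)],
            "chrom": chrom,
            "pos": pos,
            "gc": gc,
            "population_baf": pbaf,
        }
    )


def _draw_copy_numbers(config: CohortConfig, rng: np.random.Generator):
    pm = config.probe_map
    n, n_probes = config.n_samples, len(pm)
    copy = np.full((n, n_probes), 2, dtype=np.int64)
    allele_counts: dict[str, int] = {}
    for locus in config.loci:
        inside = (
            (pm["chrom"].to_numpy() == locus.chrom)
            & (pm["pos"].to_numpy() >= locus.start)
            & (pm["pos"].to_numpy() <= locus.end)
        )
        if not inside.any():
            raise ValueError(f"locus {locus.label} covers no probe in the probe map")
        # Hardy-Weinberg: two independent haplotypes per sample.
        alleles = (rng.random((n, 2)) < locus.allele_freq).sum(axis=1)
        allele_counts[locus.label] = int(alleles.sum())
        delta = alleles if locus.allele_type == "duplication" else -alleles
        copy[:, inside] += delta[:, None]
    np.clip(copy, 0, MAX_COPY, out=copy)
    return copy, allele_counts


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Simulate intensities for a cohort with planted CNV loci.

    Per sample, two CNV haplotypes are drawn per locus at the configured
    allele frequency; total copy = 2 + duplications - deletions, clipped to
    [0, 4]. LRR = cluster_mean(copy) + gc_slope*gc + sinusoidal wave +
    Gaussian noise; BAF comes from the binomial allelic composition at the
    probe's population B-allele frequency, with truncated-Gaussian spread
    (copy 0 emits uniform BAF — no allelic signal).
    """
    rng = np.random.default_rng(config.seed)
    pm = config.probe_map
    n, n_probes = config.n_samples, len(pm)
    copy, allele_counts = _draw_copy_numbers(config, rng)

    gc = pm["gc"].to_numpy(dtype=float)
    pos = pm["pos"].to_numpy(dtype=float)
    lrr = COPY_LRR_MEANS[copy] + config.gc_slope * gc[None, :]
    if config.wave_amplitude:
        wave = config.wave_amplitude * np.sin(2 * np.pi * pos / config.wave_period)
        lrr = lrr + wave[None, :]
    if config.lrr_sd > 0:
        lrr = lrr + rng.normal(0.0, config.lrr_sd, size=(n, n_probes))

    pbaf = pm["population_baf"].to_numpy(dtype=float)
    n_b = rng.binomial(copy, np.broadcast_to(pbaf, (n, n_probes)))
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(copy > 0, n_b / np.maximum(copy, 1), 0.5)
    baf = np.where(copy == 0, rng.random((n, n_probes)), baf)
    if config.baf_sd > 0:
        noise = rng.normal(0.0, config.baf_sd, size=(n, n_probes))
        baf = np.where(copy > 0, np.clip(baf + noise, 0.0, 1.0), baf)

    samples = [f"s{i:04d}" for i in range(n)]
    probes = list(pm["probe_id"])
    panel = IntensityPanel(
        pm,
        pd.DataFrame(lrr, index=samples, columns=probes),
        pd.DataFrame(baf, index=samples, columns=probes),
        cohort_id=config.cohort_id,
    )
    truth = pd.DataFrame(copy, index=samples, columns=probes)
    return SyntheticCohort(panel, truth, allele_counts, config)


# ---------------------------------------------------------------------------
# Phenotypes


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait linked (or not) to CNV dosage.

    family: gaussian (identity link), binomial (logit) or poisson (log).
    ``dispersion`` > 0 turns a poisson trait into gamma-Poisson
    (negative-binomial-like) counts with that gamma shape.
    """

    name: str
    beta: float = 0.0
    intercept: float = 0.0
    family: str = "gaussian"
    noise_sd: float = 1.0
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial", "poisson"):
            raise ValueError(f"unknown trait family {self.family!r}")


def simulate_phenotypes(
    dosage: np.ndarray | pd.Series,
    traits: Sequence[TraitSpec],
    seed: int = 0,
    trait_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a phenotype table from per-sample CNV dosage.

    Gaussian traits are ``intercept + beta*dosage + noise``; an optional
    correlation matrix couples the Gaussian noise across traits (must be
    positive definite). Binomial traits use a logit link, count traits a
    log link.
    """
    index = dosage.index if isinstance(dosage, pd.Series) else None
    dosage = np.asarray(dosage, dtype=float)
    rng = np.random.default_rng(seed)
    n = dosage.shape[0]
    gauss = [t for t in traits if t.family == "gaussian"]
    if trait_corr is not None:
        trait_corr = np.asarray(trait_corr, dtype=float)
        if trait_corr.shape != (len(gauss), len(gauss)):
            raise ValueError("trait_corr must be square over the gaussian traits")
        try:
            chol = np.linalg.cholesky(trait_corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("trait correlation matrix is not positive definite") from exc
        z = rng.standard_normal((n, len(gauss))) @ chol.T
    else:
        z = rng.standard_normal((n, len(gauss)))

    cols: dict[str, np.ndarray] = {}
    gi = 0
    for t in traits:
        eta = t.intercept + t.beta * dosage
        if t.family == "gaussian":
            cols[t.name] = eta + t.noise_sd * z[:, gi]
            gi += 1
        elif t.family == "binomial":
            p = 1.0 / (1.0 + np.exp(-eta))
            cols[t.name] = rng.random(n) < p
        else:  # poisson / gamma-poisson counts
            mu = np.exp(eta)
            if t.dispersion:
                mu = mu * rng.gamma(t.dispersion, 1.0 / t.dispersion, n)
            cols[t.name] = rng.poisson(mu).astype(float)
    out = pd.DataFrame(cols)
    if index is not None:
        out.index = index
    return out


# ---------------------------------------------------------------------------
# Expression


@dataclass(frozen=True)
class CisEffect:
    """A cis dosage->expression effect: CNV dosage at ``cnv_gene`` shifts
    the named expression probe by ``gamma`` per copy."""

    cnv_gene: str
    expr_probe: str
    gamma: float


def simulate_expression(
    dosages: pd.DataFrame,
    probe_genes: Mapping[str, str],
    effects: Sequence[CisEffect],
    n_regions: int = 2,
    baseline: float = 8.0,
    noise_sd: float = 0.5,
    shared_noise: bool = False,
    seed: int = 0,
    region_names: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate per-region expression matrices with planted cis effects.

    ``dosages`` is sample x CNV-gene; ``probe_genes`` maps every expression
    probe id to its gene (used only for bookkeeping by callers). Each
    region gets independent noise unless ``shared_noise`` reuses one draw,
    emulating a region-shared effect. Reciprocal designs (A dosage -> B
    expression and B dosage -> A expression) are just two entries in
    ``effects``.
    """
    for eff in effects:
        if eff.cnv_gene not in dosages.columns:
            raise ValueError(f"unknown CNV gene {eff.cnv_gene!r} in cis effect")
        if eff.expr_probe not in probe_genes:
            raise ValueError(f"unknown expression probe {eff.expr_probe!r} in cis effect")
    rng = np.random.default_rng(seed)
    probes = list(probe_genes)
    n = dosages.shape[0]
    mean = np.full((n, len(probes)), baseline, dtype=float)
    col = {p: j for j, p in enumerate(probes)}
    for eff in effects:
        mean[:, col[eff.expr_probe]] += eff.gamma * dosages[eff.cnv_gene].to_numpy(dtype=float)
    if region_names is None:
        region_names = [f"region{r + 1}" for r in range(n_regions)]
    shared = rng.normal(0.0, noise_sd, size=mean.shape) if shared_noise else None
    out = {}
    for name in region_names:
        noise = shared if shared is not None else (
            rng.normal(0.0, noise_sd, size=mean.shape) if noise_sd > 0 else 0.0
        )
        out[name] = pd.DataFrame(mean + noise, index=dosages.index, columns=probes)
    return out


# ---------------------------------------------------------------------------
# Methylation


@dataclass(frozen=True)
class MethylRegionSpec:
    """Mean read-count levels over a genomic interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    mean_methylated: float = 20.0
    mean_unmethylated: float = 40.0
    name: str | None = None

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


def simulate_methylation(
    regions: Sequence[MethylRegionSpec],
    spacing: int = 100,
    wave_amplitude: float = 0.0,
    wave_period: float = 5_000.0,
    flip_fraction: float = 0.0,
    n_samples: int = 1,
    poisson_noise: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate bisulfite read-count tracks over the given regions.

    Methylated counts follow region_mean + amplitude*sin(2*pi*pos/period);
    a ``flip_fraction`` of samples carries the wave phase-inverted. With
    ``poisson_noise`` counts are Poisson draws around that mean, otherwise
    they are the rounded mean itself (exact, for oracle tests). Columns:
    chrom, pos, methylated_count, unmethylated_count, sample.
    """
    if wave_period <= 0:
        raise ValueError("wave_period must be > 0")
    rng = np.random.default_rng(seed)
    n_flip = int(round(flip_fraction * n_samples))
    flipped = np.zeros(n_samples, dtype=bool)
    flipped[:n_flip] = True
    rows = []
    for s in range(n_samples):
        phase = np.pi if flipped[s] else 0.0
        for reg in regions:
            pos = np.arange(reg.start, reg.end + 1, spacing, dtype=np.int64)
            wave = wave_amplitude * np.sin(2 * np.pi * pos / wave_period + phase)
            meth = np.maximum(reg.mean_methylated + wave, 0.0)
            unmeth = np.full(pos.shape, max(reg.mean_unmethylated, 0.0))
            if poisson_noise:
                meth = rng.poisson(meth).astype(np.int64)
                unmeth = rng.poisson(unmeth).astype(np.int64)
            else:
                meth = np.rint(meth).astype(np.int64)
                unmeth = np.rint(unmeth).astype(np.int64)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": reg.chrom,
                        "pos": pos,
                        "methylated_count": meth,
                        "unmethylated_count": unmeth,
                        "sample": f"s{s:04d}",
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
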