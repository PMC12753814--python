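"""File formats, run configuration and the end-to-end pipeline.

Input intensities use the GenomeStudio-style "final report" layout: a
tab-delimited long table with columns SNP Name, Sample ID, Chr, Position,
Log R Ratio, B Allele Freq (one row per probe x sample), plus an optional
probe-info sidecar carrying GC fraction and population BAF. Internal
coordinates are 1-based inclusive; BED-like segment output is 0-based
half-open. Every pipeline run writes a JSON manifest with the config,
seeds and package version.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import dosage as dosage_mod
from . import hmm, multitest, preprocess
from .panel import IntensityPanel
from .simulate import CnvLocus, CohortConfig, TraitSpec, make_probe_map, simulate_cohort, simulate_phenotypes

FINAL_REPORT_COLUMNS = {
    "SNP Name": "probe_id",
    "Sample ID": "sample_id",
    "Chr": "chrom",
    "Position": "pos",
    "Log R Ratio": "lrr",
    "B Allele Freq": "baf",
}


def write_final_report(panel: IntensityPanel, path, probe_info_path=None) -> None:
    """Write a panel as a GenomeStudio-style final report (long TSV)."""
    pm = panel.probe_map
    lrr = panel.lrr.to_numpy()
    baf = panel.baf.to_numpy()
    n, p = lrr.shape
    out = pd.DataFrame(
        {
            "SNP Name": np.tile(pm["probe_id"].to_numpy(), n),
            "Sample ID": np.repeat(panel.lrr.index.to_numpy(), p),
            "Chr": np.tile(pm["chrom"].to_numpy(), n),
            "Position": np.tile(pm["pos"].to_numpy(), n),
            "Log R Ratio": lrr.ravel(),
            "B Allele Freq": baf.ravel(),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if probe_info_path is not None:
        pm[["probe_id", "gc", "population_baf"]].to_csv(
            probe_info_path, sep="\t", index=False, float_format="%.17g"
        )


def read_final_report(path, probe_info_path=None, cohort_id: str = "cohort") -> IntensityPanel:
    """Read a final report (order-insensitive columns) into a panel.

    Duplicate (probe, sample) rows raise; missing intensity values are
    tolerated and kept as NaN. GC / population BAF come from the optional
    probe-info sidecar (default 0.5 when absent).
    """
    raw = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in FINAL_REPORT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"final report missing mandatory column(s): {missing}")
    raw = raw.rename(columns=FINAL_REPORT_COLUMNS)
    if raw.duplicated(subset=["probe_id", "sample_id"]).any():
        dup = raw[raw.duplicated(subset=["probe_id", "sample_id"])].iloc[0]
        raise ValueError(
            f"duplicated (probe, sample) row: {dup['probe_id']!r}, {dup['sample_id']!r}"
        )
    pm = (
        raw[["probe_id", "chrom", "pos"]]
        .drop_duplicates("probe_id")
        .reset_index(drop=True)
    )
    pm["chrom"] = pm["chrom"].astype(str)
    if probe_info_path is not None:
        info = pd.read_csv(probe_info_path, sep="\t")
        pm = pm.merge(info, on="probe_id", how="left")
    for col, default in (("gc", 0.5), ("population_baf", 0.5)):
        if col not in pm.columns:
            pm[col] = default
        pm[col] = pm[col].fillna(default)
    lrr = raw.pivot(index="sample_id", columns="probe_id", values="lrr")
    baf = raw.pivot(index="sample_id", columns="probe_id", values="baf")
    lrr.index.name = None
    baf.index.name = None
    lrr.columns.name = None
    baf.columns.name = None
    return IntensityPanel(pm, lrr, baf, cohort_id=cohort_id)


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """Write Viterbi segments as BED-like TSV (0-based half-open)."""
    out = segments.copy()
    out["start"] = out["start"] - 1  # 1-based inclusive -> 0-based half-open
    out[["chrom", "start", "end", "copy_number", "mean_posterior"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_regions_bed(path) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive (chrom, start, end, name)."""
    bed = pd.read_csv(path, sep="\t", header=None)
    out = pd.DataFrame({
        "chrom": bed[0].astype(str),
        "start": bed[1].astype(int) + 1,
        "end": bed[2].astype(int),
    })
    if bed.shape[1] > 3:
        out["name"] = bed[3].astype(str)
    return out


def write_dosage(dm: dosage_mod.DosageMatrix, path, summary_path=None) -> None:
    dm.count_all.T.to_csv(path, sep="\t")  # probe rows, sample columns
    if summary_path is not None:
        dosage_mod.probe_summary(dm).to_csv(summary_path, sep="\t", index=False)


def write_assoc_results(results: list[assoc_mod.AssocResult], path, probe_map=None, maf=None) -> None:
    rows = []
    for r in results:
        row = r.to_row()
        if probe_map is not None and r.probe_id in set(probe_map["probe_id"]):
            pr = probe_map.set_index("probe_id").loc[r.probe_id]
            row["chrom"], row["pos"] = pr["chrom"], int(pr["pos"])
        if maf is not None and r.probe_id in maf.index:
            row["maf"] = float(maf[r.probe_id])
        rows.append(row)
    cols = ["probe_id", "chrom", "pos", "model", "traits", "beta", "stat", "df",
            "p_raw", "p_adj", "maf", "n", "flag"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, sep="\t", index=False)


def manhattan_table(results: list[assoc_mod.AssocResult], probe_map: pd.DataFrame) -> pd.DataFrame:
    """Manhattan-ready export: chrom, pos, -log10 p per probe."""
    pm = probe_map.set_index("probe_id")
    rows = []
    for r in results:
        if r.probe_id in pm.index and np.isfinite(r.p_raw):
            rows.append({"chrom": pm.loc[r.probe_id, "chrom"],
                         "pos": int(pm.loc[r.probe_id, "pos"]),
                         "neglog10_p": -np.log10(max(r.p_raw, 1e-320))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run.

    Thresholds default to the pipeline's documented cut-offs: certainty
    0.5, MAF 0.01, stratification 1.7/2.5, methylation 700. The seed is
    mandatory for any stochastic stage.
    """

    seed: int
    n_samples: int = 200
    n_probes: int = 300
    loci: list[dict] = field(default_factory=list)
    traits: list[dict] = field(default_factory=lambda: [{"name": "trait1", "beta": 0.5}])
    lrr_sd: float = 0.15
    baf_sd: float = 0.04
    gc_slope: float = 0.5
    wave_amplitude: float = 0.1
    wave_period: float = 1_500_000.0
    em_iters: int = 15
    min_certainty: float = 0.5
    min_maf: float = 0.01
    n_lrr_pcs: int = 0
    use_gender_covariate: bool = True
    models: list[str] = field(default_factory=lambda: ["univariate", "joint"])
    cohort_id: str = "synthetic"
    wave_span: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.min_certainty <= 1:
            raise ValueError("min_certainty must lie in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError("config must specify a seed")
        return cls(**data)


def _config_digest(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """simulate -> preprocess -> call -> dosage -> associate -> correct.

    Writes the final report, segments, dosage matrix, association results
    (Šidák-adjusted over the effective number of traits times probes
    tested) and a JSON manifest into ``out_dir``.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pm = make_probe_map(config.n_probes, seed=config.seed)
    loci = [CnvLocus(**d) for d in config.loci]
    cc = CohortConfig(
        n_samples=config.n_samples, probe_map=pm, loci=loci, lrr_sd=config.lrr_sd,
        baf_sd=config.baf_sd, gc_slope=config.gc_slope, wave_amplitude=config.wave_amplitude,
        wave_period=config.wave_period, seed=config.seed, cohort_id=config.cohort_id,
    )
    cohort = simulate_cohort(cc)
    write_final_report(cohort.intensities, out / "final_report.tsv", out / "probe_info.tsv")
    cohort.true_copy_numbers.to_csv(out / "truth_copy_numbers.tsv", sep="\t")

    panel = preprocess.wave_correct(preprocess.gc_correct(cohort.intensities), span=config.wave_span)
    emission, posterior = hmm.em_fit(panel, iters=config.em_iters)
    seg_frames = []
    lrr_arr = panel.lrr.to_numpy()
    baf_arr = panel.baf.to_numpy()
    trans = hmm.TransitionModel()
    for i, sample in enumerate(panel.sample_ids):
        segs = hmm.viterbi_segments(lrr_arr[i], baf_arr[i], panel.probe_map, emission, trans)
        segs.insert(0, "sample", sample)
        seg_frames.append(segs[segs["copy_number"] != 2])
    all_segs = pd.concat(seg_frames, ignore_index=True)
    write_segments_bed(all_segs.drop(columns="sample"), out / "segments.bed")
    all_segs.to_csv(out / "segments_by_sample.tsv", sep="\t", index=False)

    dm = dosage_mod.certainty_filter(dosage_mod.from_posterior(posterior), config.min_certainty)
    write_dosage(dm, out / "dosage.tsv", out / "dosage_summary.tsv")

    # Phenotypes keyed to the first locus (or the probe of largest MAF).
    rng_traits = [TraitSpec(**t) for t in config.traits]
    if loci:
        first = loci[0]
        in_locus = (pm["chrom"] == first.chrom) & (pm["pos"].between(first.start, first.end))
        anchor = pm.loc[in_locus, "probe_id"].iloc[0]
    else:
        anchor = dm.maf.idxmax()
    phen = simulate_phenotypes(
        dm.count_all[anchor].to_numpy(), rng_traits, seed=config.seed + 1
    )
    phen.index = dm.count_all.index
    rng = np.random.default_rng(config.seed + 2)
    gender = pd.Series(rng.integers(0, 2, len(phen)), index=phen.index, name="gender")
    phen_out = phen.copy()
    phen_out["gender"] = gender
    phen_out.to_csv(out / "phenotypes.tsv", sep="\t")

    covs = [gender.to_frame()] if config.use_gender_covariate else []
    if config.n_lrr_pcs > 0:
        covs.append(preprocess.lrr_pcs(panel, k=config.n_lrr_pcs))
    covariates = pd.concat(covs, axis=1) if covs else None

    eff = multitest.effective_tests(np.corrcoef(phen.to_numpy(), rowvar=False)
                                    if phen.shape[1] > 1 else np.array([[1.0]]))
    tested = [p for p in dm.kept_probes if dm.maf[p] >= config.min_maf]
    results: list[assoc_mod.AssocResult] = []
    for probe in tested:
        d = dm.count_all[probe]
        if "univariate" in config.models:
            for t in phen.columns:
                results.append(assoc_mod.univariate(phen[t], d, covariates=covariates,
                                                    probe_id=probe, trait_name=t))
        if "joint" in config.models:
            results.append(assoc_mod.joint_reverse(d, phen, covariates=covariates, probe_id=probe))
        if "joint_selected" in config.models:
            results.append(assoc_mod.joint_selection(d, phen, covariates=covariates, probe_id=probe))
    m_total = eff.m_effective * max(len(tested), 1)
    for r in results:
        if np.isfinite(r.p_raw):
            r.p_adjusted = float(multitest.sidak_adjust(r.p_raw, m_total))
    write_assoc_results(results, out / "assoc_results.tsv", probe_map=pm, maf=dm.maf)
    manhattan_table(results, pm).to_csv(out / "manhattan.tsv", sep="\t", index=False)

    manifest = {
        "package": "cnvdose",
        "version": __version__,
        "config": asdict(config),
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "n_results": len(results),
        "m_effective": eff.m_effective,
        "n_probes_tested": len(tested),
        "emission": {"cluster_means": emission.cluster_means.tolist(),
                     "lrr_var": emission.lrr_var},
        "audit": {"M": eff.m, "eigenvalues": eff.eigenvalues.tolist(),
                  "var_lambda": eff.var_lambda},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
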