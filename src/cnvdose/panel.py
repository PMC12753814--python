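"""Shared in-memory containers for SNP-array intensity data.

An :class:`IntensityPanel` holds one cohort's Log-R ratio (LRR) and
B-allele frequency (BAF) matrices, sample x probe, together with the probe
map (genomic coordinates, GC fraction and population B-allele frequency of
each probe). LRR is a log2-scale total-intensity measure that shifts with
copy number; BAF reflects the allelic composition at each probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROBE_MAP_COLUMNS = ("probe_id", "chrom", "pos", "gc", "population_baf")


def validate_probe_map(probe_map: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe map table and return it sorted by (chrom, pos).

    Required columns: probe_id, chrom, pos, gc, population_baf. Positions
    are 1-based and must be strictly increasing within a chromosome; gc and
    population_baf must lie in [0, 1].
    """
    missing = [c for c in PROBE_MAP_COLUMNS if c not in probe_map.columns]
    if missing:
        raise ValueError(f"probe map is missing columns: {missing}")
    pm = probe_map.copy()
    pm["chrom"] = pm["chrom"].astype(str)
    pm["pos"] = pm["pos"].astype(np.int64)
    if pm["probe_id"].duplicated().any():
        dup = pm.loc[pm["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe_id in probe map: {dup!r}")
    for col in ("gc", "population_baf"):
        vals = pm[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError(f"probe map column {col!r} must lie in [0, 1]")
    pm = pm.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    for _, grp in pm.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("probe positions must be strictly increasing within a chromosome")
    return pm


@dataclass
class IntensityPanel:
    """One cohort's probe map plus sample x probe LRR and BAF matrices.

    ``lrr`` and ``baf`` are DataFrames indexed by sample id with probe ids
    as columns, in probe-map order. Missing intensities are NaN and are
    marginalised over downstream.
    """

    probe_map: pd.DataFrame
    lrr: pd.DataFrame
    baf: pd.DataFrame
    cohort_id: str = "cohort"

    def __post_init__(self) -> None:
        self.probe_map = validate_probe_map(self.probe_map)
        order = list(self.probe_map["probe_id"])
        if set(order) != set(self.lrr.columns) or set(order) != set(self.baf.columns):
            raise ValueError("lrr/baf columns must match probe map probe_ids")
        self.lrr = self.lrr.loc[:, order]
        self.baf = self.baf.loc[:, order]
        if self.lrr.shape != self.baf.shape or not self.lrr.index.equals(self.baf.index):
            raise ValueError("lrr and baf must share samples and shape")
        b = self.baf.to_numpy(dtype=float)
        finite = np.isfinite(b)
        if np.any((b[finite] < 0) | (b[finite] > 1)):
            raise ValueError("baf values must lie in [0, 1] (or be NaN)")

    @property
    def n_samples(self) -> int:
        return self.lrr.shape[0]

    @property
    def n_probes(self) -> int:
        return self.lrr.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.lrr.index)

    def with_lrr(self, lrr: pd.DataFrame) -> "IntensityPanel":
        """Return a copy of the panel with LRR replaced (baf/map untouched)."""
        return IntensityPanel(self.probe_map, lrr, self.baf, self.cohort_id)

    def subset_probes(self, probe_ids: list[str]) -> "IntensityPanel":
        keep = self.probe_map["probe_id"].isin(probe_ids)
        pm = self.probe_map.loc[keep].reset_index(drop=True)
        return IntensityPanel(
            pm, self.lrr.loc[:, pm["probe_id"]], self.baf.loc[:, pm["probe_id"]], self.cohort_id
        )
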