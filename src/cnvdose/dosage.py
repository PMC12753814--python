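"""Expected CNV genotypes (countAll), certainty filters and CNV allele
frequencies.

The expected CNV genotype at a probe, called *countAll*, is the
posterior-weighted mean copy number: a sample with P(copy=1)=0.8 and
P(copy=2)=0.2 gets countAll = 1*0.8 + 2*0.2 = 1.2. countAll ranges 0-4
and is the genotype used by all association models. Samples can be
stratified into deletion carriers (countAll < 1.7), copy-normal, and
duplication carriers (countAll > 2.5); probes whose average call
certainty (maximum posterior) falls below 0.5 are excluded from
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import CnvPosterior, N_CLASSES

DELETION_THRESHOLD = 1.7
DUPLICATION_THRESHOLD = 2.5
DEFAULT_MIN_CERTAINTY = 0.5

_COPIES = np.arange(N_CLASSES, dtype=float)


def expected_genotype(posterior) -> float:
    """countAll for one posterior vector over copy classes 0..4.

    The vector must be non-negative and sum to 1 (within 1e-6). Vectors
    longer than 5 are collapsed by total copy min(k, 4) first.
    """
    p = np.asarray(posterior, dtype=float)
    if p.ndim != 1:
        raise ValueError("posterior must be a 1-D probability vector")
    if np.any(p < 0):
        raise ValueError("posterior probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("posterior must sum to 1")
    if len(p) > N_CLASSES:
        collapsed = np.zeros(N_CLASSES)
        for k, v in enumerate(p):
            collapsed[min(k, N_CLASSES - 1)] += v
        p = collapsed
    elif len(p) < N_CLASSES:
        p = np.pad(p, (0, N_CLASSES - len(p)))
    return float(p @ _COPIES)


def stratify(count_all: float) -> str:
    """Classify a countAll value: deletion (<1.7), neutral, duplication (>2.5)."""
    if not 0.0 <= count_all <= 4.0:
        raise ValueError("countAll must lie in [0, 4]")
    if count_all < DELETION_THRESHOLD:
        return "deletion"
    if count_all > DUPLICATION_THRESHOLD:
        return "duplication"
    return "neutral"


def stratify_matrix(count_all: np.ndarray) -> np.ndarray:
    arr = np.asarray(count_all, dtype=float)
    if np.any((arr < 0) | (arr > 4)):
        raise ValueError("countAll must lie in [0, 4]")
    out = np.full(arr.shape, "neutral", dtype=object)
    out[arr < DELETION_THRESHOLD] = "deletion"
    out[arr > DUPLICATION_THRESHOLD] = "duplication"
    return out


@dataclass
class DosageMatrix:
    """Expected CNV genotypes with certainty and allele-frequency summaries.

    ``count_all`` is sample x probe in [0, 4]; ``state0_dosage`` /
    ``state2_dosage`` are the deletion-only / duplication-only expected
    genotypes (posterior renormalised over copies {0,1,2} and {2,3,4});
    ``certainty`` is the per-entry maximum posterior; ``probe_mask`` marks
    probes excluded by the certainty filter.
    """

    count_all: pd.DataFrame
    state0_dosage: pd.DataFrame
    state2_dosage: pd.DataFrame
    certainty: pd.DataFrame
    maf: pd.Series
    probe_mask: pd.Series = field(default=None)
    probe_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ca = self.count_all.to_numpy(dtype=float)
        if np.any((ca < -1e-9) | (ca > 4 + 1e-9)):
            raise ValueError("countAll values must lie in [0, 4]")
        if self.probe_mask is None:
            self.probe_mask = pd.Series(False, index=self.count_all.columns)

    @property
    def kept_probes(self) -> list[str]:
        return list(self.probe_mask.index[~self.probe_mask])


def from_posterior(posterior: CnvPosterior) -> DosageMatrix:
    """Build the dosage matrix from copy-class posteriors."""
    g = posterior.gamma
    count_all = np.clip(g @ _COPIES, 0.0, 4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        del_mass = g[..., :3].sum(axis=-1, keepdims=True)
        state0 = (g[..., :3] @ _COPIES[:3]) / np.squeeze(del_mass, -1)
        dup_mass = g[..., 2:].sum(axis=-1, keepdims=True)
        state2 = (g[..., 2:] @ _COPIES[2:]) / np.squeeze(dup_mass, -1)
    certainty = g.max(axis=-1)
    idx = posterior.sample_ids
    cols = list(posterior.probe_map["probe_id"])
    ca = pd.DataFrame(count_all, index=idx, columns=cols)
    maf = pd.Series(
        {c: cnv_maf(ca[c].to_numpy()) for c in cols}, name="maf"
    )
    return DosageMatrix(
        count_all=ca,
        state0_dosage=pd.DataFrame(state0, index=idx, columns=cols),
        state2_dosage=pd.DataFrame(state2, index=idx, columns=cols),
        certainty=pd.DataFrame(certainty, index=idx, columns=cols),
        maf=maf,
        probe_map=posterior.probe_map,
    )


def certainty_filter(dosage: DosageMatrix, min_certainty: float = DEFAULT_MIN_CERTAINTY) -> DosageMatrix:
    """Mask probes whose average certainty falls below the threshold.

    Probes with mean maximum-posterior < ``min_certainty`` are flagged in
    ``probe_mask`` and excluded from downstream association; values are
    kept for audit.
    """
    if not 0.0 <= min_certainty <= 1.0:
        raise ValueError("min_certainty must lie in [0, 1]")
    mean_cert = dosage.certainty.mean(axis=0)
    mask = mean_cert < min_certainty
    return DosageMatrix(
        count_all=dosage.count_all,
        state0_dosage=dosage.state0_dosage,
        state2_dosage=dosage.state2_dosage,
        certainty=dosage.certainty,
        maf=dosage.maf,
        probe_mask=mask,
        probe_map=dosage.probe_map,
    )


def cnv_maf(count_all_column) -> float:
    """Folded CNV minor-allele frequency of one probe from countAll values.

    Samples are hard-classified by nearest-integer copy; the deletion
    allele frequency is (2*n_copy0 + n_copy1) / (2n), the duplication
    allele frequency (2*n_copy4 + n_copy3) / (2n). The larger non-reference
    frequency is reported, folded to <= 0.5 (a frequency of 1 folds to 0).
    """
    vals = np.asarray(count_all_column, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    classes = np.rint(vals).astype(int)
    n = classes.size
    counts = np.bincount(np.clip(classes, 0, 4), minlength=5)
    del_freq = (2 * counts[0] + counts[1]) / (2 * n)
    dup_freq = (2 * counts[4] + counts[3]) / (2 * n)
    f = max(del_freq, dup_freq)
    return float(f if f <= 0.5 else 1.0 - f)


def probe_summary(dosage: DosageMatrix) -> pd.DataFrame:
    """Per-probe summary: mean certainty, MAF, class counts, mask flag."""
    strata = stratify_matrix(dosage.count_all.to_numpy())
    rows = []
    for j, probe in enumerate(dosage.count_all.columns):
        col = strata[:, j]
        rows.append(
            {
                "probe_id": probe,
                "mean_certainty": float(dosage.certainty[probe].mean()),
                "maf": float(dosage.maf[probe]),
                "n_deletion": int((col == "deletion").sum()),
                "n_neutral": int((col == "neutral").sum()),
                "n_duplication": int((col == "duplication").sum()),
                "masked": bool(dosage.probe_mask[probe]),
            }
        )
    return pd.DataFrame(rows)
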