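"""Intensity normalisation: GC regression, genomic-wave removal, LRR PCs.

GC artefacts are regressed out of each sample's LRR by ordinary least
squares on probe GC fraction; residual long-range "genomic waves" are
removed with a localised loess (tricube-weighted local linear) smooth of
LRR against position, per chromosome. The corrected LRR matrix also yields
principal-component covariates for the association models.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .panel import IntensityPanel

MIN_WAVE_PROBES = 10


def gc_correct(panel: IntensityPanel) -> IntensityPanel:
    """Regress LRR on probe GC content, per sample; return residual panel.

    Residuals of the intercept+slope fit are mean zero by construction. A
    constant GC vector makes the regression undefined; the panel is then
    returned unchanged with a warning.
    """
    gc = panel.probe_map["gc"].to_numpy(dtype=float)
    if np.ptp(gc) == 0:
        warnings.warn("GC vector is constant; gc_correct skipped", stacklevel=2)
        return panel
    X = np.column_stack([np.ones_like(gc), gc])
    Y = panel.lrr.to_numpy(dtype=float)
    # One normal-equations solve for all samples at once; NaNs per sample
    # are handled by masking that sample's rows.
    out = np.empty_like(Y)
    nan_rows = np.isnan(Y).any(axis=1)
    ok = ~nan_rows
    if ok.any():
        beta, *_ = np.linalg.lstsq(X, Y[ok].T, rcond=None)
        out[ok] = Y[ok] - (X @ beta).T
    for i in np.nonzero(nan_rows)[0]:
        y = Y[i]
        m = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(X[m], y[m], rcond=None)
        out[i] = y - X @ beta
    lrr = pd.DataFrame(out, index=panel.lrr.index, columns=panel.lrr.columns)
    return panel.with_lrr(lrr)


def wave_correct(panel: IntensityPanel, span: float = 0.3) -> IntensityPanel:
    """Remove genomic waves by a localised loess smooth per chromosome.

    For each sample and chromosome, a tricube-weighted local linear fit of
    LRR against position (bandwidth = ``span`` of the chromosome's probes)
    is subtracted. The fit is robustified (two reweighting iterations) so
    that genuine CNV probes — large LRR outliers relative to the wave —
    do not drag the smooth and get partially erased. Chromosomes with
    fewer than ``MIN_WAVE_PROBES`` probes are left unchanged with a
    warning.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    pm = panel.probe_map
    Y = panel.lrr.to_numpy(dtype=float).copy()
    for chrom, grp in pm.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=float)
        if idx.size < MIN_WAVE_PROBES:
            warnings.warn(
                f"chromosome {chrom}: {idx.size} probes < {MIN_WAVE_PROBES}; wave_correct skipped",
                stacklevel=2,
            )
            continue
        for i in range(Y.shape[0]):
            y = Y[i, idx]
            m = np.isfinite(y)
            if m.sum() < MIN_WAVE_PROBES:
                continue
            smooth = lowess(
                y[m], pos[m], frac=span, it=2, return_sorted=False
            )
            # subtract the centred smooth: remove the wave, keep the level
            y[m] = y[m] - (smooth - smooth.mean())
            Y[i, idx] = y
    lrr = pd.DataFrame(Y, index=panel.lrr.index, columns=panel.lrr.columns)
    return panel.with_lrr(lrr)


def lrr_pcs(panel: IntensityPanel, k: int = 5) -> pd.DataFrame:
    """Top-k principal-component scores of the (column-centred) LRR matrix.

    Used as association covariates to absorb residual batch structure.
    Sign convention: each component's largest-magnitude probe loading is
    made positive, so results are deterministic. If ``k`` exceeds the
    matrix rank, the available components are returned with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    Y = panel.lrr.to_numpy(dtype=float)
    if k == 0:
        return pd.DataFrame(index=panel.lrr.index)
    if k > min(Y.shape):
        raise ValueError("k must be <= min(n_samples, n_probes)")
    Yc = Y - np.nanmean(Y, axis=0, keepdims=True)
    Yc = np.nan_to_num(Yc, nan=0.0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Yc.shape) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        warnings.warn(f"requested {k} PCs but rank is {rank}; returning {rank}", stacklevel=2)
        k = rank
    scores = U[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=panel.lrr.index, columns=[f"LRR_PC{j + 1}" for j in range(k)]
    )


def explained_variance_ratio(panel: IntensityPanel) -> np.ndarray:
    """Fraction of LRR variance captured by each principal component."""
    Y = panel.lrr.to_numpy(dtype=float)
    Yc = Y - np.nanmean(Y, axis=0, keepdims=True)
    Yc = np.nan_to_num(Yc, nan=0.0)
    s = np.linalg.svd(Yc, compute_uv=False)
    return s**2 / np.sum(s**2)
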