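"""Population-shared-emission hidden Markov model over copy-number states.

The model follows the cnvHap-style calling setup for bead-array data: a
chain over emission clusters whose LRR means are the platform calibration
values, with a Gaussian LRR emission (shared variance, capped at 0.25) and
a BAF mixture over the allelic ratios allowed at each total copy number.
The nine default cluster means correspond to total copy numbers 0-8 and
are collapsed to call classes 0-4 ("type 0" homozygous deletion through
"type 4" homozygous duplication) via ``state_map``.

Emissions are *population-shared*: EM fits one emission model across all
samples of a cohort (the population-aware simplification of joint
haplotype-aware calling, which is out of scope here). Inference is exact
forward-backward / Viterbi in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from .panel import IntensityPanel

#: Default LRR cluster means (platform calibration; total copies 0..8).
DEFAULT_CLUSTER_MEANS = (-4.5, -0.3, 0.0, 0.305, 0.528, 0.702, 0.8434, 0.9848, 1.126)
#: Ceiling on the shared LRR emission variance.
MAX_LRR_VAR = 0.25
MIN_LRR_VAR = 1e-6
#: Copy classes the clusters collapse to (copies >= 4 are class 4).
N_CLASSES = 5

_LOG_2PI = np.log(2.0 * np.pi)


def default_state_map(n_clusters: int) -> np.ndarray:
    """Map cluster index (total copy number) to call class min(copy, 4)."""
    return np.minimum(np.arange(n_clusters), N_CLASSES - 1)


@dataclass
class EmissionModel:
    """Gaussian-LRR + BAF-mixture emission model shared across a cohort."""

    cluster_means: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_CLUSTER_MEANS))
    lrr_var: float = MAX_LRR_VAR
    baf_sd: float = 0.05
    state_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster_means = np.asarray(self.cluster_means, dtype=float)
        if np.any(np.diff(self.cluster_means) <= 0):
            raise ValueError("cluster_means must be strictly increasing")
        if not 0 < self.lrr_var <= MAX_LRR_VAR:
            raise ValueError(f"lrr_var must lie in (0, {MAX_LRR_VAR}]")
        if self.state_map is None:
            self.state_map = default_state_map(len(self.cluster_means))
        self.state_map = np.asarray(self.state_map, dtype=int)
        if len(self.state_map) != len(self.cluster_means):
            raise ValueError("state_map must assign every cluster a copy class")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_means)


@dataclass
class TransitionModel:
    """Distance-independent transition model over emission clusters.

    ``stay_prob`` on the diagonal, remaining mass uniform among the other
    clusters; the resulting doubly stochastic matrix has a uniform
    stationary distribution, which is used as the initial distribution.
    An optional ``cnv_open_prob`` overrides the probability of leaving the
    diploid cluster.
    """

    stay_prob: float = 0.999
    cnv_open_prob: float | None = None
    diploid_cluster: int = 2

    def matrix(self, n_states: int) -> np.ndarray:
        if not 0 < self.stay_prob < 1:
            raise ValueError("stay_prob must lie in (0, 1)")
        off = (1.0 - self.stay_prob) / (n_states - 1)
        A = np.full((n_states, n_states), off)
        np.fill_diagonal(A, self.stay_prob)
        if self.cnv_open_prob is not None:
            d = self.diploid_cluster
            A[d] = self.cnv_open_prob / (n_states - 1)
            A[d, d] = 1.0 - self.cnv_open_prob
        return A

    def initial(self, n_states: int) -> np.ndarray:
        return np.full(n_states, 1.0 / n_states)


# ---------------------------------------------------------------------------
# Emission log-densities


def _baf_mixture_logpdf(baf: np.ndarray, copy: int, baf_sd: float) -> np.ndarray:
    """Log-density of the BAF mixture for a given total copy number.

    Components sit at the allowed allelic ratios k/copy (k = 0..copy),
    equally weighted, each a Gaussian truncated to [0, 1]. Copy 0 carries
    no allelic signal: BAF is uniform on [0, 1], log-density 0.
    """
    baf = np.asarray(baf, dtype=float)
    if copy == 0:
        return np.zeros_like(baf)
    ratios = np.arange(copy + 1) / copy
    # Truncated-normal normalisers per component.
    z = ndtr((1.0 - ratios) / baf_sd) - ndtr((0.0 - ratios) / baf_sd)
    comp = (
        -0.5 * ((baf[..., None] - ratios) / baf_sd) ** 2
        - np.log(baf_sd)
        - 0.5 * _LOG_2PI
        - np.log(z)
    )
    return logsumexp(comp, axis=-1) - np.log(copy + 1)


def emission_loglik(lrr, baf, cluster: int, model: EmissionModel):
    """Log-density of one observation under one emission cluster.

    Gaussian LRR term at the cluster mean plus the BAF mixture term for
    the cluster's total copy number; a missing (NaN) BAF contributes 0
    (marginalised), as does a missing LRR.
    """
    if not 0 <= cluster < model.n_clusters:
        raise ValueError(f"cluster {cluster} out of range")
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if np.any(np.isinf(lrr)) or np.any(np.isinf(baf)):
        raise ValueError("non-finite (infinite) intensity values")
    mu = model.cluster_means[cluster]
    ll_lrr = -0.5 * ((lrr - mu) ** 2 / model.lrr_var + np.log(model.lrr_var) + _LOG_2PI)
    ll_lrr = np.where(np.isnan(lrr), 0.0, ll_lrr)
    copy = int(cluster)  # cluster index encodes total copy number
    ll_baf = _baf_mixture_logpdf(np.nan_to_num(baf, nan=0.5), copy, model.baf_sd)
    ll_baf = np.where(np.isnan(baf), 0.0, ll_baf)
    out = ll_lrr + ll_baf
    return float(out) if out.ndim == 0 else out


def emission_logmatrix(lrr: np.ndarray, baf: np.ndarray, model: EmissionModel) -> np.ndarray:
    """Stacked emission log-densities, shape (..., n_clusters)."""
    cols = [emission_loglik(lrr, baf, k, model) for k in range(model.n_clusters)]
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# Exact inference (log space, batched over samples)


def _forward_backward_core(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray):
    """Batched forward-backward. logB: (S, T, K). Returns (gamma, loglik)."""
    S, T, K = logB.shape
    log_alpha = np.empty((S, T, K))
    log_alpha[:, 0] = logpi[None, :] + logB[:, 0]
    for t in range(1, T):
        log_alpha[:, t] = (
            logsumexp(log_alpha[:, t - 1, :, None] + logA[None, :, :], axis=1) + logB[:, t]
        )
    loglik = logsumexp(log_alpha[:, -1], axis=1)
    if np.any(~np.isfinite(loglik)):
        s = int(np.nonzero(~np.isfinite(loglik))[0][0])
        bad = np.nonzero(~np.isfinite(logsumexp(log_alpha[s], axis=1)))[0]
        probe = int(bad[0]) if bad.size else -1
        raise ValueError(
            f"zero-probability observation model (sample index {s}, probe index {probe})"
        )
    log_beta = np.empty((S, T, K))
    log_beta[:, -1] = 0.0
    for t in range(T - 2, -1, -1):
        log_beta[:, t] = logsumexp(
            logA[None, :, :] + (logB[:, t + 1] + log_beta[:, t + 1])[:, None, :], axis=2
        )
    loglik_b = logsumexp(logpi[None, :] + logB[:, 0] + log_beta[:, 0], axis=1)
    if np.any(np.abs(loglik - loglik_b) > 1e-8 * np.maximum(1.0, np.abs(loglik))):
        raise AssertionError("forward and backward log-likelihoods disagree")
    log_gamma = log_alpha + log_beta
    log_gamma -= logsumexp(log_gamma, axis=2, keepdims=True)
    return np.exp(log_gamma), loglik


def forward_backward(
    lrr: np.ndarray,
    baf: np.ndarray,
    emission: EmissionModel,
    transition: TransitionModel,
):
    """Posterior cluster probabilities for one sample's ordered observations.

    Returns ``(gamma, loglik)`` with ``gamma`` of shape
    (n_probes, n_clusters), rows summing to 1.
    """
    lrr = np.atleast_1d(np.asarray(lrr, dtype=float))
    baf = np.atleast_1d(np.asarray(baf, dtype=float))
    logB = emission_logmatrix(lrr, baf, emission)[None, ...]
    logA = np.log(transition.matrix(emission.n_clusters))
    logpi = np.log(transition.initial(emission.n_clusters))
    gamma, loglik = _forward_backward_core(logB, logA, logpi)
    return gamma[0], float(loglik[0])


def _viterbi_core(logB: np.ndarray, logA: np.ndarray, logpi: np.ndarray) -> np.ndarray:
    """Batched Viterbi. Ties resolve to the lowest state index (lowest copy)."""
    S, T, K = logB.shape
    psi = np.empty((S, T, K), dtype=np.int32)
    delta = logpi[None, :] + logB[:, 0]
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None, :, :]  # (S, prev, next)
        psi[:, t] = np.argmax(cand, axis=1)
        delta = np.max(cand, axis=1) + logB[:, t]
    path = np.empty((S, T), dtype=np.int32)
    path[:, -1] = np.argmax(delta, axis=1)
    rows = np.arange(S)
    for t in range(T - 2, -1, -1):
        path[:, t] = psi[rows, t + 1, path[:, t + 1]]
    return path


def collapse_gamma(gamma: np.ndarray, state_map: np.ndarray) -> np.ndarray:
    """Sum cluster posteriors into copy-class posteriors (last axis -> 5)."""
    out = np.zeros(gamma.shape[:-1] + (N_CLASSES,))
    for k, cls in enumerate(state_map):
        out[..., cls] += gamma[..., k]
    return out


@dataclass
class CnvPosterior:
    """Copy-class posteriors and Viterbi paths for a cohort.

    ``gamma`` is sample x probe x copy-class (0..4) and sums to 1 over
    classes at every (sample, probe); ``viterbi_path`` holds the MAP copy
    class per sample and probe.
    """

    gamma: np.ndarray
    viterbi_path: np.ndarray
    loglik_trace: np.ndarray
    sample_ids: list[str]
    probe_map: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.gamma.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("posterior probabilities must sum to 1 over states")


def viterbi_segments(
    lrr: np.ndarray,
    baf: np.ndarray,
    probe_map: pd.DataFrame,
    emission: EmissionModel,
    transition: TransitionModel,
) -> pd.DataFrame:
    """MAP copy-number segments for one sample.

    The Viterbi path over clusters is collapsed to copy classes and merged
    into maximal runs of constant class per chromosome. Returns a table
    (chrom, start, end, copy_number, n_probes, mean_posterior) with
    1-based inclusive coordinates; ties in the MAP path break toward the
    lower copy number.
    """
    lrr = np.atleast_1d(np.asarray(lrr, dtype=float))
    baf = np.atleast_1d(np.asarray(baf, dtype=float))
    logA = np.log(transition.matrix(emission.n_clusters))
    logpi = np.log(transition.initial(emission.n_clusters))
    rows = []
    gamma_full, _ = forward_backward(lrr, baf, emission, transition)
    gamma_cls = collapse_gamma(gamma_full, emission.state_map)
    for chrom, grp in probe_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        logB = emission_logmatrix(lrr[idx], baf[idx], emission)[None, ...]
        clusters = _viterbi_core(logB, logA, logpi)[0]
        classes = emission.state_map[clusters]
        pos = grp["pos"].to_numpy()
        start = 0
        for i in range(1, len(classes) + 1):
            if i == len(classes) or classes[i] != classes[start]:
                cls = int(classes[start])
                seg_idx = idx[start:i]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[start]),
                        "end": int(pos[i - 1]),
                        "copy_number": cls,
                        "n_probes": i - start,
                        "mean_posterior": float(gamma_cls[seg_idx, cls].mean()),
                    }
                )
                start = i
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "copy_number", "n_probes", "mean_posterior"])


# ---------------------------------------------------------------------------
# EM fitting


def _cohort_logB(panel: IntensityPanel, emission: EmissionModel) -> np.ndarray:
    lrr = panel.lrr.to_numpy(dtype=float)
    baf = panel.baf.to_numpy(dtype=float)
    return emission_logmatrix(lrr, baf, emission)


def em_fit(
    panel: IntensityPanel,
    init: EmissionModel | None = None,
    transition: TransitionModel | None = None,
    iters: int = 15,
    update_means: bool = False,
):
    """Fit the shared emission model by EM and return posteriors.

    E-step: forward-backward across all samples with one shared emission
    model (population-level fitting). M-step: update the shared LRR
    variance (capped at ``MAX_LRR_VAR``, floored with a warning if
    degenerate) and, optionally, the cluster means (kept in their original
    order). The total log-likelihood trace is non-decreasing.

    Returns ``(fitted EmissionModel, CnvPosterior)``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if panel.n_samples == 0:
        raise ValueError("empty cohort")
    emission = init if init is not None else EmissionModel()
    transition = transition if transition is not None else TransitionModel()
    logA = np.log(transition.matrix(emission.n_clusters))
    logpi = np.log(transition.initial(emission.n_clusters))
    lrr = panel.lrr.to_numpy(dtype=float)
    trace = []
    gamma = None
    for _ in range(iters):
        logB = _cohort_logB(panel, emission)
        gamma, loglik = _forward_backward_core(logB, logA, logpi)
        trace.append(float(loglik.sum()))
        # M-step: weighted residual variance around the cluster means,
        # pooled over samples, probes and clusters (shared variance).
        resid2 = (lrr[:, :, None] - emission.cluster_means[None, None, :]) ** 2
        w = gamma.copy()
        w[np.isnan(lrr)] = 0.0
        denom = w.sum()
        var = float((w * resid2).sum() / denom) if denom > 0 else emission.lrr_var
        if var < MIN_LRR_VAR:
            warnings.warn("degenerate LRR variance; floored", stacklevel=2)
            var = MIN_LRR_VAR
        var = min(var, MAX_LRR_VAR)
        means = emission.cluster_means
        if update_means:
            wk = w.sum(axis=(0, 1))
            num = (w * lrr[:, :, None]).sum(axis=(0, 1))
            new = np.where(wk > 1e-9, num / np.maximum(wk, 1e-300), means)
            if np.all(np.diff(new) > 0):
                means = new
        emission = EmissionModel(means, var, emission.baf_sd, emission.state_map)
    # Final E-step so posteriors match the fitted parameters.
    logB = _cohort_logB(panel, emission)
    gamma, loglik = _forward_backward_core(logB, logA, logpi)
    trace.append(float(loglik.sum()))
    # Viterbi per chromosome (transitions do not cross chromosome ends).
    paths = np.empty(lrr.shape, dtype=np.int32)
    for _, grp in panel.probe_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        paths[:, idx] = _viterbi_core(logB[:, idx], logA, logpi)
    gamma_cls = collapse_gamma(gamma, emission.state_map)
    posterior = CnvPosterior(
        gamma=gamma_cls,
        viterbi_path=emission.state_map[paths],
        loglik_trace=np.asarray(trace),
        sample_ids=panel.sample_ids,
        probe_map=panel.probe_map,
    )
    return emission, posterior


def joint_call(
    panels: list[IntensityPanel],
    reference_cohort: str,
    init: EmissionModel | None = None,
    transition: TransitionModel | None = None,
    iters: int = 15,
    update_means: bool = False,
) -> dict[str, CnvPosterior]:
    """Multi-cohort joint calling with one shared emission model.

    Probe sets are intersected by (chrom, pos); the reference cohort's
    probe ids define the shared grid (its calibration). All cohorts'
    samples are pooled into one EM fit, then posteriors are returned per
    cohort on the shared grid.
    """
    if not panels:
        raise ValueError("no cohorts given")
    by_id = {p.cohort_id: p for p in panels}
    if reference_cohort not in by_id:
        raise ValueError(f"reference cohort {reference_cohort!r} not among panels")
    if len(panels) == 1:
        emission, post = em_fit(panels[0], init=init, transition=transition, iters=iters,
                                update_means=update_means)
        return {panels[0].cohort_id: post}
    keys = None
    for p in panels:
        k = set(zip(p.probe_map["chrom"], p.probe_map["pos"]))
        keys = k if keys is None else keys & k
    if not keys:
        raise ValueError("empty probe intersection across cohorts")
    ref = by_id[reference_cohort]
    ref_keep = [
        (c, pos) in keys for c, pos in zip(ref.probe_map["chrom"], ref.probe_map["pos"])
    ]
    grid = ref.probe_map.loc[ref_keep].reset_index(drop=True)
    subsets = []
    for p in panels:
        keep = p.probe_map.apply(lambda r: (r["chrom"], r["pos"]) in keys, axis=1)
        pm = p.probe_map.loc[keep.to_numpy()].reset_index(drop=True)
        lrr = p.lrr.loc[:, pm["probe_id"]].copy()
        baf = p.baf.loc[:, pm["probe_id"]].copy()
        # Relabel onto the reference probe ids (shared (chrom, pos) grid).
        lrr.columns = grid["probe_id"].to_numpy()
        baf.columns = grid["probe_id"].to_numpy()
        subsets.append(
            IntensityPanel(grid.copy(), lrr, baf, cohort_id=p.cohort_id)
        )
    pooled = IntensityPanel(
        grid.copy(),
        pd.concat([s.lrr for s in subsets], axis=0),
        pd.concat([s.baf for s in subsets], axis=0),
        cohort_id="pooled",
    )
    emission, post = em_fit(pooled, init=init, transition=transition, iters=iters,
                            update_means=update_means)
    out = {}
    offset = 0
    for s in subsets:
        n = s.n_samples
        out[s.cohort_id] = CnvPosterior(
            gamma=post.gamma[offset:offset + n],
            viterbi_path=post.viterbi_path[offset:offset + n],
            loglik_trace=post.loglik_trace,
            sample_ids=s.sample_ids,
            probe_map=grid,
        )
        offset += n
    return out
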