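"""Consensus non-negative matrix factorization over exon-level expression.

Expression matrices (probe x sample) are factorised as X ~ W H with
non-negative factors by multiplicative updates minimising Frobenius
error. Each probe is hard-assigned to its argmax program (row of W); over
many restarts the fraction of runs in which two probes co-assign forms a
consensus matrix, which average-linkage hierarchical clustering cuts into
the final "gene programs" (meta exons/genes). Counting how often a probe
lands in each program across restarts and ranks gives its relative
importance.

Two derived inputs mirror multi-region expression studies: ``aveALL``
(per-probe mean across regions) and the ``full set`` (all regions'
columns concatenated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

_EPS = 1e-12


def ave_all(panels: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-probe mean expression across regions (samples aligned)."""
    mats = list(panels.values())
    first = mats[0]
    for m in mats[1:]:
        if not (m.index.equals(first.index) and m.columns.equals(first.columns)):
            raise ValueError("regions must share probes and samples for aveALL")
    return sum(mats) / len(mats)


def full_set(panels: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Column-wise concatenation of all regions, region-tagged columns."""
    mats = []
    first = next(iter(panels.values()))
    for region, m in panels.items():
        if not m.index.equals(first.index):
            raise ValueError("regions must share probes for the full set")
        tagged = m.copy()
        tagged.columns = [f"{region}::{c}" for c in m.columns]
        mats.append(tagged)
    return pd.concat(mats, axis=1)


def gene_window_matrix(
    expression: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    gene: str,
    gene_annotation: pd.DataFrame,
    window_bp: int = 5_000,
) -> pd.DataFrame:
    """Probes within gene boundary +/- window (closed-interval overlap).

    ``probe_annotation`` gives each expression probe's interval (probe_id,
    chrom, start, end); a probe is kept when its interval overlaps
    [gene_start - window, gene_end + window], both 1-based inclusive — a
    probe exactly at boundary + window is included.
    """
    g = gene_annotation[gene_annotation["gene"].astype(str) == str(gene)]
    if g.empty:
        raise ValueError(f"gene {gene!r} not in annotation")
    g = g.iloc[0]
    lo, hi = int(g["start"]) - window_bp, int(g["end"]) + window_bp
    pa = probe_annotation
    keep = (
        (pa["chrom"].astype(str) == str(g["chrom"]))
        & (pa["start"] <= hi)
        & (pa["end"] >= lo)
    )
    probes = [p for p in pa.loc[keep, "probe_id"] if p in expression.index]
    if not probes:
        import warnings

        warnings.warn(f"gene {gene!r}: no expression probes in window", stacklevel=2)
    return expression.loc[probes]


# ---------------------------------------------------------------------------
# Factorisation


def nmf_factorize(X, rank: int, seed: int = 0, max_iter: int = 300, tol: float = 1e-7):
    """Multiplicative-update NMF minimising Frobenius error.

    Returns ``(W, H, error_trace)`` with W (rows x rank), H (rank x cols)
    non-negative and the Frobenius reconstruction error per iteration
    (non-increasing). Deterministic under ``seed``.
    """
    A = np.asarray(X, dtype=float)
    if np.any(A < 0):
        raise ValueError("NMF input must be non-negative; shift the matrix first")
    m, n = A.shape
    if rank > min(m, n):
        raise ValueError(f"rank {rank} exceeds min matrix dimension {min(m, n)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(A.mean(), _EPS) / rank)
    W = scale * rng.random((m, rank)) + _EPS
    H = scale * rng.random((rank, n)) + _EPS
    errors = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ A) / (W.T @ W @ H + _EPS)
        W *= (A @ H.T) / (W @ H @ H.T + _EPS)
        err = float(np.linalg.norm(A - W @ H))
        errors.append(err)
        if prev - err < tol * max(prev, 1.0):
            break
        prev = err
    return W, H, np.asarray(errors)


def _assign(W: np.ndarray) -> np.ndarray:
    return np.argmax(W, axis=1)


@dataclass
class ConsensusResult:
    rank: int
    consensus: pd.DataFrame  # probe x probe co-assignment fractions
    labels: pd.Series        # final consensus cluster per probe (1..rank)
    assignments: np.ndarray  # n_runs x n_probes raw argmax programs
    errors: np.ndarray       # best reconstruction error per run


def consensus(
    X: pd.DataFrame,
    rank: int,
    n_runs: int = 50,
    base_seed: int = 0,
    max_iter: int = 300,
) -> ConsensusResult:
    """Consensus clustering over NMF restarts at one rank.

    Run ``n_runs`` factorizations (run i seeded ``base_seed + i``),
    hard-assign each probe to its argmax program, accumulate the fraction
    of runs in which each probe pair co-assigns, and cut average-linkage
    hierarchical clustering of (1 - consensus) at ``rank`` clusters.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    probes = list(X.index) if isinstance(X, pd.DataFrame) else list(range(A.shape[0]))
    m = A.shape[0]
    C = np.zeros((m, m))
    assignments = np.empty((n_runs, m), dtype=np.int32)
    errs = np.empty(n_runs)
    for i in range(n_runs):
        W, _, trace = nmf_factorize(A, rank, seed=base_seed + i, max_iter=max_iter)
        lab = _assign(W)
        assignments[i] = lab
        errs[i] = trace[-1]
        C += lab[:, None] == lab[None, :]
    C /= n_runs
    np.fill_diagonal(C, 1.0)
    dist = squareform(1.0 - C, checks=False)
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=rank, criterion="maxclust")
    return ConsensusResult(
        rank=rank,
        consensus=pd.DataFrame(C, index=probes, columns=probes),
        labels=pd.Series(labels, index=probes, name="cluster"),
        assignments=assignments,
        errors=errs,
    )


def _align_runs(assignments: np.ndarray, rank: int) -> np.ndarray:
    """Permute each run's program labels to best match run 0 (Hungarian)."""
    ref = assignments[0]
    out = assignments.copy()
    for i in range(1, assignments.shape[0]):
        overlap = np.zeros((rank, rank))
        for a in range(rank):
            sel = assignments[i] == a
            for b in range(rank):
                overlap[a, b] = np.sum(sel & (ref == b))
        rows, cols = linear_sum_assignment(-overlap)
        perm = np.empty(rank, dtype=np.int32)
        perm[rows] = cols
        out[i] = perm[assignments[i]]
    return out


def program_counts(results: Mapping[int, ConsensusResult]) -> pd.DataFrame:
    """Per-probe occurrence counts in each program across ranks and runs.

    Program labels are aligned across restarts within each rank (maximum
    assignment overlap with the first run), then occurrences are counted.
    The ``relative_importance`` of a probe at a rank is the fraction of
    runs spent in its modal program — stability of its program membership.
    """
    probe_sets = {tuple(r.consensus.index) for r in results.values()}
    if len(probe_sets) != 1:
        raise ValueError("all ranks must be computed on the same probe set")
    probes = list(next(iter(results.values())).consensus.index)
    rows = []
    for rank, res in sorted(results.items()):
        aligned = _align_runs(res.assignments, rank)
        n_runs = aligned.shape[0]
        for j, probe in enumerate(probes):
            counts = np.bincount(aligned[:, j], minlength=rank)
            modal = int(np.argmax(counts))
            for prog in range(rank):
                rows.append(
                    {
                        "probe_id": probe,
                        "rank": rank,
                        "program": prog,
                        "count": int(counts[prog]),
                        "consensus_cluster": int(res.labels.loc[probe]),
                        "relative_importance": counts[modal] / n_runs if prog == modal else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def consensus_sweep(
    X: pd.DataFrame,
    ranks: Sequence[int] = (2, 3, 4, 5, 6),
    n_runs: int = 50,
    base_seed: int = 0,
    max_iter: int = 300,
) -> dict[int, ConsensusResult]:
    """Consensus clustering across a rank sweep (default ranks 2-6)."""
    return {
        r: consensus(X, r, n_runs=n_runs, base_seed=base_seed + 1000 * r, max_iter=max_iter)
        for r in ranks
    }


def shift_nonnegative(X: pd.DataFrame) -> pd.DataFrame:
    """Shift a (possibly log-scale) matrix by its global minimum if negative."""
    lo = float(np.nanmin(X.to_numpy()))
    return X - lo if lo < 0 else X
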