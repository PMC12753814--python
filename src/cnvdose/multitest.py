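"""Effective number of tests and Šidák adjustment.

With M correlated traits the nominal Šidák correction over-counts. The
modified Šidák approach derives an effective number of tests from the
eigenvalue spread of the trait correlation matrix:

    M_effective = 1 + (M - 1) * (1 - Var(lambda) / M)

where lambda are the eigenvalues and Var uses the sample variance
(denominator M - 1), which makes the two limits exact: independent traits
give M_effective = M, perfectly correlated traits give 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EffectiveTests:
    m: int
    eigenvalues: np.ndarray
    var_lambda: float
    m_effective: float


def effective_tests(corr) -> EffectiveTests:
    """Effective number of tests from a trait correlation matrix.

    The matrix must be symmetric with unit diagonal and positive
    semi-definite within tolerance. M = 1 returns M_effective = 1 without
    an eigendecomposition; the result is clipped to [1, M].
    """
    C = np.asarray(corr, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    M = C.shape[0]
    if M == 1:
        return EffectiveTests(1, np.array([1.0]), 0.0, 1.0)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(C)
    if lam.min() < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")
    var = float(np.var(lam, ddof=1))
    m_eff = 1.0 + (M - 1) * (1.0 - var / M)
    m_eff = float(np.clip(m_eff, 1.0, M))
    return EffectiveTests(M, lam, var, m_eff)


def sidak_adjust(p_raw, m_effective: float):
    """Šidák adjustment p_adj = 1 - (1 - p)^M_effective.

    Monotone in both arguments; never below the raw p. Computed via
    expm1/log1p for accuracy at small p.
    """
    if m_effective < 1:
        raise ValueError("m_effective must be >= 1")
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        adj = -np.expm1(m_effective * np.log1p(-p))
    adj = np.where(p >= 1.0, 1.0, adj)
    out = np.clip(adj, p, 1.0)
    return float(out) if out.ndim == 0 else out
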