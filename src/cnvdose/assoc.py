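"""MultiPhen-style association models for CNV dosage (or raw LRR).

Three linear modes, each usable with the countAll dosage or directly with
corrected LRR as the CNV signal:

* **univariate** — the standard GWAS direction, one phenotype at a time:
  ``glm(phenotype ~ covariates + dosage)`` with a Wald test on the dosage
  coefficient (exact t inference for the Gaussian family).
* **joint (reverse regression)** — the multivariate direction: a Gaussian
  regression of dosage on *all* phenotypes plus covariates, testing the
  phenotype block jointly against the covariates-only null. The reported
  statistic is the likelihood-ratio value -2*(ll0 - ll1) =
  n*log(RSS0/RSS1) (asymptotically chi^2 with df = number of traits); the
  p value comes from the exact nested-model F test, which makes the
  single-trait joint p identical to the univariate p (the forward/reverse
  symmetry of the correlation test).
* **joint with backward variable selection** — repeatedly drop the trait
  with the largest per-coefficient Wald p above ``alpha_step`` and refit;
  the final model is tested against the covariates-only null with df =
  retained traits (p = 1 by convention when nothing survives).

Also here: cis CNV-QTL pairing of dosage probes with expression probes in
a window around each gene, and the reciprocal-dosage scan (gene pairs
where A's dosage hits B's expression and vice versa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_P = np.nextafter(0.0, 1.0)
DEFAULT_ALPHA_STEP = 0.05
DEFAULT_WINDOW_BP = 5_000


@dataclass
class AssocResult:
    """One probe x trait-set association result."""

    probe_id: str
    traits: list[str]
    model: str
    beta: dict[str, float]
    statistic: float
    df: int
    p_raw: float
    n_used: int
    p_adjusted: float | None = None
    flag: str | None = None

    def to_row(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "model": self.model,
            "traits": ";".join(self.traits),
            "beta": ";".join(f"{self.beta[t]:.6g}" for t in self.traits if t in self.beta),
            "stat": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_adj": self.p_adjusted,
            "n": self.n_used,
            "flag": self.flag or "",
        }


# ---------------------------------------------------------------------------
# Internals


def _as_matrix(covariates) -> tuple[np.ndarray | None, list[str]]:
    if covariates is None:
        return None, []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    if isinstance(covariates, pd.Series):
        return covariates.to_numpy(dtype=float)[:, None], [covariates.name or "cov1"]
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"cov{i + 1}" for i in range(arr.shape[1])]


def _listwise(*arrays):
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a).all(axis=1) if a.ndim == 2 else np.isfinite(a)
    return mask


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with exact t inference: (beta, se, pvals, rss, dfe)."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dfe = n - rank
    XtX_inv = np.linalg.pinv(X.T @ X)
    sigma2 = rss / dfe if dfe > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dfe) if dfe > 0 else np.full(p, np.nan)
    return beta, se, pvals, rss, dfe


# ---------------------------------------------------------------------------
# The three models


def univariate(
    trait,
    dosage,
    covariates=None,
    family: str = "gaussian",
    probe_id: str = "",
    trait_name: str = "trait",
) -> AssocResult:
    """Standard univariate GWAS model: phenotype ~ covariates + dosage.

    Gaussian traits use exact OLS t inference (identical to the Pearson
    correlation t test when there are no covariates); binomial and poisson
    traits use a GLM Wald z test. Samples with any missing value are
    dropped listwise. A zero-variance dosage column is flagged
    ``monomorphic``; perfect separation in a binomial fit is flagged, not
    raised.
    """
    y = np.asarray(trait, dtype=float)
    d = np.asarray(dosage, dtype=float)
    C, _ = _as_matrix(covariates)
    keep = _listwise(y, d, C)
    y, d = y[keep], d[keep]
    C = C[keep] if C is not None else None
    n = int(keep.sum())
    base = dict(probe_id=probe_id, traits=[trait_name], model="univariate", n_used=n)
    if n == 0 or np.ptp(d) == 0:
        return AssocResult(beta={trait_name: np.nan}, statistic=np.nan, df=1,
                           p_raw=np.nan, flag="monomorphic", **base)
    X = np.column_stack([np.ones(n)] + ([C] if C is not None else []) + [d])
    if family == "gaussian":
        beta, se, pvals, rss, dfe = _ols(X, y)
        p = pvals[-1]
        flag = None
        if not np.isfinite(p) or p <= 0:
            p, flag = MIN_P, "degenerate"
        return AssocResult(beta={trait_name: float(beta[-1])}, statistic=float(beta[-1] / se[-1])
                           if se[-1] > 0 else np.inf, df=1, p_raw=float(p), flag=flag, **base)
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    fam = {"binomial": sm.families.Binomial(), "poisson": sm.families.Poisson()}.get(family)
    if fam is None:
        raise ValueError(f"unknown family {family!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam).fit()
        z = res.tvalues[-1]
        p = res.pvalues[-1]
        flag = None
        if not np.isfinite(p):
            p, flag = MIN_P, "degenerate"
        return AssocResult(beta={trait_name: float(res.params[-1])}, statistic=float(z),
                           df=1, p_raw=float(max(p, MIN_P)), flag=flag, **base)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return AssocResult(beta={trait_name: np.nan}, statistic=np.nan, df=1,
                           p_raw=np.nan, flag="separation", **base)


def _drop_collinear(T: np.ndarray, names: list[str], base: np.ndarray):
    """Drop trait columns that add nothing to the column space of base."""
    kept_idx: list[int] = []
    cur = base
    for j in range(T.shape[1]):
        trial = np.column_stack([cur, T[:, j]])
        if np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(cur):
            kept_idx.append(j)
            cur = trial
    if len(kept_idx) < T.shape[1]:
        dropped = [names[j] for j in range(T.shape[1]) if j not in kept_idx]
        warnings.warn(f"dropping collinear traits: {dropped}", stacklevel=3)
    return T[:, kept_idx], [names[j] for j in kept_idx]


def joint_reverse(
    dosage,
    traits,
    covariates=None,
    probe_id: str = "",
    model_name: str = "joint",
) -> AssocResult:
    """MultiPhen reverse (joint) regression: dosage ~ traits + covariates.

    Tests all trait coefficients jointly against the covariates-only null.
    The statistic is the Gaussian likelihood-ratio value; the p value is
    the exact nested-model F test (see module docstring).
    """
    traits = pd.DataFrame(traits)
    names = [str(c) for c in traits.columns]
    if not names:
        raise ValueError("at least one trait required")
    d = np.asarray(dosage, dtype=float)
    T = traits.to_numpy(dtype=float)
    C, _ = _as_matrix(covariates)
    keep = _listwise(d, T, C)
    d, T = d[keep], T[keep]
    C = C[keep] if C is not None else None
    n = int(keep.sum())
    n_cov = 0 if C is None else C.shape[1]
    if n < T.shape[1] + n_cov + 2:
        raise ValueError(f"n = {n} too small for {T.shape[1]} traits + {n_cov} covariates")
    base_cols = [np.ones(n)] + ([C] if C is not None else [])
    X0 = np.column_stack(base_cols)
    T, names = _drop_collinear(T, names, X0)
    q = T.shape[1]
    if q == 0:
        return AssocResult(probe_id=probe_id, traits=[], model=model_name, beta={},
                           statistic=0.0, df=0, p_raw=1.0, n_used=n, flag="all_collinear")
    X1 = np.column_stack(base_cols + [T])
    beta0, _, _, rss0, _ = _ols(X0, d)
    beta1, se1, _, rss1, dfe = _ols(X1, d)
    betas = {nm: float(beta1[X0.shape[1] + j]) for j, nm in enumerate(names)}
    if rss1 <= 0 or dfe <= 0:
        return AssocResult(probe_id=probe_id, traits=names, model=model_name, beta=betas,
                           statistic=np.inf, df=q, p_raw=MIN_P, n_used=n, flag="degenerate")
    lrt = n * np.log(rss0 / rss1)
    F = ((rss0 - rss1) / q) / (rss1 / dfe)
    p = float(stats.f.sf(F, q, dfe))
    return AssocResult(probe_id=probe_id, traits=names, model=model_name, beta=betas,
                       statistic=float(lrt), df=q, p_raw=max(p, MIN_P), n_used=n)


def joint_selection(
    dosage,
    traits,
    covariates=None,
    alpha_step: float = DEFAULT_ALPHA_STEP,
    probe_id: str = "",
) -> AssocResult:
    """Joint model with backward variable selection.

    Starting from all traits, repeatedly drop the trait with the largest
    per-coefficient p above ``alpha_step`` and refit; stop when every
    retained trait is significant at ``alpha_step`` or none remain. The
    final retained set is tested against the covariates-only null; an
    empty final set reports p = 1 by convention.
    """
    traits = pd.DataFrame(traits)
    d = np.asarray(dosage, dtype=float)
    T_all = traits.to_numpy(dtype=float)
    C, _ = _as_matrix(covariates)
    keep = _listwise(d, T_all, C)
    d, T_all = d[keep], T_all[keep]
    C = C[keep] if C is not None else None
    n = int(keep.sum())
    names = [str(c) for c in traits.columns]
    n_cov = 0 if C is None else C.shape[1]
    if n < T_all.shape[1] + n_cov + 2:
        raise ValueError(f"n = {n} too small for {T_all.shape[1]} traits + {n_cov} covariates")
    base_cols = [np.ones(n)] + ([C] if C is not None else [])
    X0 = np.column_stack(base_cols)
    T, names = _drop_collinear(T_all, names, X0)
    active = list(range(T.shape[1]))
    while active:
        X1 = np.column_stack(base_cols + [T[:, active]])
        _, _, pvals, _, _ = _ols(X1, d)
        trait_p = pvals[X0.shape[1]:]
        worst = int(np.nanargmax(trait_p))
        if np.isnan(trait_p[worst]) or trait_p[worst] > alpha_step:
            active.pop(worst)
        else:
            break
    if not active:
        return AssocResult(probe_id=probe_id, traits=[], model="joint_selected", beta={},
                           statistic=0.0, df=0, p_raw=1.0, n_used=n, flag="empty_selection")
    sel = pd.DataFrame(T[:, active], columns=[names[j] for j in active])
    res = joint_reverse(d, sel, covariates=C, probe_id=probe_id, model_name="joint_selected")
    return res


def lrr_assoc(
    traits,
    lrr,
    covariates=None,
    mode: str = "univariate",
    probe_id: str = "",
    **kwargs,
) -> AssocResult:
    """LRR-based replication models: the same three modes with corrected
    LRR as the CNV signal in place of countAll."""
    if mode == "univariate":
        res = univariate(traits, lrr, covariates=covariates, probe_id=probe_id, **kwargs)
        res.model = "lrr_univariate"
    elif mode == "joint":
        res = joint_reverse(lrr, traits, covariates=covariates, probe_id=probe_id,
                            model_name="lrr_joint")
    elif mode == "joint_selected":
        res = joint_selection(lrr, traits, covariates=covariates, probe_id=probe_id, **kwargs)
        res.model = "lrr_joint_selected"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return res


# ---------------------------------------------------------------------------
# cis CNV-QTL


def _gene_of_probe(chrom: str, pos: int, annotation: pd.DataFrame) -> str | None:
    hit = annotation[
        (annotation["chrom"].astype(str) == str(chrom))
        & (annotation["start"] <= pos)
        & (annotation["end"] >= pos)
    ]
    return str(hit.iloc[0]["gene"]) if len(hit) else None


def cis_qtl(
    count_all: pd.DataFrame,
    cnv_probe_map: pd.DataFrame,
    expression: Mapping[str, pd.DataFrame],
    gene_annotation: pd.DataFrame,
    expr_probe_genes: Mapping[str, str],
    window_bp: int = DEFAULT_WINDOW_BP,
    covariates=None,
) -> pd.DataFrame:
    """Pair CNV probes with expression probes in a window around each gene.

    For every gene, CNV probes within [start - window, end + window]
    (1-based inclusive) are tested against each of the gene's expression
    probes (``expression ~ dosage`` univariate Gaussian model), per region
    label. The CNV probe's own gene (body containment) is annotated for
    the reciprocal scan. Requires overlapping samples between the dosage
    and expression panels.
    """
    pm = cnv_probe_map.set_index("probe_id")
    gene_probes: dict[str, list[str]] = {}
    for probe, gene in expr_probe_genes.items():
        gene_probes.setdefault(str(gene), []).append(probe)
    rows = []
    for _, g in gene_annotation.iterrows():
        lo, hi = int(g["start"]) - window_bp, int(g["end"]) + window_bp
        near = pm[
            (pm["chrom"].astype(str) == str(g["chrom"])) & (pm["pos"] >= lo) & (pm["pos"] <= hi)
        ]
        eprobes = gene_probes.get(str(g["gene"]), [])
        if near.empty or not eprobes:
            continue
        for region, expr in expression.items():
            shared = count_all.index.intersection(expr.index)
            if len(shared) == 0:
                raise ValueError(f"no overlapping samples with expression region {region!r}")
            for cnv_probe, crow in near.iterrows():
                dose = count_all.loc[shared, cnv_probe]
                cov = covariates.loc[shared] if covariates is not None else None
                cnv_gene = _gene_of_probe(crow["chrom"], int(crow["pos"]), gene_annotation)
                for eprobe in eprobes:
                    if eprobe not in expr.columns:
                        raise ValueError(f"unknown expression probe {eprobe!r}")
                    res = univariate(
                        expr.loc[shared, eprobe], dose, covariates=cov,
                        probe_id=str(cnv_probe), trait_name=str(eprobe),
                    )
                    rows.append(
                        {
                            "region": region,
                            "gene": str(g["gene"]),
                            "expr_probe": str(eprobe),
                            "cnv_probe": str(cnv_probe),
                            "cnv_gene": cnv_gene,
                            "chrom": str(crow["chrom"]),
                            "pos": int(crow["pos"]),
                            "beta": res.beta.get(str(eprobe), np.nan),
                            "stat": res.statistic,
                            "df": res.df,
                            "p_raw": res.p_raw,
                            "n": res.n_used,
                            "flag": res.flag or "",
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["region", "gene", "expr_probe", "cnv_probe", "cnv_gene", "chrom", "pos",
                 "beta", "stat", "df", "p_raw", "n", "flag"],
    )


def reciprocal_scan(qtl: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Gene pairs with significant dosage->expression effects both ways.

    A pair (A, B) is reported when some test of A-dosage against
    B-expression and some test of B-dosage against A-expression both fall
    under ``p_threshold``. Pairs are reported once, lexicographically
    ordered, with each direction's minimum p.
    """
    tab = qtl.dropna(subset=["cnv_gene", "p_raw"])
    tab = tab[tab["cnv_gene"] != tab["gene"]]
    best = tab.groupby(["cnv_gene", "gene"])["p_raw"].min()
    pairs = []
    for (a, b), p_ab in best.items():
        if (b, a) not in best.index:
            continue
        lo, hi = sorted([a, b])
        if (lo, hi) in {(x, y) for x, y, *_ in pairs}:
            continue
        p_ba = best.loc[(b, a)]
        p_lo_hi = p_ab if (a, b) == (lo, hi) else p_ba
        p_hi_lo = p_ba if (a, b) == (lo, hi) else p_ab
        if p_lo_hi < p_threshold and p_hi_lo < p_threshold:
            pairs.append((lo, hi, float(p_lo_hi), float(p_hi_lo)))
    pairs.sort()
    return pd.DataFrame(pairs, columns=["gene_a", "gene_b", "p_a_to_b", "p_b_to_a"])
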