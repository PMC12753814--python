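"""Association models: identities, null behaviour, selection, cis QTL."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvdose.assoc import (
    cis_qtl,
    joint_reverse,
    joint_selection,
    lrr_assoc,
    reciprocal_scan,
    univariate,
)
from cnvdose.simulate import CisEffect, simulate_expression


class TestUnivariate:
    def test_gaussian_p_equals_pearson_t_test(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(2, 0.5, 60)
            y = 0.2 * d + rng.normal(0, 1, 60)
            res = univariate(y, d)
            _, p = stats.pearsonr(y, d)
            assert abs(res.p_raw - p) < 1e-10

    def test_monomorphic_dosage_flagged(self):
        res = univariate(np.random.default_rng(0).normal(0, 1, 30), np.full(30, 2.0))
        assert res.flag == "monomorphic"
        assert np.isnan(res.p_raw)

    def test_perfect_fit_flagged_with_minimum_p(self):
        d = np.arange(30, dtype=float)
        res = univariate(d.copy(), d)
        assert res.flag == "degenerate"
        assert res.p_raw > 0

    def test_listwise_deletion_counts_reported(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 50)
        d = rng.normal(2, 0.5, 50)
        y[:5] = np.nan
        res = univariate(y, d)
        assert res.n_used == 45

    def test_binomial_family_runs_and_detects_effect(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, 400).astype(float)
        p = 1 / (1 + np.exp(-(-0.5 + 1.2 * d)))
        y = (rng.random(400) < p).astype(float)
        res = univariate(y, d, family="binomial")
        assert res.p_raw < 1e-4
        assert res.beta["trait"] > 0

    def test_type_one_error_rate_controlled(self):
        rej = 0
        reps = 400
        for i in range(reps):
            rng = np.random.default_rng(10_000 + i)
            d = rng.normal(2, 0.5, 100)
            y = rng.normal(0, 1, 100)
            rej += univariate(y, d).p_raw < 0.05
        lo, hi = stats.binom.ppf([0.0025, 0.9975], reps, 0.05) / reps
        assert lo <= rej / reps <= hi


class TestJointReverse:
    def test_single_trait_matches_univariate(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = rng.normal(2, 0.5, 70)
            y = 0.3 * d + rng.normal(0, 1, 70)
            c = rng.normal(0, 1, (70, 2))
            pf = univariate(y, d, covariates=c).p_raw
            pr = joint_reverse(d, pd.DataFrame({"t": y}), covariates=c).p_raw
            assert abs(pf - pr) < 1e-8

    def test_statistic_matches_explicit_likelihood_oracle(self):
        rng = np.random.default_rng(5)
        n = 80
        d = rng.normal(2, 0.5, n)
        T = rng.normal(0, 1, (n, 3))
        T[:, 0] += 0.4 * d
        res = joint_reverse(d, pd.DataFrame(T, columns=["a", "b", "c"]))

        def gaussian_ll(y, X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            s2 = rss / len(y)
            return -0.5 * len(y) * (np.log(2 * np.pi * s2) + 1)

        X0 = np.ones((n, 1))
        X1 = np.column_stack([np.ones(n), T])
        lrt = -2 * (gaussian_ll(d, X0) - gaussian_ll(d, X1))
        assert res.statistic == pytest.approx(lrt, abs=1e-8)
        assert res.df == 3

    def test_null_lrt_follows_chi_square(self):
        lrts = []
        for i in range(400):
            rng = np.random.default_rng(20_000 + i)
            d = rng.normal(2, 0.5, 300)
            T = rng.normal(0, 1, (300, 4))
            lrts.append(joint_reverse(d, pd.DataFrame(T)).statistic)
        assert stats.kstest(lrts, stats.chi2(4).cdf).pvalue > 0.01

    def test_collinear_trait_dropped_with_reduced_df(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 60)
        traits = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(0, 1, 60)})
        with pytest.warns(UserWarning, match="collinear"):
            res = joint_reverse(rng.normal(2, 0.5, 60), traits)
        assert res.df == 2

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="too small"):
            joint_reverse(rng.normal(0, 1, 4), pd.DataFrame(rng.normal(0, 1, (4, 3))))


class TestJointSelection:
    def test_single_trait_identical_to_joint(self):
        rng = np.random.default_rng(8)
        d = rng.normal(2, 0.5, 80)
        y = pd.DataFrame({"t": 1.5 * d + rng.normal(0, 1, 80)})
        a = joint_reverse(d, y)
        b = joint_selection(d, y)
        assert b.p_raw == pytest.approx(a.p_raw, abs=1e-12)
        assert b.traits == ["t"]

    def test_strong_causal_trait_retained(self):
        hits = 0
        for i in range(100):
            rng = np.random.default_rng(30_000 + i)
            d = rng.binomial(2, 0.3, 250).astype(float)
            T = rng.normal(0, 1, (250, 5))
            T[:, 2] += 0.6 * d
            res = joint_selection(d, pd.DataFrame(T, columns=list("abcde")))
            hits += "c" in res.traits
        assert hits >= 95

    def test_all_null_traits_mostly_empty_with_unit_p(self):
        empty = 0
        for i in range(100):
            rng = np.random.default_rng(40_000 + i)
            res = joint_selection(rng.normal(0, 1, 150), pd.DataFrame(rng.normal(0, 1, (150, 4))))
            if res.flag == "empty_selection":
                assert res.p_raw == 1.0
                empty += 1
        assert empty > 50


class TestLrrAssoc:
    def test_lrr_and_dosage_agree_on_top_probe_when_proportional(self):
        rng = np.random.default_rng(9)
        n, p = 120, 10
        dosage = rng.binomial(2, 0.3, (n, p)).astype(float)
        lrr = 0.3 * (dosage - 2) + rng.normal(0, 0.05, (n, p))
        y = 0.5 * dosage[:, 4] + rng.normal(0, 1, n)
        p_dos = [univariate(y, dosage[:, j]).p_raw for j in range(p)]
        p_lrr = [lrr_assoc(y, lrr[:, j], mode="univariate").p_raw for j in range(p)]
        assert np.argmin(p_dos) == np.argmin(p_lrr) == 4

    def test_permuted_traits_behave_as_null(self):
        rej = 0
        for i in range(200):
            rng = np.random.default_rng(50_000 + i)
            lrr = rng.normal(0, 0.2, 150)
            T = rng.normal(0, 1, (150, 3))
            rej += lrr_assoc(T, lrr, mode="joint").p_raw < 0.05
        lo, hi = stats.binom.ppf([0.0025, 0.9975], 200, 0.05) / 200
        assert lo <= rej / 200 <= hi

    def test_constant_lrr_flagged_monomorphic(self):
        res = lrr_assoc(np.random.default_rng(0).normal(0, 1, 40), np.zeros(40),
                        mode="univariate")
        assert res.flag == "monomorphic"


def _qtl_fixture(seed, gamma_ab=1.0, gamma_ba=1.0):
    """Six genes on one chromosome; (g0, g1) adjacent within the cis window."""
    rng = np.random.default_rng(seed)
    n = 150
    genes, pos = [], 100_000
    for i in range(6):
        genes.append({"gene": f"g{i}", "chrom": "1", "start": pos, "end": pos + 4_000})
        pos += 4_000 + (1_000 if i % 2 == 0 else 50_000)
    ann = pd.DataFrame(genes)
    cnv_pm = pd.DataFrame({
        "probe_id": [f"cnv{i}" for i in range(6)],
        "chrom": "1",
        "pos": [(g["start"] + g["end"]) // 2 for g in genes],
    })
    dosages = pd.DataFrame(
        {f"g{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(6)},
        index=[f"s{j}" for j in range(n)],
    )
    probe_genes = {f"e{i}": f"g{i}" for i in range(6)}
    effects = []
    if gamma_ab:
        effects.append(CisEffect("g0", "e1", gamma_ab))
    if gamma_ba:
        effects.append(CisEffect("g1", "e0", gamma_ba))
    expr = simulate_expression(dosages, probe_genes, effects, n_regions=2,
                               noise_sd=0.5, seed=seed + 1)
    count_all = pd.DataFrame({f"cnv{i}": dosages[f"g{i}"] for i in range(6)})
    return count_all, cnv_pm, expr, ann, probe_genes


class TestCisQtl:
    def test_planted_cis_effect_is_window_minimum(self):
        count_all, cnv_pm, expr, ann, probe_genes = _qtl_fixture(60)
        qtl = cis_qtl(count_all, cnv_pm, expr, ann, probe_genes, window_bp=5_000)
        g1_rows = qtl[qtl["gene"] == "g1"]
        best = g1_rows.loc[g1_rows["p_raw"].idxmin()]
        assert best["cnv_probe"] == "cnv0"  # the causal dosage probe

    def test_zero_window_excludes_outside_probes(self):
        count_all, cnv_pm, expr, ann, probe_genes = _qtl_fixture(61)
        qtl = cis_qtl(count_all, cnv_pm, expr, ann, probe_genes, window_bp=0)
        # with window 0 only each gene's own centre probe pairs with it
        assert (qtl["cnv_gene"] == qtl["gene"]).all()

    def test_shuffled_samples_give_uniform_p(self):
        pvals = []
        for seed in range(70, 90):
            count_all, cnv_pm, expr, ann, probe_genes = _qtl_fixture(seed, 0.0, 0.0)
            qtl = cis_qtl(count_all, cnv_pm, expr, ann, probe_genes, window_bp=5_000)
            pvals.extend(qtl["p_raw"].tolist())
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_no_shared_samples_rejected(self):
        count_all, cnv_pm, expr, ann, probe_genes = _qtl_fixture(62)
        shifted = {r: m.set_axis([f"x{j}" for j in range(len(m))], axis=0)
                   for r, m in expr.items()}
        with pytest.raises(ValueError, match="overlapping samples"):
            cis_qtl(count_all, cnv_pm, shifted, ann, probe_genes)


class TestReciprocalScan:
    def test_planted_reciprocal_pair_detected(self):
        count_all, cnv_pm, expr, ann, probe_genes = _qtl_fixture(63)
        qtl = cis_qtl(count_all, cnv_pm, expr, ann, probe_genes, window_bp=5_000)
        rec = reciprocal_scan(qtl, 1e-6)
        assert list(zip(rec["gene_a"], rec["gene_b"])) == [("g0", "g1")]

    def test_one_directional_effect_not_reported(self):
        count_all, cnv_pm, expr, ann, probe_genes = _qtl_fixture(64, gamma_ba=0.0)
        qtl = cis_qtl(count_all, cnv_pm, expr, ann, probe_genes, window_bp=5_000)
        assert len(reciprocal_scan(qtl, 1e-6)) == 0

    def test_zero_threshold_empty(self):
        count_all, cnv_pm, expr, ann, probe_genes = _qtl_fixture(65)
        qtl = cis_qtl(count_all, cnv_pm, expr, ann, probe_genes, window_bp=5_000)
        assert len(reciprocal_scan(qtl, 0.0)) == 0
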