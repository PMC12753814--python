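"""HMM inference: emissions, exact posteriors, Viterbi segments, EM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from cnvdose.hmm import (
    EmissionModel,
    TransitionModel,
    _forward_backward_core,
    collapse_gamma,
    em_fit,
    emission_loglik,
    forward_backward,
    joint_call,
    viterbi_segments,
)
from cnvdose.simulate import COPY_LRR_MEANS, CnvLocus, CohortConfig, make_probe_map, simulate_cohort


class TestEmission:
    def test_lrr_term_closed_form_at_cluster_mean(self):
        model = EmissionModel(lrr_var=0.25)
        # BAF missing: only the Gaussian LRR term contributes.
        ll = emission_loglik(model.cluster_means[2], np.nan, 2, model)
        assert abs(ll - (-0.5 * np.log(2 * np.pi * 0.25))) < 1e-12

    def test_diploid_baf_mixture_symmetric_around_half(self):
        model = EmissionModel()
        for delta in (0.05, 0.1, 0.2):
            lo = emission_loglik(0.0, 0.5 - delta, 2, model)
            hi = emission_loglik(0.0, 0.5 + delta, 2, model)
            assert abs(lo - hi) < 1e-10

    def test_homozygous_deletion_cluster_ignores_baf(self):
        model = EmissionModel()
        vals = [emission_loglik(-4.5, b, 0, model) for b in (0.0, 0.3, 0.7, 1.0)]
        assert max(vals) - min(vals) < 1e-12

    def test_infinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            emission_loglik(np.inf, 0.5, 2, EmissionModel())


class TestForwardBackward:
    def test_equals_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(42)
        T, K = 6, 5
        logB = rng.normal(0, 1, (1, T, K))
        A = TransitionModel(stay_prob=0.8).matrix(K)
        logA, logpi = np.log(A), np.log(np.full(K, 1.0 / K))
        gamma, ll = _forward_backward_core(logB, logA, logpi)
        post = np.zeros((T, K))
        lps = []
        for path in itertools.product(range(K), repeat=T):
            lp = logpi[path[0]] + logB[0, 0, path[0]]
            for t in range(1, T):
                lp += logA[path[t - 1], path[t]] + logB[0, t, path[t]]
            lps.append(lp)
            for t in range(T):
                post[t, path[t]] += np.exp(lp)
        Z = np.exp(logsumexp(lps))
        assert np.abs(gamma[0] - post / Z).max() < 1e-9
        assert abs(ll[0] - logsumexp(lps)) < 1e-9

    def test_uninformative_emissions_give_stationary_posterior(self):
        K = 9
        logB = np.zeros((1, 20, K))
        trans = TransitionModel()
        gamma, _ = _forward_backward_core(
            logB, np.log(trans.matrix(K)), np.log(trans.initial(K))
        )
        assert np.abs(gamma - 1.0 / K).max() < 1e-12

    def test_single_probe_posterior_is_prior_times_likelihood(self):
        model = EmissionModel()
        trans = TransitionModel()
        gamma, _ = forward_backward([0.0], [0.5], model, trans)
        logb = np.array([emission_loglik(0.0, 0.5, k, model) for k in range(model.n_clusters)])
        expected = np.exp(logb) * trans.initial(model.n_clusters)
        expected /= expected.sum()
        assert np.abs(gamma[0] - expected).max() < 1e-12

    def test_posteriors_normalised_long_sequence(self):
        rng = np.random.default_rng(0)
        model = EmissionModel(lrr_var=0.04)
        lrr = rng.normal(0, 0.2, 2000)
        baf = rng.random(2000)
        gamma, ll = forward_backward(lrr, baf, model, TransitionModel())
        assert np.isfinite(ll)
        assert np.abs(gamma.sum(axis=1) - 1.0).max() < 1e-9


class TestViterbiSegments:
    def _zero_noise_panel(self, n_probes=100, del_range=(40, 59)):
        pm = make_probe_map(n_probes, seed=1)
        copy = np.full(n_probes, 2)
        copy[del_range[0]:del_range[1] + 1] = 1
        lrr = COPY_LRR_MEANS[copy].astype(float)
        baf = np.where(copy == 1, 0.0, 0.5)
        return pm, lrr, baf, copy

    def test_planted_heterozygous_deletion_recovered_exactly(self):
        pm, lrr, baf, copy = self._zero_noise_panel()
        model = EmissionModel(lrr_var=0.01)
        segs = viterbi_segments(lrr, baf, pm, model, TransitionModel())
        dels = segs[segs["copy_number"] == 1]
        assert len(dels) == 1
        assert dels.iloc[0]["start"] == pm["pos"].iloc[40]
        assert dels.iloc[0]["end"] == pm["pos"].iloc[59]
        assert dels.iloc[0]["n_probes"] == 20

    def test_all_diploid_sample_yields_single_neutral_segment(self):
        pm = make_probe_map(60, seed=2)
        lrr = np.zeros(60)
        baf = np.full(60, 0.5)
        segs = viterbi_segments(lrr, baf, pm, EmissionModel(lrr_var=0.01), TransitionModel())
        assert (segs["copy_number"] == 2).all()
        assert len(segs) == 1

    def test_two_separated_cnvs_give_two_segments(self):
        pm = make_probe_map(200, seed=3)
        copy = np.full(200, 2)
        copy[20:35] = 1
        copy[120:140] = 3
        lrr = COPY_LRR_MEANS[copy].astype(float)
        baf = np.where(copy == 1, 0.0, np.where(copy == 3, 1 / 3, 0.5))
        segs = viterbi_segments(lrr, baf, pm, EmissionModel(lrr_var=0.01), TransitionModel())
        non_diploid = segs[segs["copy_number"] != 2]
        assert len(non_diploid) == 2
        assert set(non_diploid["copy_number"]) == {1, 3}


class TestEmFit:
    def test_loglik_trace_non_decreasing(self, noisy_cohort):
        _, post = em_fit(noisy_cohort.intensities, iters=6)
        assert np.all(np.diff(post.loglik_trace) >= -1e-6)

    def test_variance_recovered_from_inflated_init(self, probe_map):
        cfg = CohortConfig(60, probe_map, [], lrr_sd=0.15, baf_sd=0.04,
                           gc_slope=0.0, wave_amplitude=0.0, seed=21)
        cohort = simulate_cohort(cfg)
        init = EmissionModel(lrr_var=2 * 0.15**2)
        fitted, _ = em_fit(cohort.intensities, init=init, iters=15)
        assert abs(fitted.lrr_var - 0.15**2) / 0.15**2 < 0.10

    def test_near_fixed_point_when_initialised_at_truth(self, probe_map):
        cfg = CohortConfig(60, probe_map, [], lrr_sd=0.15, baf_sd=0.04,
                           gc_slope=0.0, wave_amplitude=0.0, seed=22)
        cohort = simulate_cohort(cfg)
        init = EmissionModel(lrr_var=0.15**2, baf_sd=0.04)
        fitted, _ = em_fit(cohort.intensities, init=init, iters=15)
        assert abs(fitted.lrr_var - 0.15**2) / 0.15**2 < 0.10
        assert np.array_equal(fitted.cluster_means, init.cluster_means)

    def test_call_classes_match_planted_truth_at_low_noise(self, clean_cohort):
        _, post = em_fit(clean_cohort.intensities, iters=8)
        truth = clean_cohort.true_copy_numbers.to_numpy()
        assert (post.viterbi_path == truth).mean() > 0.99

    def test_empty_cohort_rejected(self, probe_map):
        from cnvdose.panel import IntensityPanel

        empty = IntensityPanel(
            probe_map,
            pd.DataFrame(columns=list(probe_map["probe_id"]), dtype=float),
            pd.DataFrame(columns=list(probe_map["probe_id"]), dtype=float),
        )
        with pytest.raises(ValueError, match="empty"):
            em_fit(empty)


class TestJointCall:
    def _cohort_pair_same_truth(self, probe_map):
        """Two cohorts sharing one realised copy-number matrix, independent noise."""
        rng = np.random.default_rng(31)
        cfg = CohortConfig(50, probe_map, [CnvLocus(
            "1", int(probe_map["pos"].iloc[80]), int(probe_map["pos"].iloc[99]),
            "deletion", 0.3)], lrr_sd=0.1, baf_sd=0.03, gc_slope=0.0,
            wave_amplitude=0.0, seed=31, cohort_id="A")
        a = simulate_cohort(cfg)
        copy = a.true_copy_numbers.to_numpy()
        lrr = COPY_LRR_MEANS[copy] + rng.normal(0, 0.1, copy.shape)
        nb = rng.binomial(copy, 0.5)
        baf = np.where(copy > 0, nb / np.maximum(copy, 1), rng.random(copy.shape))
        baf = np.clip(baf + np.where(copy > 0, rng.normal(0, 0.03, copy.shape), 0), 0, 1)
        from cnvdose.panel import IntensityPanel

        b = IntensityPanel(
            probe_map,
            pd.DataFrame(lrr, index=a.intensities.lrr.index, columns=a.intensities.lrr.columns),
            pd.DataFrame(baf, index=a.intensities.baf.index, columns=a.intensities.baf.columns),
            cohort_id="B",
        )
        return a.intensities, b

    def test_same_truth_cohorts_get_matching_posteriors(self, probe_map):
        pa, pb = self._cohort_pair_same_truth(probe_map)
        out = joint_call([pa, pb], "A", iters=6)
        diff = np.abs(out["A"].gamma - out["B"].gamma).mean()
        assert diff < 0.02  # only noise-level disagreement

    def test_single_cohort_equals_em_fit(self, clean_cohort):
        single = em_fit(clean_cohort.intensities, iters=4)[1]
        joint = joint_call([clean_cohort.intensities], clean_cohort.intensities.cohort_id,
                           iters=4)[clean_cohort.intensities.cohort_id]
        assert np.allclose(single.gamma, joint.gamma)

    def test_disjoint_probe_sets_rejected(self, probe_map):
        pm2 = make_probe_map(50, chrom="2", seed=9)
        a = simulate_cohort(CohortConfig(5, probe_map, [], seed=1, cohort_id="A")).intensities
        b = simulate_cohort(CohortConfig(5, pm2, [], seed=2, cohort_id="B")).intensities
        with pytest.raises(ValueError, match="intersection"):
            joint_call([a, b], "A")


class TestPosteriorInvariants:
    def test_gamma_sums_to_one_and_viterbi_valid(self, clean_cohort):
        _, post = em_fit(clean_cohort.intensities, iters=5)
        assert np.abs(post.gamma.sum(axis=-1) - 1.0).max() < 1e-9
        assert post.viterbi_path.min() >= 0 and post.viterbi_path.max() <= 4

    def test_collapse_gamma_preserves_mass(self):
        rng = np.random.default_rng(1)
        g = rng.dirichlet(np.ones(9), size=(3, 7))
        c = collapse_gamma(g, EmissionModel().state_map)
        assert np.abs(c.sum(axis=-1) - 1.0).max() < 1e-12
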