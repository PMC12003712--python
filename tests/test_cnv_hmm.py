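"""HMM contracts: transitions, emissions, smoothing vs enumeration, dosages."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cnvmetabo.cnv_hmm import (
    HMMParams,
    StatePosterior,
    cnv_allele_frequency,
    emission_loglik,
    emission_loglik_matrix,
    expected_genotypes,
    forward_backward,
    transition_matrix,
    viterbi_segments,
    _forward_backward_chrom,
    _viterbi_chrom,
)
from cnvmetabo.simulate import (
    ProbeMap,
    SimulationConfig,
    simulate_cnv_truth,
    simulate_intensities,
    simulate_probe_map,
)


def _map(n, spacing=3000):
    pos = np.arange(1, n + 1) * spacing
    return ProbeMap(
        probe_id=np.array([f"p{i}" for i in range(n)]),
        chrom=np.array(["chr1"] * n),
        pos=pos,
        gc_fraction=np.full(n, 0.4),
    )


def enumerate_posteriors(logB, pos, params):
    """Brute-force smoothing posteriors and best path over all 5^T state paths."""
    T = logB.shape[0]
    A = [transition_matrix(int(d), params) for d in np.diff(pos)]
    pi = np.asarray(params.stationary_prior)
    joint = {}
    for path in itertools.product(range(5), repeat=T):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[t - 1][path[t - 1], path[t]]) + logB[t, path[t]]
        joint[path] = lp
    lps = np.array(list(joint.values()))
    m = lps.max()
    probs = np.exp(lps - m)
    Z = probs.sum()
    gamma = np.zeros((T, 5))
    for path, lp in joint.items():
        w = np.exp(lp - m) / Z
        for t, s in enumerate(path):
            gamma[t, s] += w
    best_path = max(joint, key=joint.get)
    return gamma, np.log(Z) + m, np.array(best_path), joint[best_path]


class TestTransitions:
    def test_zero_distance_zero_min_switch_gives_identity(self):
        params = HMMParams(min_switch_prob=0.0)
        assert np.allclose(transition_matrix(0, params), np.eye(5))

    def test_large_distance_forgets_toward_prior(self):
        params = HMMParams(max_switch_prob=1 - 1e-12)
        A = transition_matrix(10**12, params)
        pi = np.asarray(params.stationary_prior)
        for i in range(5):
            others = pi.copy()
            others[i] = 0
            others /= others.sum()
            expected = others.copy()
            expected[i] = 0  # with p_switch → 1, all mass leaves the diagonal
            assert np.allclose(A[i], expected, atol=1e-9)

    def test_rows_sum_to_one_over_random_distances(self):
        rng = np.random.default_rng(0)
        params = HMMParams()
        for d in rng.integers(0, 10**7, size=100):
            assert np.allclose(transition_matrix(int(d), params).sum(axis=1), 1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(-1, HMMParams())


class TestEmissions:
    def test_lrr_at_state_mean_beats_three_sd_away(self):
        params = HMMParams()
        for s in range(5):
            mu, sd = params.lrr_mean[s], params.lrr_sd[s]
            assert emission_loglik(mu, 0.5, s, params) > emission_loglik(mu + 3 * sd, 0.5, s, params)

    def test_heterozygous_baf_prefers_neutral_over_deletion(self):
        params = HMMParams()
        assert emission_loglik(0.0, 0.5, 2, params) > emission_loglik(0.0, 0.5, 1, params)

    def test_matches_direct_density_formula(self):
        rng = np.random.default_rng(1)
        params = HMMParams()
        for _ in range(20):
            lrr = rng.normal(0, 1)
            baf = rng.uniform(0, 1)
            s = int(rng.integers(0, 5))
            comps = params.baf_components[s]
            if comps:
                dens = sum(
                    w
                    * norm.pdf(baf, m, sd)
                    / (norm.cdf(1, m, sd) - norm.cdf(0, m, sd))
                    for m, sd, w in comps
                )
            else:
                dens = 1.0
            expected = norm.logpdf(lrr, params.lrr_mean[s], params.lrr_sd[s]) + np.log(dens)
            assert emission_loglik(lrr, baf, s, params) == pytest.approx(expected, abs=1e-10)

    def test_non_finite_lrr_rejected(self):
        with pytest.raises(ValueError):
            emission_loglik(np.nan, 0.5, 2, HMMParams())


class TestForwardBackward:
    def test_single_probe_posterior_is_prior_times_emission(self):
        pm = _map(1)
        params = HMMParams()
        post = forward_backward(np.array([-0.6]), np.array([0.1]), pm, params)
        logB = emission_loglik_matrix(np.array([-0.6]), np.array([0.1]), params)[0]
        expected = np.asarray(params.stationary_prior) * np.exp(logB - logB.max())
        expected /= expected.sum()
        assert np.allclose(post.gamma[0], expected, atol=1e-12)

    def test_uniform_emissions_propagate_the_prior(self):
        pm = _map(6)
        params = HMMParams()
        logB = np.zeros((6, 5))
        gamma, _ = _forward_backward_chrom(logB, pm.pos, params)
        marg = np.asarray(params.stationary_prior)
        for t in range(6):
            assert np.allclose(gamma[t], marg, atol=1e-12)
            if t < 5:
                marg = marg @ transition_matrix(int(pm.pos[t + 1] - pm.pos[t]), params)

    def test_three_probe_chain_matches_enumeration(self):
        rng = np.random.default_rng(2)
        pm = _map(3, spacing=50_000)
        params = HMMParams()
        for _ in range(10):
            lrr = rng.normal(0, 1, size=3)
            baf = rng.uniform(0, 1, size=3)
            post = forward_backward(lrr, baf, pm, params)
            logB = emission_loglik_matrix(lrr, baf, params)
            gamma_ref, ll_ref, path_ref, best_lp_ref = enumerate_posteriors(logB, pm.pos, params)
            assert np.allclose(post.gamma, gamma_ref, atol=1e-10)
            assert post.log_likelihood == pytest.approx(ll_ref, abs=1e-8)
            path, best_lp = _viterbi_chrom(logB, pm.pos, params)
            lp0 = np.log(np.asarray(params.stationary_prior)) + logB[0]
            assert np.array_equal(path, path_ref)
            assert best_lp == pytest.approx(best_lp_ref, abs=1e-8)

    def test_all_missing_chromosome_gives_uniform_posterior(self):
        pm = _map(4)
        with pytest.warns(UserWarning, match="all-missing"):
            post = forward_backward(np.full(4, np.nan), None, pm, HMMParams())
        assert np.allclose(post.gamma, 0.2)

    def test_long_sequence_no_underflow(self):
        cfg = SimulationConfig(n_samples=1, n_probes=5000, n_chromosomes=1, seed=12)
        pm = simulate_probe_map(cfg)
        truth = simulate_cnv_truth(pm, cfg)
        panel = simulate_intensities(truth, pm, cfg)
        post = forward_backward(panel.lrr[0], panel.baf[0], pm, HMMParams())
        assert np.all(np.isfinite(post.gamma))
        assert np.isfinite(post.log_likelihood)


class TestViterbiSegments:
    def test_neutral_panel_yields_no_segments(self):
        cfg = SimulationConfig(n_samples=3, n_probes=300, seed=13, lrr_noise_sd=0.1)
        pm = simulate_probe_map(cfg)
        truth = simulate_cnv_truth(pm, cfg)
        panel = simulate_intensities(truth, pm, cfg)
        segs = [
            s
            for i in range(3)
            for s in viterbi_segments(panel.lrr[i], panel.baf[i], pm, HMMParams(), f"s{i}")
        ]
        assert segs == []

    def test_planted_region_recovered_within_two_probes(self):
        from cnvmetabo.simulate import CNVRegion

        cfg = SimulationConfig(
            n_samples=1, n_probes=200, n_chromosomes=1, seed=14, lrr_noise_sd=0.1
        )
        pm = simulate_probe_map(cfg)
        lo = 90
        region = CNVRegion("chr1", int(pm.pos[lo]), int(pm.pos[lo + 19]), 1, 1.0)
        cfg = replace(cfg, regions=(region,))
        truth = simulate_cnv_truth(pm, cfg)
        panel = simulate_intensities(truth, pm, cfg)
        segs = viterbi_segments(panel.lrr[0], panel.baf[0], pm, HMMParams(), "s0")
        assert len(segs) == 1
        seg = segs[0]
        assert seg.state == 1
        start_idx = int(np.searchsorted(pm.pos, seg.start_pos))
        end_idx = int(np.searchsorted(pm.pos, seg.end_pos))
        assert abs(start_idx - lo) <= 2 and abs(end_idx - (lo + 19)) <= 2


class TestDosages:
    def test_worked_example_puts_countall_at_1_3(self):
        gamma = np.zeros((1, 1, 5))
        gamma[0, 0, 1] = 0.7
        gamma[0, 0, 2] = 0.3
        dos = expected_genotypes(StatePosterior(gamma=gamma))
        assert dos.count_all[0, 0] == pytest.approx(1.3, abs=1e-15)

    def test_pure_neutral_and_symmetric_extremes(self):
        gamma = np.zeros((2, 1, 5))
        gamma[0, 0, 2] = 1.0
        gamma[1, 0, 0] = 0.5
        gamma[1, 0, 4] = 0.5
        dos = expected_genotypes(StatePosterior(gamma=gamma))
        assert dos.count_all[0, 0] == 2.0
        assert dos.count_all[1, 0] == 2.0

    def test_unnormalised_posterior_rejected(self):
        gamma = np.full((1, 1, 5), 0.3)  # sums to 1.5
        post = StatePosterior.__new__(StatePosterior)  # bypass constructor check
        object.__setattr__(post, "gamma", gamma)
        with pytest.raises(ValueError, match="not normalised"):
            expected_genotypes(post)

    def test_restricted_dosages_renormalise(self):
        gamma = np.zeros((1, 1, 5))
        gamma[0, 0] = [0.1, 0.2, 0.4, 0.2, 0.1]
        dos = expected_genotypes(StatePosterior(gamma=gamma))
        assert dos.del_only[0, 0] == pytest.approx((0.2 + 0.8) / 0.7)
        assert dos.dup_only[0, 0] == pytest.approx((0.8 + 0.6 + 0.4) / 0.7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5))
    def test_countall_always_in_0_4(self, raw):
        gamma = np.array(raw)[None, None, :]
        gamma /= gamma.sum()
        dos = expected_genotypes(StatePosterior(gamma=gamma))
        assert 0.0 <= dos.count_all[0, 0] <= 4.0


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "dosages, expected",
        [
            (np.full(10, 2.0), 0.0),
            (np.full(10, 1.0), 0.5),
            (np.array([1.0] * 5 + [2.0] * 5), 0.25),
        ],
    )
    def test_folded_frequency_formula(self, dosages, expected):
        assert cnv_allele_frequency(dosages) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cnv_allele_frequency(np.array([]))


def test_noise_degrades_posterior_confidence():
    """Raising LRR noise lowers the mean max-posterior (sanity trend)."""
    confidences = []
    for noise in (0.1, 0.3, 0.6):
        cfg = SimulationConfig(n_samples=3, n_probes=200, seed=15, lrr_noise_sd=noise)
        pm = simulate_probe_map(cfg)
        truth = simulate_cnv_truth(pm, cfg)
        panel = simulate_intensities(truth, pm, cfg)
        conf = np.mean(
            [
                forward_backward(panel.lrr[i], panel.baf[i], pm, HMMParams()).gamma.max(axis=1).mean()
                for i in range(3)
            ]
        )
        confidences.append(conf)
    assert confidences[0] > confidences[1] > confidences[2]
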