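import itertools
import math

import numpy as np
import pytest

from ibdcoal.identify import CandidateSegment, IdentifyParams
from ibdcoal.panel_io import (
    DemographicModel,
    coalescent_prior,
    make_quantile_discretization,
)
from ibdcoal.verify import (
    EmissionModel,
    PairObservation,
    PosteriorMatrix,
    TransitionModel,
    VerifyParams,
    calibrate_emission,
    decode_posterior,
    detect,
    emission_probs,
    read_ibd_file,
    refine_segment,
    smc_rate_matrix,
    transition_matrix,
    write_ibd_file,
)

from conftest import make_random_panel


@pytest.fixture
def disc3(const_model):
    return coalescent_prior(const_model, [0.0, 100.0, 2000.0, np.inf])


# ---------------------------------------------------------------------------
# Transition model
# ---------------------------------------------------------------------------


class TestTransitionMatrix:
    def test_zero_distance_identity(self, const_model, disc3):
        P = transition_matrix(0.0, disc3, const_model)
        assert np.allclose(P, np.eye(3))

    def test_rows_sum_to_one(self, two_epoch_model):
        disc = make_quantile_discretization(two_epoch_model, 20, pinned=[50.0])
        tm = TransitionModel(disc, two_epoch_model)
        for d in (0.01, 0.1, 1.0, 10.0):
            P = tm(d)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(P >= 0)

    def test_prior_is_stationary(self, two_epoch_model):
        disc = make_quantile_discretization(two_epoch_model, 20, pinned=[50.0])
        tm = TransitionModel(disc, two_epoch_model)
        pi = disc.probabilities
        P = tm(0.37)
        # products of transition matrices preserve the prior
        prod = np.linalg.matrix_power(P, 7) @ tm(2.0)
        assert np.allclose(pi @ P, pi, atol=1e-6)
        assert np.allclose(pi @ prod, pi, atol=1e-6)

    def test_long_distance_loses_linkage(self, const_model, disc3):
        P = transition_matrix(1e4, disc3, const_model)
        assert np.abs(P - disc3.probabilities).max() < 1e-4

    def test_negative_distance_rejected(self, const_model, disc3):
        with pytest.raises(ValueError):
            transition_matrix(-0.1, disc3, const_model)

    def test_generator_matches_dense_quadrature(self, const_model, disc3):
        """Dense-grid oracle: rebuild the jump-rate integrals on a 1e4-point
        trapezoid grid and compare off-diagonal generator entries."""
        from scipy.integrate import cumulative_trapezoid

        model = const_model
        b = disc3.boundaries.copy()
        b[-1] = model.upper_time_bound(1e-12)
        K = disc3.n_intervals
        pieces = [np.linspace(b[k], b[k + 1], 3334)[:-1] for k in range(K)]
        grid = np.unique(np.concatenate(pieces + [[b[-1]]]))

        H = model.cumulative_hazard(grid)
        f = model.rate(grid) * np.exp(-H)
        Wg = cumulative_trapezoid(np.exp(H), grid, initial=0.0)

        def idx(lo, hi):
            return (grid >= lo) & (grid < hi)

        A = np.zeros((K, K))
        for k in range(K):
            mk = idx(b[k], b[k + 1])
            for l in range(K):
                ml = idx(b[l], b[l + 1])
                # kappa_l(t) = 2 int_{I_l} f(t') W(min(t, t')) dt'
                # W is monotone, so W(min(t, t')) = min(W(t), W(t'))
                w_min = np.minimum.outer(Wg[mk], Wg[ml])
                inner = np.trapezoid(f[ml][None, :] * w_min, grid[ml], axis=1)
                A[k, l] = np.trapezoid(f[mk] * 2 * inner, grid[mk])
        pi = disc3.probabilities
        R_oracle = A / pi[:, None]
        R = smc_rate_matrix(disc3, model)
        for k in range(K):
            for l in range(K):
                if k != l:
                    assert R[k, l] == pytest.approx(R_oracle[k, l], rel=2e-2, abs=1e-3)


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------


class TestEmission:
    def make_emodel(self):
        return EmissionModel(np.array([0.0, 0.5, 1.0]), np.array([1e-4, 5e-4]))

    def test_t_zero_is_certain_concordance(self):
        em = self.make_emodel()
        assert emission_probs(True, 0.3, 0.0, em) == 1.0
        assert emission_probs(False, 0.3, 0.0, em) == 0.0

    def test_monotone_in_t(self):
        em = self.make_emodel()
        t = np.linspace(1, 5000, 50)
        p = em.p_discordant(0.7, t)
        assert np.all(np.diff(p) > 0)

    def test_uncalibrated_raises(self):
        with pytest.raises(ValueError, match="calibrated"):
            emission_probs(True, 0.3, 10.0, None)

    def test_single_interval_closed_form(self, const_model):
        # one interval: mu = -ln(1 - p) / (2 t*), t* = E[TMRCA] = Ne
        disc = coalescent_prior(const_model, [0.0, np.inf])
        t_star = disc.representatives[0]
        rng = np.random.default_rng(3)
        panel = make_random_panel(rng, 6, 200)
        em = calibrate_emission(panel, disc, const_model, n_freq_bins=1)
        # observed discordance over all pairs
        n = panel.n_haplotypes
        ps = [
            (panel.alleles[i] != panel.alleles[j]).mean()
            for i in range(n) for j in range(i + 1, n)
        ]
        p_hat = float(np.mean(ps))
        assert em.mu[0] == pytest.approx(-math.log(1 - p_hat) / (2 * t_star), rel=1e-8)

    def test_zero_discordance_zero_mu(self, const_model, disc3):
        from ibdcoal.verify import _solve_mu

        assert _solve_mu(0.0, disc3.representatives, disc3.probabilities) == 0.0

    def test_calibration_self_consistency(self, two_epoch_model):
        rng = np.random.default_rng(11)
        panel = make_random_panel(rng, 20, 400)
        disc = make_quantile_discretization(two_epoch_model, 15)
        em = calibrate_emission(panel, disc, two_epoch_model, n_freq_bins=3, max_pairs=10**6)
        # E_pi[P(disc | t)] must equal the observed per-bin mean discordance
        bin_idx = em.bin_index(panel.derived_freq)
        n = panel.n_haplotypes
        for b in range(3):
            sel = bin_idx == b
            obs = np.mean([
                (panel.alleles[i, sel] != panel.alleles[j, sel]).mean()
                for i in range(n) for j in range(i + 1, n)
            ])
            model_exp = float(np.sum(
                disc.probabilities * -np.expm1(-2 * em.mu[b] * disc.representatives)
            ))
            assert model_exp == pytest.approx(obs, abs=1e-6)

    def test_mu_recovery_from_simulated_discordance(self, two_epoch_model):
        # simulation oracle: Bernoulli discordance at known mu, 1e5 site-pairs
        from ibdcoal.verify import _solve_mu

        disc = make_quantile_discretization(two_epoch_model, 20)
        mu_true = 3e-5
        rng = np.random.default_rng(5)
        t = two_epoch_model.sample_tmrca(rng, 100_000)
        p_obs = float(np.mean(rng.random(len(t)) < -np.expm1(-2 * mu_true * t)))
        mu_hat = _solve_mu(p_obs, disc.representatives, disc.probabilities)
        assert mu_hat == pytest.approx(mu_true, rel=0.05)

    def test_impossible_discordance_raises(self, disc3):
        from ibdcoal.verify import _solve_mu

        with pytest.raises(ValueError, match="achievable"):
            _solve_mu(1.0, disc3.representatives, disc3.probabilities)


# ---------------------------------------------------------------------------
# Posterior decoding
# ---------------------------------------------------------------------------


def enumerate_posterior(pi, mats, emit):
    """Exhaustive hidden-path enumeration oracle."""
    n, K = emit.shape
    post = np.zeros((n, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=n):
        p = pi[path[0]] * emit[0, path[0]]
        for s in range(1, n):
            p *= mats[s - 1][path[s - 1], path[s]] * emit[s, path[s]]
        total += p
        for s in range(n):
            post[s, path[s]] += p
    return post / total


class TestDecodePosterior:
    def test_flat_likelihood_returns_prior(self, const_model, disc3):
        em = EmissionModel(np.array([0.0, 1.0]), np.array([0.0]))  # P(disc)=0 always
        obs = PairObservation(np.array([True]), np.array([0.5]))
        post = decode_posterior(obs, disc3, const_model, em, np.array([0.0]))
        assert np.allclose(post.posterior[0], disc3.probabilities, atol=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_path_enumeration(self, seed, two_epoch_model):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 5))
        n = int(rng.integers(1, 7))
        bounds = np.concatenate([[0.0], np.sort(rng.uniform(10, 5000, K - 1)), [np.inf]])
        disc = coalescent_prior(two_epoch_model, bounds)
        em = EmissionModel(np.array([0.0, 1.0]), np.array([rng.uniform(1e-5, 3e-4)]))
        gen = np.cumsum(rng.uniform(0.001, 0.3, n))
        obs = PairObservation(rng.random(n) < 0.8, rng.uniform(0.05, 0.95, n))
        tm = TransitionModel(disc, two_epoch_model)
        post = decode_posterior(obs, disc, two_epoch_model, em, gen, tm)

        reps = disc.representatives
        p_disc = em.p_discordant(obs.derived_freq, reps)
        emit = np.where(obs.concordant[:, None], 1 - p_disc, p_disc)
        mats = [tm(float(gen[s] - gen[s - 1])) for s in range(1, n)]
        oracle = enumerate_posterior(disc.probabilities, mats, emit)
        assert np.abs(post.posterior - oracle).max() < 1e-10

    def test_columns_normalized_and_map_ties_recent(self, two_epoch_model):
        disc = make_quantile_discretization(two_epoch_model, 10, pinned=[50.0])
        em = EmissionModel(np.array([0.0, 1.0]), np.array([2e-5]))
        rng = np.random.default_rng(2)
        n = 40
        obs = PairObservation(np.ones(n, dtype=bool), rng.uniform(0.1, 0.9, n))
        post = decode_posterior(obs, disc, two_epoch_model, em, np.linspace(0, 1, n))
        assert np.allclose(post.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(post.map_index == np.argmax(post.posterior, axis=1))

    def test_concordant_run_mass_rises_inside(self, const_model):
        disc = make_quantile_discretization(const_model, 12, pinned=[50.0])
        em = EmissionModel(np.array([0.0, 1.0]), np.array([1e-4]))
        n = 60
        obs = PairObservation(np.ones(n, dtype=bool), np.full(n, 0.5))
        post = decode_posterior(obs, disc, const_model, em, np.linspace(0, 2.0, n))
        mass = post.mass_below(50.0)
        half = n // 2
        # non-decreasing toward the interior (allow tiny numerical wiggle)
        assert np.all(np.diff(mass[:half]) > -1e-9)
        assert np.all(np.diff(mass[half:]) < 1e-9)


# ---------------------------------------------------------------------------
# refine_segment
# ---------------------------------------------------------------------------


def make_posterior(disc, mass_below_pattern):
    """Two-interval posterior with given mass-below-T per site."""
    m = np.asarray(mass_below_pattern, dtype=float)
    post = np.column_stack([m, 1 - m])
    return PosteriorMatrix(post, np.argmax(post, axis=1), disc)


class TestRefineSegment:
    @pytest.fixture
    def setup(self, const_model):
        disc = coalescent_prior(const_model, [0.0, 50.0, np.inf])
        rng = np.random.default_rng(0)
        panel = make_random_panel(rng, 4, 20, length_cm=2.0)
        return disc, panel

    def cand(self, lo, hi):
        return CandidateSegment(0, 1, 0, 0, lo, hi, 0, 1.0)

    def test_never_above_prior_empty(self, setup):
        disc, panel = setup
        prior = disc.probabilities[0]
        post = make_posterior(disc, np.full(10, prior * 0.5))
        assert refine_segment(self.cand(0, 10), post, 50.0, panel) == []

    def test_uniform_high_mass_single_segment(self, setup):
        disc, panel = setup
        post = make_posterior(disc, np.full(10, 0.9))
        segs = refine_segment(self.cand(0, 10), post, 50.0, panel)
        assert len(segs) == 1
        assert segs[0].score == pytest.approx(0.9)
        assert (segs[0].start_site, segs[0].end_site) == (0, 10)

    def test_hand_pattern_two_segments(self, setup):
        disc, panel = setup
        prior = disc.probabilities[0]
        hi, lo = 0.8, prior / 2
        pattern = [hi] * 5 + [lo] * 2 + [hi] * 4
        post = make_posterior(disc, pattern)
        segs = refine_segment(self.cand(0, 11), post, 50.0, panel)
        assert [(s.start_site, s.end_site) for s in segs] == [(0, 5), (7, 11)]

    def test_min_output_filter(self, setup):
        disc, panel = setup
        post = make_posterior(disc, np.full(10, 0.9))
        assert refine_segment(self.cand(0, 10), post, 50.0, panel, min_output_cM=50.0) == []

    def test_t_must_be_boundary(self, setup):
        disc, panel = setup
        post = make_posterior(disc, np.full(10, 0.9))
        with pytest.raises(ValueError, match="boundary"):
            refine_segment(self.cand(0, 10), post, 42.0, panel)


# ---------------------------------------------------------------------------
# detect + file round trip
# ---------------------------------------------------------------------------


class TestDetect:
    def test_planted_identical_pair_high_score(self, const_model):
        rng = np.random.default_rng(42)
        panel = make_random_panel(rng, 20, 400, length_cm=4.0)
        panel.alleles[1] = panel.alleles[0]
        segs = detect(
            panel,
            const_model,
            IdentifyParams(word_size=16, min_length_cM=1.0),
            VerifyParams(time_threshold=50.0),
        )
        mine = [s for s in segs if (s.hap_a, s.hap_b) == (0, 1)]
        assert mine
        best = max(mine, key=lambda s: s.length_cM)
        assert best.score > 0.9
        assert best.length_cM > 2.0

    def test_empty_candidates_empty_output(self, const_model, tmp_path):
        rng = np.random.default_rng(1)
        panel = make_random_panel(rng, 8, 100)
        segs = detect(
            panel, const_model, IdentifyParams(word_size=8, min_length_cM=50.0)
        )
        assert segs == []
        out = tmp_path / "empty.ibd.tsv"
        write_ibd_file(segs, out)
        assert out.read_text().startswith("ind_a\thap_a")

    def test_segments_never_overlap_per_pair(self, const_model):
        rng = np.random.default_rng(9)
        panel = make_random_panel(rng, 16, 300, length_cm=3.0)
        segs = detect(
            panel, const_model,
            IdentifyParams(word_size=8, min_length_cM=0.2),
            VerifyParams(time_threshold=50.0, min_output_cM=0.0),
        )
        by_pair = {}
        for s in segs:
            by_pair.setdefault((s.hap_a, s.hap_b), []).append((s.start_site, s.end_site))
        for ranges in by_pair.values():
            ranges.sort()
            for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
                assert b1 <= a2

    def test_file_round_trip(self, const_model, tmp_path):
        rng = np.random.default_rng(42)
        panel = make_random_panel(rng, 20, 400, length_cm=4.0)
        panel.alleles[1] = panel.alleles[0]
        segs = detect(
            panel, const_model,
            IdentifyParams(word_size=16, min_length_cM=1.0),
        )
        path = tmp_path / "segs.tsv"
        write_ibd_file(segs, path)
        df = read_ibd_file(path)
        assert len(df) == len(segs)
        assert df["score"].between(0, 1).all()
        # fixed formatting contract
        line = path.read_text().splitlines()[1].split("\t")
        assert len(line[8].split(".")[1]) == 4  # score, 4 dp
        assert len(line[9].split(".")[1]) == 2  # age, 2 dp
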