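"""MCMC correctness: full conditionals, chain plumbing, diagnostics."""

import numpy as np
import pytest
from scipy import stats

import koalasc as k
from koalasc import _kernels
from koalasc.sampler import PosteriorDraws


def _toy_state(M, space, rng, **over):
    kw = dict(
        z=(rng.random(M) < 0.5).astype(np.int8),
        sx=rng.uniform(space.xmin, space.xmax, M),
        sy=rng.uniform(space.ymin, space.ymax, M),
        lambda0=1.0, sigma=100.0, psi=0.5,
    )
    kw.update(over)
    return k.LatentState(**kw)


@pytest.fixture(scope="module")
def toy(two_detectors):
    space = k.build_state_space(two_detectors, 500)
    counts = k.NightlyCounts(["a", "b"], np.array([[0], [0]]))
    return two_detectors, space, counts


class TestUpdateZ:
    def test_psi_zero_excludes_everyone(self, toy, rng):
        arr, space, counts = toy
        state = _toy_state(6, space, rng, psi=0.0)
        out = k.update_z(state, counts, arr, seed=1)
        assert out.N == 0

    def test_psi_one_includes_everyone(self, toy, rng):
        arr, space, counts = toy
        state = _toy_state(6, space, rng, psi=1.0)
        out = k.update_z(state, counts, arr, seed=1)
        assert out.N == 6

    def test_matches_analytic_bernoulli_probability(self, rng):
        # one individual at the first detector, zero count on one night:
        # p(z=1) = psi e^-lam0 / (psi e^-lam0 + 1 - psi)
        arr = k.DetectorArray(["a", "b"], np.array([0.0, 1e5]), np.array([0.0, 0.0]))
        space = k.build_state_space(arr, 500)
        counts = k.NightlyCounts(["a", "b"], np.array([[0], [0]]))
        psi, lam0 = 0.6, 1.0
        p_true = psi * np.exp(-lam0) / (psi * np.exp(-lam0) + 1 - psi)
        state = _toy_state(1, space, rng, sx=np.array([0.0]), sy=np.array([0.0]),
                           lambda0=lam0, psi=psi)
        _kernels.set_seed(777)
        n_draws, hits = 50_000, 0
        for _ in range(n_draws):
            hits += k.update_z(state, counts, arr).N
        se = np.sqrt(p_true * (1 - p_true) / n_draws)
        assert abs(hits / n_draws - p_true) < 3 * se

    def test_positive_count_forces_last_contributor_in(self, rng):
        # the only individual near a detector with a positive count cannot
        # leave: removing it would zero the rate against data
        arr = k.DetectorArray(["a", "b"], np.array([0.0, 1e5]), np.array([0.0, 0.0]))
        space = k.build_state_space(arr, 500)
        counts = k.NightlyCounts(["a", "b"], np.array([[3], [0]]))
        state = _toy_state(1, space, rng, z=np.array([1], dtype=np.int8),
                           sx=np.array([0.0]), sy=np.array([0.0]), psi=0.01)
        for s in range(50):
            assert k.update_z(state, counts, arr, seed=s).N == 1


class TestUpdateS:
    def test_positions_stay_inside_state_space(self, toy, rng):
        arr, space, counts = toy
        state = _toy_state(8, space, rng)
        for s in range(30):
            state = k.update_s(state, counts, arr, space, step=5000.0, seed=s)
            assert space.contains(state.sx, state.sy).all()

    def test_flat_likelihood_accepts_in_bounds_proposals(self, two_detectors, rng):
        # all cells masked -> flat likelihood; with a tiny step essentially
        # every proposal is in-bounds, so every move is accepted
        space = k.build_state_space(two_detectors, 500)
        counts = k.NightlyCounts(
            ["a", "b"], np.zeros((2, 2), dtype=int), np.ones((2, 2), dtype=bool)
        )
        state = _toy_state(5, space, rng, z=np.ones(5, dtype=np.int8))
        _kernels.set_seed(99)
        for _ in range(40):
            new = k.update_s(state, counts, two_detectors, space, step=0.1)
            assert (new.sx != state.sx).all()
            state = new

    def test_excluded_individuals_redrawn_uniformly(self, toy):
        arr, space, counts = toy
        state = k.LatentState(
            z=np.zeros(1, dtype=np.int8), sx=np.array([0.0]), sy=np.array([0.0]),
            lambda0=1.0, sigma=100.0, psi=0.5,
        )
        _kernels.set_seed(4242)
        xs = []
        for _ in range(2000):
            state = k.update_s(state, counts, arr, space, step=50.0)
            xs.append(state.sx[0])
        u = (np.array(xs) - space.xmin) / space.width
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_nonpositive_step_rejected(self, toy, rng):
        arr, space, counts = toy
        with pytest.raises(ValueError):
            k.update_s(_toy_state(2, space, rng), counts, arr, space, step=0.0)


class TestUpdateScalars:
    def test_psi_conjugate_beta_moments(self):
        # a = b = 1, sum z = 3, M = 5 -> Beta(4, 3): mean 4/7, var 12/392
        z = np.array([1, 1, 1, 0, 0], dtype=np.int8)
        _kernels.set_seed(2718)
        draws = np.array([_kernels.update_psi(z, 1.0, 1.0) for _ in range(50_000)])
        mean, var = 4 / 7, 12 / (49 * 8)
        assert abs(draws.mean() - mean) < 3 * np.sqrt(var / 50_000)
        m2 = var + mean**2
        se_m2 = np.std(draws**2, ddof=1) / np.sqrt(50_000)
        assert abs((draws**2).mean() - m2) < 3 * se_m2

    def test_lambda0_stays_positive_and_within_prior(self, toy, rng):
        arr, space, counts = toy
        priors = k.make_priors("strong", homerange_mean=40.0)
        state = _toy_state(4, space, rng, lambda0=0.3)
        _kernels.set_seed(31)
        for _ in range(200):
            state = k.update_scalars(state, counts, arr, priors, step_lambda0=2.0)
            assert 0.0 < state.lambda0 < priors.lambda0_hi
            assert state.sigma > 0
            assert 0.0 <= state.psi <= 1.0

    def test_sigma_chain_recovers_gamma_prior_on_flat_likelihood(self, two_detectors, rng):
        # all counts masked: the sigma marginal must reproduce its prior
        space = k.build_state_space(two_detectors, 500)
        counts = k.NightlyCounts(
            ["a", "b"], np.zeros((2, 3), dtype=int), np.ones((2, 3), dtype=bool)
        )
        priors = k.make_priors("strong", homerange_mean=40.0, cv=0.2)
        state = _toy_state(3, space, rng, sigma=priors.sigma_mean)
        _kernels.set_seed(1618)
        sigmas = np.empty(30_000)
        for i in range(30_000):
            state = k.update_scalars(state, counts, two_detectors, priors,
                                     step_sigma=0.5)
            sigmas[i] = state.sigma
        # batch-means SE to absorb chain autocorrelation
        bm = sigmas.reshape(60, -1).mean(axis=1)
        se = bm.std(ddof=1) / np.sqrt(60)
        assert abs(sigmas.mean() - priors.sigma_mean) < 3 * se


class TestRunChains:
    @pytest.fixture(scope="class")
    def small_fit(self):
        arr = k.make_grid_array(3, 3, 300)
        space = k.build_state_space(arr, 400)
        pop = k.simulate_population(0.08, space, seed=5)
        counts = k.simulate_counts_model_exact(pop, arr, 0.5, 120, 10, seed=6)
        config = k.MCMCConfig.desk(seed=7, n_iter=800, n_burnin=200, n_adapt=200,
                                   M=40)
        priors = k.make_priors("strong", homerange_mean=40.0)
        return arr, space, counts, priors, config

    def test_bit_identical_reruns(self, small_fit):
        arr, space, counts, priors, config = small_fit
        a = k.run_chains(counts, arr, space, priors, config)
        b = k.run_chains(counts, arr, space, priors, config)
        for p in a.params:
            np.testing.assert_array_equal(a.params[p], b.params[p])
        np.testing.assert_array_equal(a.snapshots.x, b.snapshots.x)

    def test_retention_and_bookkeeping(self, small_fit):
        arr, space, counts, priors, config = small_fit
        draws = k.run_chains(counts, arr, space, priors, config)
        assert draws.n_retained == (config.n_iter - config.n_burnin) // config.thin
        assert draws.params["N"].max() <= config.M
        np.testing.assert_allclose(
            draws.params["D"], draws.params["N"] / space.area_ha
        )
        # snapshots every 10th retained iteration, all chains
        assert draws.snapshots.n_snapshots == config.n_chains * 60

    def test_thinning(self, small_fit):
        arr, space, counts, priors, _ = small_fit
        config = k.MCMCConfig.desk(seed=7, n_iter=800, n_burnin=200, n_adapt=200,
                                   M=40, thin=3)
        draws = k.run_chains(counts, arr, space, priors, config)
        assert draws.n_retained == 200

    def test_all_masked_counts_rejected(self, small_fit):
        arr, space, counts, priors, config = small_fit
        masked = k.NightlyCounts(
            list(counts.detector_ids), counts.counts,
            np.ones_like(counts.counts, dtype=bool),
        )
        with pytest.raises(ValueError, match="masked"):
            k.run_chains(masked, arr, space, priors, config)

    def test_augmentation_ceiling_warns(self):
        # M far below the true abundance: posterior N piles at M
        arr = k.make_grid_array(3, 3, 300)
        space = k.build_state_space(arr, 300)
        pop = k.simulate_population(0.15, space, seed=8)
        assert pop.size > 10
        counts = k.simulate_counts_model_exact(pop, arr, 2.0, 150, 10, seed=9)
        config = k.MCMCConfig.desk(seed=10, n_iter=600, n_burnin=200, n_adapt=200,
                                   M=3)
        priors = k.make_priors("strong", homerange_mean=40.0)
        with pytest.warns(RuntimeWarning, match="augmentation ceiling"):
            k.run_chains(counts, arr, space, priors, config)

    def test_adapted_acceptance_in_target_band(self, small_fit):
        arr, space, counts, priors, config = small_fit
        draws = k.run_chains(counts, arr, space, priors, config)
        # post-adaptation acceptance for the tuned moves within a loose band
        assert ((draws.accept_rates > 0.1) & (draws.accept_rates < 0.6)).all()


class TestMCMCConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            k.MCMCConfig(n_iter=100, n_burnin=100, n_adapt=10, seeds=(1, 2, 3))
        with pytest.raises(ValueError):
            k.MCMCConfig(seeds=(1, 1, 2))
        with pytest.raises(ValueError):
            k.MCMCConfig(n_chains=2, seeds=(1, 2, 3))

    def test_seed_sequence_distinct_and_31bit(self):
        seeds = k.seed_sequence(42, 8)
        assert len(set(seeds.tolist())) == 8
        assert (seeds > 0).all() and (seeds < 2**31).all()


class TestGelmanRubin:
    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(size=(3, 4000))
        r = k.gelman_rubin({"x": chains})["x"]
        assert r == pytest.approx(1.0, abs=0.02)

    def test_identical_chains_closed_form(self):
        c = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        r = k.gelman_rubin({"x": c})["x"]
        assert r == pytest.approx(np.sqrt(3 / 4), abs=1e-12)

    def test_zero_within_chain_variance_undefined(self):
        c = np.array([[0.0, 0, 0, 0], [10.0, 10, 10, 10]])
        assert np.isnan(k.gelman_rubin({"x": c})["x"])

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            k.gelman_rubin({"x": np.ones((1, 10))})

    def test_diverged_chains_flagged(self, rng):
        c = np.stack([rng.normal(0, 1, 2000), rng.normal(8, 1, 2000)])
        assert k.gelman_rubin({"x": c})["x"] > 1.1


class TestSummarize:
    def _draws(self, params, area=100.0):
        return PosteriorDraws(params=params, snapshots=None, area_ha=area, M=50)

    def test_constant_draws_degenerate_interval(self):
        s = k.summarize(self._draws({"sigma": np.full((2, 10), 3.5)}))
        row = s.loc["sigma"]
        assert (row["mean"], row["q25"], row["q75"]) == (3.5, 3.5, 3.5)

    def test_percentile_rule_on_1_to_100(self):
        draws = np.arange(1.0, 101.0).reshape(1, -1).repeat(2, axis=0)
        row = k.summarize(self._draws({"N": draws})).loc["N"]
        assert row["q25"] == pytest.approx(25.75)
        assert row["q75"] == pytest.approx(75.25)

    def test_density_is_scaled_abundance(self, rng):
        n = rng.poisson(40, size=(3, 200)).astype(float)
        d = self._draws({"N": n, "D": n / 100.0})
        s = k.summarize(d)
        for col in ("mean", "q25", "q75"):
            assert s.loc["D", col] == pytest.approx(s.loc["N", col] / 100.0)


class TestJointDistribution:
    def test_successive_conditional_matches_forward_sampling(self, two_detectors):
        """Geweke-style check: alternating data- and parameter-updates leaves
        the prior-predictive joint distribution invariant."""
        arr = two_detectors
        space = k.StateSpace(-200, 300, -200, 200)
        M, K = 8, 2
        shape, rate = 11.11, 0.1111  # sigma prior: mean ~100 m, cv ~0.3
        rng = np.random.default_rng(7)

        def draw_prior():
            psi = rng.beta(2, 2)
            return (
                (rng.random(M) < psi).astype(np.int8),
                rng.uniform(space.xmin, space.xmax, M),
                rng.uniform(space.ymin, space.ymax, M),
                rng.uniform(0, 3), rng.gamma(shape, 1 / rate), psi,
            )

        def sim_counts(z, sx, sy, lam0, sig):
            r = np.exp(-((sx[:, None] - arr.x) ** 2 + (sy[:, None] - arr.y) ** 2)
                       / (2 * sig**2))
            lam = lam0 * (z[:, None] * r).sum(axis=0)
            return rng.poisson(lam[:, None], size=(2, K))

        n_fwd = 30_000
        fwd = np.array([(d[0].sum(), d[4]) for d in (draw_prior() for _ in range(n_fwd))])

        _kernels.set_seed(12345)
        z, sx, sy, lam0, sig, psi = draw_prior()
        R = np.empty((M, 2)); T = np.empty(2)
        r_buf = np.empty_like(R); t_buf = np.empty_like(T)
        k_j = np.full(2, float(K))
        n_cyc = 20_000
        sc = np.empty((n_cyc, 2))
        for c in range(n_cyc):
            n_j = sim_counts(z, sx, sy, lam0, sig).sum(axis=1).astype(float)
            _kernels.compute_R(sx, sy, arr.x, arr.y, sig, R)
            _kernels.compute_T(z, R, T)
            _kernels.update_z(z, R, T, lam0, psi, n_j, k_j)
            psi = _kernels.update_psi(z, 2.0, 2.0)
            _kernels.update_s(z, sx, sy, R, T, lam0, n_j, k_j, arr.x, arr.y,
                              sig, space.xmin, space.xmax, space.ymin,
                              space.ymax, 80.0)
            lam0, _ = _kernels.update_lambda0(lam0, T, n_j, k_j, 0.0, 3.0, 0.5)
            sig, _ = _kernels.update_sigma(sig, z, sx, sy, R, T, lam0, n_j, k_j,
                                           arr.x, arr.y, _kernels.SIGMA_GAMMA,
                                           shape, rate, 0.3, r_buf, t_buf)
            sc[c] = z.sum(), sig

        def batch_se(x, nb=40):
            b = x[: len(x) // nb * nb].reshape(nb, -1).mean(axis=1)
            return b.std(ddof=1) / np.sqrt(nb)

        for col, name in ((0, "N"), (1, "sigma")):
            se = np.sqrt(fwd[:, col].var(ddof=1) / n_fwd + batch_se(sc[:, col]) ** 2)
            zscore = (sc[:, col].mean() - fwd[:, col].mean()) / se
            assert abs(zscore) < 3.5, f"{name} moment mismatch: z = {zscore:.2f}"
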