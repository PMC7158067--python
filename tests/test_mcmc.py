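import numpy as np
import pytest
from scipy import stats

import stsurv
from stsurv import CountPanel, McmcConfig
from stsurv.mcmc import (
    PosteriorSamples,
    gelman_rubin,
    icar_log_density,
    normal_log_density,
    poisson_loglik,
    run_chain,
    rw1_log_density,
)


class TestRw1LogDensity:
    def test_constant_sequence_has_zero_penalty(self):
        # only the normalizing terms remain
        g = np.full(5, 2.2)
        assert rw1_log_density(g, tau=1.0) == pytest.approx(
            0.5 * 4 * (np.log(1.0) - np.log(2 * np.pi))
        )

    def test_hand_summed_penalty(self):
        lp = rw1_log_density([0.0, 1.0, 0.0], tau=1.0)
        const = 0.5 * 2 * (-np.log(2 * np.pi))
        assert lp == pytest.approx(const - 1.0)

    def test_agrees_with_normal_increment_oracle(self):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(10)
        tau = 2.7
        oracle = stats.norm.logpdf(np.diff(g), scale=1 / np.sqrt(tau)).sum()
        assert rw1_log_density(g, tau) == pytest.approx(oracle)

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            rw1_log_density([0.0, 1.0], tau=0.0)


class TestPoissonLoglik:
    def test_all_zero_counts_closed_form(self):
        E = np.array([[1.0, 2.0], [3.0, 4.0]])
        panel = CountPanel(y=np.zeros((2, 2), dtype=int), E=E)
        assert poisson_loglik(panel, np.zeros((2, 2))) == pytest.approx(-E.sum())

    def test_single_cell_hand_value(self):
        panel = CountPanel(y=np.array([[2]]), E=np.array([[1.0]]))
        assert poisson_loglik(panel, np.zeros((1, 1))) == pytest.approx(-1 - np.log(2))

    def test_matches_scipy_poisson_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.poisson(8, (4, 6))
            E = rng.uniform(2, 10, (4, 6))
            log_rr = rng.standard_normal((4, 6)) * 0.3
            panel = CountPanel(y=y, E=E)
            oracle = stats.poisson.logpmf(y, E * np.exp(log_rr)).sum()
            assert poisson_loglik(panel, log_rr) == pytest.approx(oracle)

    def test_shape_mismatch_rejected(self):
        panel = CountPanel(y=np.zeros((2, 2), dtype=int), E=np.ones((2, 2)))
        with pytest.raises(ValueError):
            poisson_loglik(panel, np.zeros((3, 2)))


class TestIcarLogDensity:
    def test_matches_quadratic_form(self, lattice33):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(9)
        tau = 1.7
        q = stsurv.icar_quadratic_form(v, lattice33)
        rank = 8  # 9 nodes, 1 component
        expected = 0.5 * rank * (np.log(tau) - np.log(2 * np.pi)) - 0.5 * tau * q
        assert icar_log_density(v, tau, lattice33) == pytest.approx(expected)


class TestGelmanRubin:
    def _ps(self, arr):
        return PosteriorSamples(draws={"x": np.asarray(arr, dtype=float)},
                                acceptance={})

    def test_identical_chains_give_exactly_one(self):
        chain = np.random.default_rng(0).standard_normal(50)
        r = gelman_rubin(self._ps(np.stack([chain, chain])))
        assert r["x"] == pytest.approx(1.0)

    def test_separated_chains_blow_up(self):
        r = gelman_rubin(self._ps([np.zeros(50) + np.random.default_rng(0).normal(0, .01, 50),
                                   np.ones(50) * 10 + np.random.default_rng(1).normal(0, .01, 50)]))
        assert r["x"] > 10

    def test_two_chain_hand_computation(self):
        # chains (1,3) and (2,6): W = mean(var ddof=1) = mean(2, 8) = 5;
        # chain means 2, 4 -> B/n = var([2,4], ddof=1) = 2;
        # R = sqrt(1 + (B/n)/W) = sqrt(1 + 2/5)
        r = gelman_rubin(self._ps([[1.0, 3.0], [2.0, 6.0]]))
        assert r["x"] == pytest.approx(np.sqrt(1.4))

    def test_single_chain_unavailable(self):
        with pytest.raises(ValueError):
            gelman_rubin(self._ps([[1.0, 2.0]]))

    def test_agrees_with_arviz_on_well_mixed_chains(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = rng.standard_normal((4, 500))
        ours = gelman_rubin(self._ps(chains))["x"]
        theirs = float(
            np.asarray(arviz.rhat(arviz.convert_to_dataset(chains[:, :, None]))["x"]).item()
        )
        assert abs(ours - theirs) < 0.05


class TestRunChain:
    def test_thinning_halves_draw_count(self, small_panel, planar30):
        base = dict(n_iterations=400, burn_in=200, n_chains=1, seed=0)
        s1 = run_chain("dm", small_panel, planar30, McmcConfig(thin=2, **base))
        s2 = run_chain("dm", small_panel, planar30, McmcConfig(thin=4, **base))
        assert s1.n_draws == 2 * s2.n_draws

    def test_seed_determinism(self, small_panel, planar30):
        cfg = McmcConfig(n_iterations=300, burn_in=100, thin=2, n_chains=2, seed=4)
        a = run_chain("dm", small_panel, planar30, cfg)
        b = run_chain("dm", small_panel, planar30, cfg)
        c = run_chain(
            "dm", small_panel, planar30,
            McmcConfig(n_iterations=300, burn_in=100, thin=2, n_chains=2, seed=5),
        )
        np.testing.assert_array_equal(a.get("psi"), b.get("psi"))
        assert not np.array_equal(a.get("psi"), c.get("psi"))

    def test_unknown_model_rejected(self, small_panel, planar30):
        with pytest.raises(KeyError):
            run_chain("nope", small_panel, planar30, McmcConfig(seed=0))

    def test_posterior_samples_invariants(self, small_panel, planar30, quick_cfg):
        s = run_chain("stmix", small_panel, planar30, quick_cfg)
        s.validate()
        assert np.isin(s.get("c"), (0, 1)).all()
        assert (s.get("p") >= 0).all() and (s.get("p") <= 1).all()
        for k in s.draws:
            if k.startswith("tau") or k.startswith("sigma"):
                assert (s.get(k) > 0).all()

    def test_log_posterior_decomposes_into_parts(self, small_panel, planar30):
        # sampler's joint log-posterior equals likelihood + prior terms
        # computed independently
        from stsurv.models import DmSampler, _gamma_logpdf

        sampler = DmSampler(small_panel, planar30)
        rng = np.random.default_rng(0)
        state = sampler.init_state(rng)
        for _ in range(10):
            sampler.sweep(state, rng, adapting=False)
        log_rr = (state["alpha"] + state["theta"][:, None] + state["phi"][:, None]
                  + state["gamma"][None, :] + state["psi"])
        manual = (
            poisson_loglik(small_panel, log_rr)
            + icar_log_density(state["theta"], state["tau_theta"], planar30)
            + normal_log_density(state["phi"], state["tau_phi"])
            + rw1_log_density(state["gamma"], state["tau_gamma"])
            + normal_log_density(state["psi"], state["tau_psi"])
            + sum(_gamma_logpdf(state[k], 1.0, 0.01)
                  for k in ("tau_theta", "tau_phi", "tau_gamma", "tau_psi"))
        )
        assert sampler.log_posterior(state) == pytest.approx(manual)

    def test_to_dataframe_row_count(self, small_panel, planar30, quick_cfg):
        s = run_chain("dm", small_panel, planar30, quick_cfg)
        df = s.to_dataframe()
        assert len(df) == s.n_chains * s.n_draws
        assert "alpha" in df.columns and "tau_psi" in df.columns


def test_conjugate_precision_gibbs_matches_mh_estimate(planar30):
    """Two-sampler agreement: the Gibbs full conditional for an iid-normal
    precision equals what a generic MH sampler targets."""
    rng = np.random.default_rng(0)
    x = rng.standard_normal(40) * 0.5
    a0, b0 = 1.0, 0.01
    shape, rate = a0 + 0.5 * len(x), b0 + 0.5 * float(np.sum(x * x))
    gibbs = rng.gamma(shape, 1.0 / rate, size=20000)
    # independent MH on tau with the same target density
    tau, draws, rng2 = 1.0, [], np.random.default_rng(1)
    def logp(t):
        return (a0 - 1) * np.log(t) - b0 * t + 0.5 * len(x) * np.log(t) - 0.5 * t * np.sum(x * x)
    for _ in range(20000):
        prop = tau * np.exp(0.3 * rng2.standard_normal())
        if np.log(rng2.uniform()) < logp(prop) - logp(tau) + np.log(prop) - np.log(tau):
            tau = prop
        draws.append(tau)
    draws = np.array(draws[2000:])
    assert draws.mean() == pytest.approx(gibbs.mean(), rel=0.05)
    assert np.percentile(draws, 90) == pytest.approx(np.percentile(gibbs, 90), rel=0.08)
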