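import numpy as np
import pytest

import stsurv
from stsurv import CountPanel, ScenarioConfig
from stsurv.scenarios import (
    generate_baseline,
    inject_signals,
    make_scenario,
    make_scenario1,
    sample_counts,
)


def _cfg30(**kw):
    base = dict(n_areas=30, n_times=8, n_unusual=4, up_times=frozenset({2}),
                down_times=frozenset({5}))
    base.update(kw)
    return ScenarioConfig(**base)


class TestCountPanel:
    def test_rejects_nonpositive_expected(self):
        with pytest.raises(ValueError):
            CountPanel(y=np.zeros((2, 2), dtype=int), E=np.zeros((2, 2)))

    def test_rejects_negative_or_float_counts(self):
        with pytest.raises(ValueError):
            CountPanel(y=np.full((2, 2), -1), E=np.ones((2, 2)))
        with pytest.raises(ValueError):
            CountPanel(y=np.ones((2, 2)), E=np.ones((2, 2)))  # float y

    def test_dataframe_round_trip(self):
        rng = np.random.default_rng(0)
        panel = CountPanel(y=rng.poisson(10, (4, 3)), E=rng.uniform(5, 9, (4, 3)))
        back = CountPanel.from_dataframe(panel.to_dataframe())
        np.testing.assert_array_equal(back.y, panel.y)
        np.testing.assert_allclose(back.E, panel.E)

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        panel = CountPanel(y=rng.poisson(10, (3, 5)), E=rng.uniform(5, 9, (3, 5)))
        panel.to_csv(tmp_path / "p.csv")
        back = CountPanel.from_csv(tmp_path / "p.csv")
        np.testing.assert_array_equal(back.y, panel.y)
        np.testing.assert_allclose(back.E, panel.E)


class TestScenarioConfig:
    def test_rejects_overlapping_schedules(self):
        with pytest.raises(ValueError):
            ScenarioConfig(up_times=frozenset({3}), down_times=frozenset({3, 6}))

    def test_rejects_out_of_range_times(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_times=10, down_times=frozenset({12}))

    def test_default_schedule_matches_benchmark_design(self):
        cfg = ScenarioConfig()
        sched = cfg.signal_schedule
        assert {t for t, d in sched.items() if d > 0} == {3, 10}
        assert {t for t, d in sched.items() if d < 0} == {6, 12, 15}
        assert all(abs(d) == pytest.approx(np.log(2)) for d in sched.values())


class TestGenerateBaseline:
    def test_degenerate_scales_give_constant_surface(self, planar30):
        cfg = _cfg30(sd_spatial=0, sd_temporal=0, sd_unstructured=0,
                     sd_interaction=0, alpha0=0.4)
        surf = generate_baseline(cfg, planar30, seed=0)
        np.testing.assert_allclose(surf.log_rr, 0.4)

    def test_deterministic_given_seed(self, planar30):
        cfg = _cfg30()
        a = generate_baseline(cfg, planar30, seed=3)
        b = generate_baseline(cfg, planar30, seed=3)
        c = generate_baseline(cfg, planar30, seed=4)
        np.testing.assert_array_equal(a.log_rr, b.log_rr)
        assert not np.array_equal(a.log_rr, c.log_rr)

    def test_gauge_constraints(self, planar30):
        surf = generate_baseline(_cfg30(), planar30, seed=1)
        assert surf.theta.sum() == pytest.approx(0.0, abs=1e-10)
        assert surf.gamma.sum() == pytest.approx(0.0, abs=1e-10)

    def test_log_rr_is_componentwise_sum(self, planar30):
        surf = generate_baseline(_cfg30(), planar30, seed=2)
        manual = (surf.alpha + surf.theta[:, None] + surf.phi[:, None]
                  + surf.gamma[None, :] + surf.psi)
        np.testing.assert_allclose(surf.log_rr, manual)

    def test_temporal_increment_variance_monte_carlo(self, planar30):
        # increments of the trend should have the configured variance
        cfg = _cfg30(sd_temporal=0.15)
        incs = []
        for seed in range(400):
            g = generate_baseline(cfg, planar30, seed=seed).gamma
            incs.append(np.diff(g))
        sd = np.std(np.concatenate(incs))
        assert sd == pytest.approx(0.15, rel=0.05)

    def test_dimension_mismatch_rejected(self, planar30):
        with pytest.raises(ValueError):
            generate_baseline(ScenarioConfig(n_areas=7, n_times=8), planar30, seed=0)


class TestInjectSignals:
    def test_risk_doubles_at_up_time_and_halves_at_down_time(self, planar30):
        cfg = _cfg30()
        base = generate_baseline(cfg, planar30, seed=0)
        shifted, truth = inject_signals(base, cfg, seed=1)
        ratio = np.exp(shifted.log_rr - base.log_rr)
        for u in truth.unusual_areas:
            assert ratio[u, 1] == pytest.approx(2.0)  # time point 2 (1-based)
            assert ratio[u, 4] == pytest.approx(0.5)  # time point 5
        assert len(truth.unusual_areas) == cfg.n_unusual

    def test_unflagged_areas_untouched(self, planar30):
        cfg = _cfg30()
        base = generate_baseline(cfg, planar30, seed=0)
        shifted, truth = inject_signals(base, cfg, seed=1)
        common = sorted(set(range(30)) - truth.unusual_areas)
        np.testing.assert_array_equal(truth.per_unit_offset[common], 0.0)
        np.testing.assert_array_equal(shifted.log_rr[common], base.log_rr[common])

    def test_too_many_unusual_rejected(self, planar30):
        cfg = _cfg30()
        base = generate_baseline(cfg, planar30, seed=0)
        with pytest.raises(ValueError):
            inject_signals(base, ScenarioConfig(n_areas=30, n_times=8, n_unusual=31),
                           seed=0)


class TestSampleCounts:
    def test_poisson_moments(self, planar30):
        cfg = _cfg30(sd_spatial=0, sd_temporal=0, sd_unstructured=0, sd_interaction=0)
        surf = generate_baseline(cfg, planar30, seed=0)  # log_rr = 0
        E = np.full((30, 8), 10.0)
        draws = np.array(
            [sample_counts(surf, E, seed=s).y for s in range(50)], dtype=float
        )
        mean = draws.mean()
        se = np.sqrt(10.0 / draws.size)
        assert abs(mean - 10.0) < 3 * se
        # Poisson: variance approximately equals mean at each fixed cell
        assert np.mean(draws.var(axis=0)) == pytest.approx(10.0, rel=0.1)

    def test_vanishing_expected_counts_give_zero(self, planar30):
        cfg = _cfg30()
        surf = generate_baseline(cfg, planar30, seed=0)
        panel = sample_counts(surf, np.full((30, 8), 1e-8), seed=0)
        assert panel.y.sum() == 0

    def test_rejects_nonpositive_expected(self, planar30):
        surf = generate_baseline(_cfg30(), planar30, seed=0)
        with pytest.raises(ValueError):
            sample_counts(surf, np.zeros((30, 8)), seed=0)


class TestMakeScenario1:
    def test_shapes_and_truth(self):
        panel, truth, graph = make_scenario1(seed=0)
        assert panel.y.shape == (211, 15)
        assert graph.n_areas == 211
        assert len(truth.unusual_areas) == 15
        nonzero_times = {t for t in range(15) if np.any(truth.per_unit_offset[:, t])}
        assert nonzero_times == {2, 5, 9, 11, 14}  # 1-based {3,6,10,12,15}

    def test_distinct_seeds_distinct_data(self):
        panels = [make_scenario1(seed=s)[0].y for s in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.array_equal(panels[i], panels[j])

    def test_reproducible(self):
        a = make_scenario1(seed=3)
        b = make_scenario1(seed=3)
        np.testing.assert_array_equal(a[0].y, b[0].y)
        assert a[1].unusual_areas == b[1].unusual_areas

    def test_expected_counts_constant_over_time_in_range(self):
        panel, _, _ = make_scenario1(seed=2)
        assert np.all(panel.E == panel.E[:, [0]])
        assert panel.E.min() >= 20.0 and panel.E.max() <= 60.0


def test_signal_verification_at_generator_level(planar30):
    # mean count in flagged areas at an up time, relative to its own baseline
    # expectation, converges to the injected risk ratio 2
    cfg = _cfg30(expected_range=(50.0, 50.0))
    ratios = []
    for seed in range(150):
        base = generate_baseline(cfg, planar30, seed=seed)
        shifted, truth = inject_signals(base, cfg, seed=seed + 1000)
        E = np.full((30, 8), 50.0)
        y = sample_counts(shifted, E, seed=seed + 2000).y
        u = sorted(truth.unusual_areas)
        baseline_mean = E[u, 1] * np.exp(base.log_rr[u, 1])
        ratios.append(y[u, 1].mean() / baseline_mean.mean())
    assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)
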