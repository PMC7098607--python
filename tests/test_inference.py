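import numpy as np
import pytest

from txnsim import (
    SearchDomain,
    SimSettings,
    StageConfig,
    region_penalty,
    run_genetic_stage,
    summarize_population,
)
from txnsim.inference import TargetSummary, stage_objective


class TestSearchDomain:
    def test_free_names_follow_canonical_order(self):
        d = SearchDomain(fixed={"k_ini": 95.0, "v_el": 41.5})
        assert d.free_names == ("k_on", "k_off", "k_deg")

    def test_log_bounds_shape(self):
        d = SearchDomain()
        assert d.log_bounds().shape == (5, 2)

    def test_to_params_merges_fixed_and_free(self):
        d = SearchDomain(fixed={"k_ini": 95.0, "k_on": 1.0, "k_off": 10.0,
                                "v_el": 41.5})
        p = d.to_params(np.array([-0.301]), L=5300.0, N=15)
        assert p.k_deg == pytest.approx(0.5, rel=1e-3)
        assert p.k_ini == 95.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchDomain(bounds={"k_on": (10.0, 1.0)})
        with pytest.raises(ValueError):
            SearchDomain(fixed={"protein": 1.0})


class TestRegionPenalty:
    def test_zero_at_center_and_on_boundary(self):
        center = np.zeros(3)
        assert region_penalty(np.zeros(3), center, 0.5) == 0.0
        assert region_penalty(np.array([0.5, -0.5, 0.0]), center, 0.5) == 0.0

    def test_quadratic_one_unit_beyond_radius(self):
        # one log10 unit beyond the radius -> unit penalty (weight applied
        # by the stage runner)
        assert region_penalty(np.array([1.5]), np.zeros(1), 0.5) == pytest.approx(1.0)

    def test_per_parameter_radius(self):
        r = np.array([0.5, 2.0])
        x = np.array([1.5, 1.5])
        assert region_penalty(x, np.zeros(2), r) == pytest.approx(1.0)


class TestSummarizePopulation:
    def test_identical_vectors_have_zero_sigma(self):
        pop = np.tile([1.0, -2.0], (8, 1))
        est = summarize_population(pop, ("k_on", "k_deg"))
        assert np.all(est.sigma_log10 == 0.0)

    def test_two_point_population(self):
        est = summarize_population(np.array([[1.0], [3.0]]), ("k_on",))
        assert est.mean_log10[0] == pytest.approx(2.0)
        assert est.sigma_log10[0] == pytest.approx(1.0)
        assert est.point["k_on"] == pytest.approx(100.0)

    def test_permutation_invariance(self, rng):
        pop = rng.normal(size=(20, 3))
        a = summarize_population(pop, ("a", "b", "c"))
        b = summarize_population(pop[::-1], ("a", "b", "c"))
        np.testing.assert_allclose(a.mean_log10, b.mean_log10)
        np.testing.assert_allclose(a.sigma_log10, b.sigma_log10)

    def test_one_sigma_interval_and_containment(self):
        # population {10^0, 10^1}: mean 0.5, sigma 0.5 in log10
        est = summarize_population(np.array([[0.0], [1.0]]), ("k_on",))
        lo, hi = est.one_sigma_interval("k_on")
        assert (lo, hi) == (pytest.approx(1.0), pytest.approx(10.0))
        assert est.contains({"k_on": 5.0}) == {"k_on": True}
        assert est.contains({"k_on": 1000.0}) == {"k_on": False}


class TestStageConfig:
    def test_full_scale_filter_keeps_one_tenth(self):
        cfg = StageConfig(stage_id=1, population=5000, generations=0,
                          n_cells=200)
        assert cfg.elite_count == 500

    def test_metric_lookup(self):
        assert StageConfig(stage_id=4, population=10, generations=1,
                           n_cells=10).metric == "nascent_mean_mse"


class TestGeneticStage:
    @staticmethod
    def _convex_objective(target):
        def objective(x, gen):
            return float(np.sum((x - target) ** 2))
        return objective

    def test_converges_on_synthetic_convex_function(self):
        bounds = np.array([[-2.0, 2.0]] * 3)
        target = np.array([0.7, -1.2, 0.3])
        cfg = StageConfig(stage_id=2, population=60, generations=20,
                          n_cells=1, elite_fraction=0.1)
        rng = np.random.default_rng(0)
        init = rng.uniform(bounds[:, 0], bounds[:, 1], size=(60, 3))
        result = run_genetic_stage(self._convex_objective(target), bounds, cfg,
                                   init, rng)
        assert np.all(np.abs(result.center - target) < 0.1)

    def test_fixed_seed_reproduces_elite(self):
        bounds = np.array([[-1.0, 1.0]] * 2)
        cfg = StageConfig(stage_id=2, population=30, generations=5, n_cells=1)
        elites = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            init = rng.uniform(-1, 1, size=(30, 2))
            res = run_genetic_stage(self._convex_objective(np.zeros(2)), bounds,
                                    cfg, init, rng)
            elites.append(res.elite)
        np.testing.assert_array_equal(elites[0], elites[1])

    def test_all_infinite_population_is_an_error(self):
        bounds = np.array([[-1.0, 1.0]])
        cfg = StageConfig(stage_id=2, population=10, generations=1, n_cells=1)
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError):
            run_genetic_stage(lambda x, gen: float("inf"), bounds, cfg,
                              rng.uniform(-1, 1, (10, 1)), rng)

    def test_penalty_weight_scaled_to_initial_median(self):
        bounds = np.array([[-1.0, 1.0]])
        cfg = StageConfig(stage_id=2, population=20, generations=2, n_cells=1)
        rng = np.random.default_rng(1)
        init = rng.uniform(-1, 1, (20, 1))
        res = run_genetic_stage(lambda x, gen: 4.0, bounds, cfg, init, rng,
                                penalty=lambda x: 0.0)
        assert res.penalty_weight == pytest.approx(4.0)


class TestStageObjective:
    def test_true_parameters_beat_perturbed_degradation(
        self, ground_truth, validation_target
    ):
        """Two-point comparison: the generating parameter set scores lower on
        the total-mean metric than the same set with k_deg scaled 10x."""
        summary = TargetSummary.from_target(validation_target)
        settings = SimSettings(L=ground_truth.L, N=ground_truth.N)
        cfg = StageConfig(stage_id=2, population=1, generations=0, n_cells=200)
        good = stage_objective(cfg, ground_truth, summary, settings, sim_seed=3)
        bad = stage_objective(cfg, ground_truth.with_rates(k_deg=5.0), summary,
                              settings, sim_seed=3)
        assert good < bad

    def test_noise_floor_shrinks_with_trial_ensemble_size(
        self, ground_truth, validation_target
    ):
        """Distribution-distance objectives evaluated at the generating
        parameters measure pure sampling noise; more simulated cells per
        trial must lower that floor."""
        summary = TargetSummary.from_target(validation_target)
        settings = SimSettings(L=ground_truth.L, N=ground_truth.N)
        floors = {}
        for n_cells in (200, 2000):
            cfg = StageConfig(stage_id=5, population=1, generations=0,
                              n_cells=n_cells)
            floors[n_cells] = np.mean([
                stage_objective(cfg, ground_truth, summary, settings, sim_seed=s)
                for s in (1, 2, 3)
            ])
        assert floors[2000] < floors[200]

    def test_runaway_trial_is_culled_not_fatal(self, ground_truth,
                                               validation_target):
        summary = TargetSummary.from_target(validation_target)
        settings = SimSettings(L=ground_truth.L, N=ground_truth.N,
                               max_events=200)
        cfg = StageConfig(stage_id=2, population=1, generations=0, n_cells=20)
        assert stage_objective(cfg, ground_truth, summary, settings,
                               sim_seed=3) == np.inf
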