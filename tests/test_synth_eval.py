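import dataclasses

import numpy as np
import pytest

from readmix.greedy_build import Solution
from readmix.pipeline import EnsembleReport
from readmix.simplex_fit import chebyshev_weights
from readmix.synth_eval import (
    EvalMetrics,
    MixtureScenario,
    draw_scenarios,
    evaluate_prediction,
    generate_panel,
    haversine_km,
    scenario_weights,
    simulate_mixture,
    summarize_metrics,
    zombie_genotypes,
)


def make_report(panel, names, weights):
    """Minimal report fixture with the given stable populations."""
    idx = [panel.index_of(n) for n in names]
    w = np.asarray(weights, float)
    sol = Solution(tuple(idx), w / w.sum(), 0.0)
    return EnsembleReport(
        stable=[(n, float(wi), 1.0) for n, wi in zip(names, w / w.sum())],
        regional=[],
        mode="unconditional",
        prior_discarded=False,
        unmixed=False,
        solutions=[sol],
        minimax_error=0.0,
        panel_names={n: tuple(panel.coords[panel.index_of(n)]) for n in names},
    )


class TestGeneratePanel:
    def test_rows_on_simplex(self):
        panel = generate_panel(10, 6, seed=0)
        assert np.all(panel.R >= 0)
        np.testing.assert_allclose(panel.R.sum(axis=1), 1.0, atol=1e-9)
        assert panel.variances.shape == (10, 6)
        assert np.all((panel.variances >= 1e-5) & (panel.variances <= 1e-3))

    def test_small_concentration_near_vertices(self):
        panel = generate_panel(6, 2, concentration=0.02, seed=1)
        assert np.all(panel.R.max(axis=1) > 0.9)

    def test_seed_reproducibility(self):
        a = generate_panel(8, 4, seed=5)
        b = generate_panel(8, 4, seed=5)
        np.testing.assert_array_equal(a.R, b.R)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.names == b.names


class TestSimulateMixture:
    def test_noiseless_midpoint(self):
        panel = generate_panel(5, 4, seed=2)
        sc = MixtureScenario(
            sources=(panel.names[0], panel.names[1]), weights=(0.5, 0.5)
        )
        T = simulate_mixture(panel, sc)
        np.testing.assert_allclose(T, (panel.R[0] + panel.R[1]) / 2, atol=1e-12)

    def test_three_way_scenario_composition(self):
        panel = generate_panel(6, 5, seed=3)
        sc = MixtureScenario(
            sources=tuple(panel.names[:3]), weights=(0.5, 0.25, 0.25)
        )
        T = simulate_mixture(panel, sc)
        expected = np.array([0.5, 0.25, 0.25]) @ panel.R[:3]
        np.testing.assert_allclose(T, expected, atol=1e-12)

    def test_noiseless_mixture_in_hull_fits_exactly(self):
        panel = generate_panel(8, 4, seed=4)
        sc = MixtureScenario(
            sources=tuple(panel.names[2:5]), weights=(0.4, 0.35, 0.25)
        )
        T = simulate_mixture(panel, sc)
        fit = chebyshev_weights((2, 3, 4), panel, T)
        assert fit.minimax_error < 1e-8
        np.testing.assert_allclose(fit.weights, [0.4, 0.35, 0.25], atol=1e-6)

    def test_noise_variance_matches_model(self):
        panel = generate_panel(4, 3, seed=6)
        eps = 0.05
        idx = [0, 1]
        w = np.array([0.5, 0.5])
        draws = []
        mean = w @ panel.R[idx]
        for rep in range(1000):
            sc = MixtureScenario(
                sources=(panel.names[0], panel.names[1]),
                weights=(0.5, 0.5),
                noise_scale=eps,
                seed=rep,
            )
            draws.append(simulate_mixture(panel, sc))
        draws = np.array(draws)
        raw_var = eps**2 * (w**2) @ panel.variances[idx]
        # delta-method correction for the renormalization T' = T / sum(T):
        # var'_k ~= var_k (1 - 2 m_k) + m_k^2 sum_j var_j
        expected_var = raw_var * (1 - 2 * mean) + mean**2 * raw_var.sum()
        sample_var = draws.var(axis=0)
        np.testing.assert_allclose(sample_var, expected_var, rtol=0.2)

    def test_noise_scaling_quadratic_in_eps(self):
        panel = generate_panel(4, 3, seed=8)
        variances = {}
        for eps in (0.01, 0.03, 0.05):
            draws = [
                simulate_mixture(
                    panel,
                    MixtureScenario(
                        sources=(panel.names[0], panel.names[1]),
                        weights=(0.5, 0.5),
                        noise_scale=eps,
                        seed=rep,
                    ),
                )
                for rep in range(600)
            ]
            variances[eps] = np.mean(np.var(draws, axis=0))
        slope = np.polyfit(
            np.log([0.01, 0.03, 0.05]),
            np.log([variances[e] for e in (0.01, 0.03, 0.05)]),
            1,
        )[0]
        assert slope == pytest.approx(2.0, abs=0.3)

    def test_missing_variances_error(self):
        from tests.conftest import make_panel

        panel = make_panel(np.eye(3))
        sc = MixtureScenario(
            sources=("P0", "P1"), weights=(0.5, 0.5), noise_scale=0.03, seed=0
        )
        with pytest.raises(ValueError, match="variance"):
            simulate_mixture(panel, sc)


def test_scenario_weights_parsing():
    assert scenario_weights("50x50") == (0.5, 0.5)
    assert scenario_weights("50 x 25 x 25") == (0.5, 0.25, 0.25)
    with pytest.raises(ValueError):
        scenario_weights("50x40")


def test_draw_scenarios_distinct_sources():
    panel = generate_panel(10, 4, seed=9)
    scs = draw_scenarios(panel, (0.25,) * 4, 0.01, 20, seed=1)
    assert len(scs) == 20
    for sc in scs:
        assert len(set(sc.sources)) == 4


class TestZombieGenotypes:
    def test_fixed_frequencies(self):
        P = np.zeros((5, 2))
        P[:, 1] = 1.0
        assert np.all(zombie_genotypes(P, 0, 3, seed=0) == 0)
        assert np.all(zombie_genotypes(P, 1, 3, seed=0) == 2)

    def test_values_in_genotype_range(self):
        rng = np.random.default_rng(0)
        P = rng.random((100, 3))
        G = zombie_genotypes(P, 1, 15, seed=1)
        assert G.shape == (15, 100)
        assert set(np.unique(G)) <= {0, 1, 2}

    def test_mean_matches_binomial_expectation(self):
        L, m, p = 10000, 15, 0.3
        P = np.full((L, 1), p)
        G = zombie_genotypes(P, 0, m, seed=2)
        se = np.sqrt(2 * p * (1 - p) / (L * m))
        assert abs(G.mean() - 2 * p) < 3 * se

    def test_bad_index_rejected(self):
        with pytest.raises(ValueError):
            zombie_genotypes(np.full((10, 2), 0.5), 2, 5)


class TestHaversine:
    def test_zero_distance(self):
        assert haversine_km((10, 20), (10, 20)) == pytest.approx(0.0)

    def test_antipodal(self):
        assert haversine_km((0, 0), (0, 180)) == pytest.approx(
            np.pi * 6371, rel=1e-6
        )

    def test_quarter_great_circle(self):
        assert haversine_km((0, 0), (0, 90)) == pytest.approx(
            6371 * np.pi / 2, rel=1e-6
        )


class TestEvaluatePrediction:
    @pytest.fixture
    def panel(self):
        return generate_panel(10, 4, seed=12)

    def test_exact_prediction_perfect_scores(self, panel):
        sc = MixtureScenario(
            sources=(panel.names[0], panel.names[1]), weights=(0.5, 0.5)
        )
        rep = make_report(panel, list(sc.sources), [0.5, 0.5])
        m = evaluate_prediction(rep, sc, panel)
        assert m == EvalMetrics(100.0, 100.0, 100.0, 0.0)

    def test_nearby_wrong_name_counts_position_only(self):
        from tests.conftest import make_panel

        # P1 is ~111 km north of P0 (1 degree of latitude)
        panel = make_panel(
            [[1, 0], [0.8, 0.2], [0, 1]],
            names=["true", "near", "far"],
            coords=[(10.0, 20.0), (11.0, 20.0), (-60.0, -150.0)],
        )
        sc = MixtureScenario(
            sources=("true", "far"), weights=(0.5, 0.5)
        )
        rep = make_report(panel, ["near", "far"], [0.5, 0.5])
        m = evaluate_prediction(rep, sc, panel)
        assert m.correct_position_pct == 100.0
        assert m.correct_populations_pct == 0.0
        assert m.at_least_one_correct_origin_pct == 100.0
        assert 50 < m.avg_distance_to_correct_population_km < 60  # mean(111, 0)

    def test_batch_percentages_match_hand_count(self, panel):
        cases = [
            EvalMetrics(100.0, 100.0, 100.0, 0.0),
            EvalMetrics(100.0, 100.0, 0.0, 10.0),
            EvalMetrics(0.0, 0.0, 0.0, 2000.0),
        ]
        agg = summarize_metrics(cases)
        assert agg.correct_position_pct == pytest.approx(200 / 3)
        assert agg.at_least_one_correct_origin_pct == pytest.approx(200 / 3)
        assert agg.correct_populations_pct == pytest.approx(100 / 3)
        assert agg.avg_distance_to_correct_population_km == pytest.approx(670.0)

    def test_permutation_invariance(self, panel):
        sc1 = MixtureScenario(
            sources=(panel.names[2], panel.names[5]), weights=(0.5, 0.5)
        )
        sc2 = MixtureScenario(
            sources=(panel.names[5], panel.names[2]), weights=(0.5, 0.5)
        )
        rep_a = make_report(panel, [panel.names[5], panel.names[3]], [0.6, 0.4])
        rep_b = make_report(panel, [panel.names[3], panel.names[5]], [0.4, 0.6])
        m1 = evaluate_prediction(rep_a, sc1, panel)
        m2 = evaluate_prediction(rep_b, sc2, panel)
        assert dataclasses.asdict(m1) == pytest.approx(dataclasses.asdict(m2))

    def test_empty_prediction_is_failure(self, panel):
        sc = MixtureScenario(
            sources=(panel.names[0], panel.names[1]), weights=(0.5, 0.5)
        )
        rep = make_report(panel, [panel.names[2]], [1.0])
        rep.stable = []
        rep.solutions = []
        m = evaluate_prediction(rep, sc, panel)
        assert m.correct_position_pct == 0.0
        assert m.at_least_one_correct_origin_pct == 0.0
        assert m.avg_distance_to_correct_population_km > 0


def test_scenario_validation():
    with pytest.raises(ValueError):
        MixtureScenario(sources=("A",), weights=(1.0,))
    with pytest.raises(ValueError):
        MixtureScenario(sources=("A", "B"), weights=(0.7, 0.7))
    with pytest.raises(ValueError):
        MixtureScenario(sources=("A", "B"), weights=(0.5, 0.5), noise_scale=-1)
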