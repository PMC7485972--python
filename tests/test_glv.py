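import numpy as np
import pandas as pd
import pytest

from linkrisk.glv import (
    GLVParameterSet,
    GLVSystem,
    LinkExclusion,
    UnidentifiableError,
    add_degree_columns,
    build_system,
    estimate_delta,
    feasibility_contribution,
    network_feasibility_run,
    omega_center_deviation,
    omega_solid_angle,
    stability_threshold,
    structural_center,
)
from linkrisk.network_io import WeightedBipartiteNetwork, assemble_link_table
from linkrisk.synthetic import MetawebConfig, generate_glv_fixture, generate_metaweb


def _net(weights, network_id="n"):
    weights = np.asarray(weights, dtype=float)
    return WeightedBipartiteNetwork(
        network_id, "pollination",
        [f"p{i}" for i in range(weights.shape[0])],
        [f"a{j}" for j in range(weights.shape[1])],
        weights,
    )


class TestEstimateDelta:
    def test_toy_table_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(
            {
                "weight": rng.uniform(1, 50, 6),
                "d_plant": [1.0, 2, 3, 2, 4, 1],
                "d_animal": [2.0, 1, 2, 3, 1, 4],
            }
        )
        res = estimate_delta(table)
        # independent closed-form least squares on the stacked design
        y = np.log(table.weight / (table.d_plant * table.d_animal))
        y2 = np.concatenate([y, y])
        X = np.zeros((12, 3))
        X[:6, 0] = 1
        X[6:, 1] = 1
        X[:, 2] = np.concatenate([np.log(table.d_plant), np.log(table.d_animal)])
        beta = np.linalg.solve(X.T @ X, X.T @ y2)
        assert res.delta == pytest.approx(-beta[2], abs=1e-12)
        assert res.intercept_plants == pytest.approx(beta[0], abs=1e-12)
        assert res.n_obs == 12

    def test_noise_free_planted_metaweb_is_exact(self):
        cfg = MetawebConfig(
            seed=3, frequency_noise_scale=0.0, cross_link_prob=0.0,
            consistency_planted=False, true_delta=0.5,
        )
        nets, _, _ = generate_metaweb(cfg)
        table = add_degree_columns(assemble_link_table(nets), nets)
        assert estimate_delta(table).delta == pytest.approx(0.5, abs=1e-10)

    def test_no_degree_variation_unidentifiable(self):
        table = pd.DataFrame(
            {"weight": [1.0, 2.0], "d_plant": [2.0, 2.0], "d_animal": [2.0, 2.0]}
        )
        with pytest.raises(UnidentifiableError):
            estimate_delta(table)


class TestBuildSystem:
    def test_single_link_hand_assembly(self, two_by_two):
        L = np.array([[1, 0], [0, 0]])
        params = GLVParameterSet(rho=0.0, delta=0.0, gamma0=0.5, adjacency=L)
        B = build_system(two_by_two, params).B
        expected = np.eye(4)
        expected[0, 2] = expected[2, 0] = -0.5
        np.testing.assert_allclose(B, expected)

    def test_gamma_zero_gives_identity(self, two_by_two):
        params = GLVParameterSet(rho=0.0, delta=0.3, gamma0=0.0, adjacency=two_by_two.adjacency)
        np.testing.assert_allclose(build_system(two_by_two, params).B, np.eye(4))

    def test_rho_only_structure(self, two_by_two):
        rho = 0.01
        params = GLVParameterSet(rho=rho, delta=0.0, gamma0=0.0,
                                 adjacency=np.zeros((2, 2)))
        B = build_system(two_by_two, params).B
        block = (1 - rho) * np.eye(2) + rho * np.ones((2, 2))
        expected = np.zeros((4, 4))
        expected[:2, :2] = block
        expected[2:, 2:] = block
        np.testing.assert_allclose(B, expected)

    def test_trade_off_divides_by_focal_degree(self, two_by_two):
        delta = 0.339
        params = GLVParameterSet(rho=0.0, delta=delta, gamma0=1.0,
                                 adjacency=two_by_two.adjacency)
        B = build_system(two_by_two, params).B
        np.testing.assert_allclose(B[0, 2], -1.0 / 2**delta)


class TestStabilityThreshold:
    def test_matches_svd_closed_form_at_rho_zero(self):
        # at rho = 0 the symmetric part is I + gamma0 * K, so the threshold
        # is exactly 1 / sigma_max(K)
        for seed in (1, 2, 3):
            net = generate_glv_fixture(4, 5, 0.5, seed=seed)
            delta = 0.339
            L = net.adjacency.astype(float)
            gp = L / net.plant_degrees()[:, None] ** delta
            ga = L.T / net.animal_degrees()[:, None] ** delta
            oracle = 1.0 / np.linalg.svd((gp + ga.T) / 2, compute_uv=False)[0]
            assert stability_threshold(net, delta, 0.0) == pytest.approx(oracle, rel=1e-5)

    def test_grid_scan_oracle_complete_2x2(self, two_by_two):
        delta = 0.339
        thr = stability_threshold(two_by_two, delta, 0.0)
        grid = np.linspace(1e-4, 3, 30_000)
        stable = []
        for g in grid:
            B = build_system(
                two_by_two,
                GLVParameterSet(rho=0.0, delta=delta, gamma0=g, adjacency=two_by_two.adjacency),
            ).B
            stable.append(np.linalg.eigvalsh((B + B.T) / 2)[0] > 0)
        grid_thr = grid[np.argmin(stable)] if not all(stable) else grid[-1]
        assert thr == pytest.approx(grid_thr, abs=1e-4)

    def test_smallest_eigenvalue_decreasing_in_gamma0(self, random_10x15):
        delta = 0.339
        eigs = []
        for g in np.linspace(0, 2, 10):
            B = build_system(
                random_10x15,
                GLVParameterSet(rho=0.0, delta=delta, gamma0=g, adjacency=random_10x15.adjacency),
            ).B
            eigs.append(np.linalg.eigvalsh((B + B.T) / 2)[0])
        assert all(a >= b for a, b in zip(eigs, eigs[1:]))

    def test_threshold_nonincreasing_when_link_added(self):
        net = _net([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        thr = stability_threshold(net, 0.339, 0.0)
        with_link = net.weights.copy()
        with_link[0, 2] = 1.0
        denser = _net(with_link)
        assert stability_threshold(denser, 0.339, 0.0) <= thr + 1e-9


class TestStructuralCenter:
    def test_identity_center_is_diagonal(self):
        rc = structural_center(GLVSystem(B=np.eye(3), n_plants=2, n_animals=1))
        np.testing.assert_allclose(rc, np.ones(3) / np.sqrt(3))

    def test_bisects_planar_cone(self):
        B = np.array([[1.0, 1.0], [0.0, 1.0]])
        rc = structural_center(GLVSystem(B=B, n_plants=1, n_animals=1))
        assert np.degrees(np.arctan2(rc[1], rc[0])) == pytest.approx(22.5, abs=1e-9)

    def test_invariant_to_positive_column_rescaling(self):
        rng = np.random.default_rng(4)
        B = rng.normal(size=(5, 5))
        scales = rng.uniform(0.1, 10, 5)
        a = structural_center(GLVSystem(B=B, n_plants=3, n_animals=2))
        b = structural_center(GLVSystem(B=B * scales, n_plants=3, n_animals=2))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_center_always_feasible(self):
        for seed in range(5):
            net = generate_glv_fixture(3, 4, 0.6, seed=seed)
            thr = stability_threshold(net, 0.339, 0.0)
            sys = build_system(
                net,
                GLVParameterSet(rho=0.0, delta=0.339, gamma0=thr / 2, adjacency=net.adjacency),
            )
            rc = structural_center(sys)
            assert (np.linalg.solve(sys.B, rc) > 0).all()


class TestOmegaEstimators:
    def test_identity_quadrant_fractions(self):
        for S, expect in [(2, 0.25), (3, 0.125)]:
            est = omega_solid_angle(GLVSystem(B=np.eye(S), n_plants=S, n_animals=0),
                                    100_000, seed=11)
            assert abs(est.omega - expect) <= 3 * est.mc_standard_error

    def test_half_quadrant_cone(self):
        # columns (1,0) and (1,1): a 45-degree cone = 1/8 of the circle
        B = np.array([[1.0, 1.0], [0.0, 1.0]])
        est = omega_solid_angle(GLVSystem(B=B, n_plants=1, n_animals=1), 200_000, seed=2)
        assert abs(est.omega - 0.125) <= 3 * est.mc_standard_error

    def test_center_deviation_identity_2d_is_quarter(self):
        est = omega_center_deviation(GLVSystem(B=np.eye(2), n_plants=1, n_animals=1),
                                     500, seed=3)
        # every arc hits the boundary at exactly pi/4
        assert est.omega == pytest.approx(0.25, abs=1e-4)

    def test_both_estimators_scale_invariant(self):
        rng = np.random.default_rng(9)
        B = np.eye(4) - 0.2 * rng.random((4, 4))
        scales = rng.uniform(0.5, 5, 4)
        for fn in (omega_solid_angle, omega_center_deviation):
            a = fn(GLVSystem(B=B, n_plants=2, n_animals=2), 5_000, seed=1).omega
            b = fn(GLVSystem(B=B * scales, n_plants=2, n_animals=2), 5_000, seed=1).omega
            assert a == pytest.approx(b, abs=1e-9)

    def test_same_seed_reproduces(self):
        sys = GLVSystem(B=np.eye(4), n_plants=2, n_animals=2)
        for fn in (omega_solid_angle, omega_center_deviation):
            assert fn(sys, 3_000, seed=5).omega == fn(sys, 3_000, seed=5).omega

    def test_singular_matrix_rejected(self):
        B = np.ones((3, 3))
        with pytest.raises(np.linalg.LinAlgError):
            omega_solid_angle(GLVSystem(B=B, n_plants=2, n_animals=1), 100, seed=0)


class TestFeasibilityContribution:
    def test_identical_systems_give_exactly_zero(self, two_by_two):
        # common random numbers: the O/O ratio is exactly 1
        from linkrisk.glv import _omega_from_dirs, sample_directions

        params = GLVParameterSet(rho=0.0, delta=0.0, gamma0=0.3,
                                 adjacency=two_by_two.adjacency)
        B = build_system(two_by_two, params).B
        dirs = sample_directions(4, 2_000, seed=0)
        for est in ("solid_angle", "center_deviation"):
            assert _omega_from_dirs(B, dirs, est) == _omega_from_dirs(B, dirs, est)

    def test_removal_isolating_species_signals_exclusion(self):
        net = _net([[1, 1], [0, 1]])
        params = GLVParameterSet(rho=0.0, delta=0.0, gamma0=0.1, adjacency=net.adjacency)
        with pytest.raises(LinkExclusion):
            feasibility_contribution(net, 0, 0, params, n_directions=100, seed=0)

    def test_low_precision_agrees_with_high_precision(self):
        net = generate_glv_fixture(3, 3, 0.8, seed=4)
        thr = stability_threshold(net, 0.339, 0.0)
        params = GLVParameterSet(rho=0.0, delta=0.339, gamma0=thr / 2, adjacency=net.adjacency)
        idx = net.link_indices()
        i, j = next((i, j) for i, j in idx
                    if net.plant_degrees()[i] > 1 and net.animal_degrees()[j] > 1)
        lo = feasibility_contribution(net, i, j, params, "solid_angle", 10_000, seed=1)
        hi = feasibility_contribution(net, i, j, params, "solid_angle", 1_000_000, seed=2)
        assert np.sign(lo) == np.sign(hi)
        assert lo == pytest.approx(hi, abs=3.0)


class TestNetworkFeasibilityRun:
    def test_complete_2x2_has_no_exclusions(self, two_by_two):
        result, diag = network_feasibility_run(two_by_two, 0.0, 0.339,
                                               n_directions=500, seed=0)
        assert diag["n_excluded"] == 0
        assert result["I_percent"].notna().all()

    def test_star_network_excludes_every_link(self, double_star):
        result, diag = network_feasibility_run(double_star, 0.0, 0.339,
                                               n_directions=200, seed=0)
        assert result["excluded"].all()
        assert diag["n_included"] == 0

    def test_excluded_count_matches_degree_scan(self, random_10x15):
        result, _ = network_feasibility_run(random_10x15, 0.0, 0.339,
                                            n_directions=200, seed=0)
        dp = random_10x15.plant_degrees()
        da = random_10x15.animal_degrees()
        brute = sum(
            1 for i, j in random_10x15.link_indices() if dp[i] == 1 or da[j] == 1
        )
        assert int(result["excluded"].sum()) == brute

    def test_cross_estimator_omega_rank_agreement(self):
        # the two estimators measure cone size differently but must rank a
        # panel of systems the same way
        from scipy.stats import spearmanr

        oms, omc = [], []
        for seed in range(12):
            net = generate_glv_fixture(2 + seed % 3, 2 + (seed + 1) % 3, 0.7, seed=300 + seed)
            thr = stability_threshold(net, 0.339, 0.0)
            g = thr * (0.2 + 0.6 * (seed % 5) / 4)
            sys = build_system(
                net, GLVParameterSet(rho=0.0, delta=0.339, gamma0=g, adjacency=net.adjacency)
            )
            oms.append(omega_solid_angle(sys, 100_000, seed=1).omega)
            omc.append(omega_center_deviation(sys, 3_000, seed=1).omega)
        assert spearmanr(oms, omc).statistic >= 0.8
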