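"""Unit and property tests of the cellular-automaton engine."""

import numpy as np
import pytest

from snailtrail.config import CAConfig, ConfigError, TAFField
from snailtrail.ca import (attempt_branch, attempt_move, direction_probabilities,
                           init_lattice, run_realization, step)


def make_state(config, positions, ecs=(), rng_seed=0):
    """A lattice with TCs at the given positions and ECs at the given
    (i, j, count) triples."""
    state = init_lattice(config.with_(R=config.R), np.random.RandomState(rng_seed))
    for aid in list(state.agents):
        state.kill(aid)
    state.ec_grid[:] = 0
    ids = [state.spawn(i, j) for i, j in positions]
    for i, j, n in ecs:
        state.ec_grid[i, j] = n
    return state, ids


class TestInitLattice:
    def test_alternating_limbus_placement(self):
        cfg = CAConfig(R=200)
        state = init_lattice(cfg)
        assert state.n_tc == 100
        assert state.n_ec == 0
        occupied = np.nonzero(state.tc_grid)
        assert set(occupied[0]) == {0}
        assert sorted(occupied[1]) == list(range(1, 200, 2))

    def test_smallest_lattice_single_tip(self):
        state = init_lattice(CAConfig(R=2, k=0.5))
        assert state.n_tc == 1
        assert state.tc_grid[0, 1] == 1

    @pytest.mark.parametrize("R", [4, 10, 36])
    def test_tc_count_is_half_R(self, R):
        cfg = CAConfig(R=R, k=R / 4)
        assert init_lattice(cfg).n_tc == R // 2

    def test_odd_R_rejected(self):
        with pytest.raises(ConfigError):
            CAConfig(R=7)


class TestDirectionProbabilities:
    def test_standard_bias_saturates_backward_motion(self):
        """k=100 with h=1/200 gives (1/2, 0, 1/4, 1/4)."""
        taf = TAFField.linear(200)
        probs = direction_probabilities(taf, 100.0, (100, 50))
        np.testing.assert_allclose(probs, [0.5, 0.0, 0.25, 0.25], atol=1e-14)

    def test_unbiased_walk_at_zero_sensitivity(self):
        probs = direction_probabilities(TAFField.linear(20), 0.0, (5, 5))
        np.testing.assert_allclose(probs, [0.25] * 4)

    def test_intermediate_bias(self):
        """k * (c_{i+1}-c_{i-1}) = 0.5 gives (0.375, 0.125, 0.25, 0.25)."""
        taf = TAFField.linear(20)  # central difference 2h = 0.1
        probs = direction_probabilities(taf, 5.0, (10, 3))
        np.testing.assert_allclose(probs, [0.375, 0.125, 0.25, 0.25])

    def test_components_sum_to_one(self):
        taf = TAFField.linear(40)
        for i in (0, 1, 20, 39, 40):
            assert direction_probabilities(taf, 10.0, (i, 5)).sum() == pytest.approx(1.0)

    def test_oversized_k_rejected(self):
        with pytest.raises(ConfigError):
            direction_probabilities(TAFField.linear(10), 11.0, (5, 5))


class TestAttemptMove:
    def test_vacant_target_deposits_ec_at_origin(self, rng):
        cfg = CAConfig(R=10, k=2.0, mode=1)
        state, (aid,) = make_state(cfg, [(5, 5)])
        out = None
        while out is None or out.kind != "moved":
            out = attempt_move(state, aid, cfg, rng)
        assert state.n_tc == 1
        assert state.ec_grid[5, 5] == 1
        ag = state.agents[aid]
        assert (ag.i, ag.j) == out.target
        assert (5, 5) in ag.trail

    def test_tip_to_tip_anastomosis_removes_both_and_places_two_ecs(self):
        cfg = CAConfig(R=10, k=2.0, a_n=1.0, mode=1)
        state, ids = make_state(cfg, [(5, 5), (5, 6)])
        rng = np.random.RandomState(0)
        out = None
        while state.n_tc == 2:
            out = attempt_move(state, state.alive[0], cfg, rng)
        assert out.kind == "tip_tip"
        assert state.n_tc == 0
        assert state.ec_grid[out.origin] == 1
        assert state.ec_grid[out.target] == 1

    def test_pure_exclusion_never_changes_state(self, rng):
        """With a_n=0 a move onto a TC is always aborted (10^4 trials)."""
        cfg = CAConfig(R=2, k=0.5, P_m=1.0, a_n=0.0, mode=1)
        state, ids = make_state(cfg, [(1, 1), (1, 2), (0, 1), (2, 1), (1, 0)])
        # centre TC is boxed in by TCs on all four sides
        before_tc = state.tc_grid.copy()
        for _ in range(10_000):
            out = attempt_move(state, ids[0], cfg, rng)
            assert out.kind in ("excluded_tc", "no_attempt")
        np.testing.assert_array_equal(state.tc_grid, before_tc)
        assert state.n_ec == 0

    def test_boundary_moves_aborted(self, rng):
        cfg = CAConfig(R=2, k=0.5, mode=1)
        state, (aid,) = make_state(cfg, [(0, 0)])
        kinds = {attempt_move(state, aid, cfg, rng).kind for _ in range(500)}
        assert "boundary_aborted" in kinds
        ag = state.agents.get(aid)
        if ag is not None:
            assert 0 <= ag.i <= 2 and 0 <= ag.j <= 2

    def test_self_loop_prohibited_in_model_2(self):
        cfg = CAConfig(R=10, k=2.0, a_e=1.0, mode=2, P_m=1.0)
        state, (aid,) = make_state(cfg, [(5, 5)])
        state.ec_grid[5, 6] = 1
        state.agents[aid].trail.add((5, 6))
        rng = np.random.RandomState(1)
        kinds = set()
        for _ in range(2000):
            if aid not in state.agents:
                break
            out = attempt_move(state, aid, cfg, rng)
            kinds.add(out.kind)
            if out.kind == "moved":
                break
        assert "selfloop_aborted" in kinds
        assert "tip_sprout" not in kinds

    def test_tip_to_sprout_removes_tc_and_keeps_target_ec(self):
        cfg = CAConfig(R=10, k=2.0, a_e=1.0, mode=2, P_m=1.0)
        ecs = [(6, 5, 1), (4, 5, 1), (5, 6, 1), (5, 4, 1)]
        state, (aid,) = make_state(cfg, [(5, 5)], ecs=ecs)
        rng = np.random.RandomState(2)
        out = attempt_move(state, aid, cfg, rng)
        while out.kind == "no_attempt":
            out = attempt_move(state, aid, cfg, rng)
        assert out.kind == "tip_sprout"
        assert state.n_tc == 0
        assert state.ec_grid[5, 5] == 1      # deposited at origin
        assert state.ec_grid[out.target] == 1  # target EC remains

    def test_dead_agent_raises(self, rng):
        cfg = CAConfig(R=4, k=1.0)
        state, (aid,) = make_state(cfg, [(2, 2)])
        state.kill(aid)
        from snailtrail.ca import CAError
        with pytest.raises(CAError):
            attempt_move(state, aid, cfg, rng)


class TestAttemptBranch:
    def test_branch_replaces_parent_with_two_daughters(self):
        cfg = CAConfig(R=10, k=2.0, P_p=1.0, mode=1)
        state, (aid,) = make_state(cfg, [(10, 5)])  # c=1 so P_b = 1
        rng = np.random.RandomState(0)
        out = attempt_branch(state, aid, cfg, rng)
        assert out == "branched"
        assert state.n_tc == 2
        assert state.tc_grid[10, 4] == 1 and state.tc_grid[10, 6] == 1
        assert state.tc_grid[10, 5] == 0
        assert state.n_ec == 0  # branching never creates ECs
        for a in state.agents.values():
            assert a.trail == set()

    def test_no_branching_at_zero_taf(self, rng):
        cfg = CAConfig(R=10, k=2.0, P_p=1.0, mode=1)
        state, (aid,) = make_state(cfg, [(0, 5)])  # c=0 at the limbus
        assert all(attempt_branch(state, aid, cfg, rng) == "no_attempt"
                   for _ in range(1000))

    def test_blocked_by_ec_in_model_2(self):
        cfg = CAConfig(R=10, k=2.0, P_p=1.0, mode=2)
        state, (aid,) = make_state(cfg, [(10, 5)], ecs=[(10, 6, 1)])
        rng = np.random.RandomState(0)
        assert attempt_branch(state, aid, cfg, rng) == "blocked"
        assert state.n_tc == 1

    def test_blocked_at_transverse_edge(self):
        cfg = CAConfig(R=10, k=2.0, P_p=1.0, mode=1)
        state, (aid,) = make_state(cfg, [(10, 0)])
        rng = np.random.RandomState(0)
        assert attempt_branch(state, aid, cfg, rng) == "blocked"


class TestStepAndRealization:
    def test_tc_count_conserved_without_birth_death(self):
        cfg = CAConfig(R=20, k=5.0, P_p=0.0, a_n=0.0, mode=1, K_max=50)
        state = init_lattice(cfg)
        n0 = state.n_tc
        for _ in range(50):
            step(state, cfg)
        assert state.n_tc == n0

    def test_empty_lattice_noop(self):
        cfg = CAConfig(R=4, k=1.0)
        state, _ = make_state(cfg, [])
        step(state, cfg, np.random.RandomState(0))
        assert state.K == 1 and state.n_tc == 0 and state.n_ec == 0

    def test_ec_count_equals_successful_moves_in_first_step(self):
        """From the initial condition with P_m=1, every EC present after
        one step marks a departure site."""
        cfg = CAConfig(R=20, k=5.0, P_m=1.0, P_p=0.0, a_n=0.0, mode=1)
        state = init_lattice(cfg, np.random.RandomState(3))
        step(state, cfg)
        # each successful move deposits exactly one EC at the vacated site
        moved = state.n_ec
        assert 0 < moved <= 10
        assert state.n_tc == 10

    def test_same_seed_bit_identical(self, small_config):
        a = run_realization(small_config, 99, [0, 20, 40], engine="python")
        b = run_realization(small_config, 99, [0, 20, 40], engine="python")
        for (t1, e1), (t2, e2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_different_seeds_diverge(self, small_config):
        a = run_realization(small_config, 1, [40], engine="python")
        b = run_realization(small_config, 2, [40], engine="python")
        assert not np.array_equal(a[0][0], b[0][0]) or not np.array_equal(a[0][1], b[0][1])

    def test_record_time_zero_returns_initial_condition(self, small_config):
        (tc, ec), = run_realization(small_config, 5, [0], engine="python")
        ref = init_lattice(small_config)
        np.testing.assert_array_equal(tc, ref.tc_grid)
        assert ec.sum() == 0

    @pytest.mark.parametrize("mode,a_n,a_e", [(1, 0.3, 1.0), (2, 0.3, 0.4)])
    def test_numba_and_python_engines_bit_identical(self, mode, a_n, a_e):
        cfg = CAConfig(R=20, k=5.0, P_m=1.0, P_p=0.05, a_n=a_n, a_e=a_e,
                       mode=mode, K_max=60)
        for seed in (0, 7):
            nb = run_realization(cfg, seed, [0, 15, 60], engine="numba")
            py = run_realization(cfg, seed, [0, 15, 60], engine="python")
            for (t1, e1), (t2, e2) in zip(nb, py):
                np.testing.assert_array_equal(t1, t2)
                np.testing.assert_array_equal(e1, e2)


class TestInvariants:
    """Occupancy and bookkeeping invariants on randomized runs."""

    @pytest.mark.parametrize("mode", [1, 2])
    def test_occupancy_and_bookkeeping(self, mode):
        cfg = CAConfig(R=16, k=4.0, P_m=1.0, P_p=0.1, a_n=0.4, a_e=0.5,
                       mode=mode, K_max=200)
        rng = np.random.RandomState(42)
        state = init_lattice(cfg, rng)
        prev_ec = 0
        for _ in range(200):
            step(state, cfg)
            state.check_consistency()
            assert state.tc_grid.max() <= 1
            if mode == 2:
                assert (state.tc_grid + state.ec_grid).max() <= 1
            assert state.ec_grid.min() >= 0
            ec = state.n_ec
            assert ec >= prev_ec  # total EC count non-decreasing
            prev_ec = ec

    def test_event_level_deltas(self, rng):
        """Per event: dTC in {0,+1,-1,-2}, dEC in {0,+1,+2}."""
        cfg = CAConfig(R=12, k=3.0, P_m=1.0, P_p=0.3, a_n=0.5, a_e=0.5,
                       mode=2, K_max=100)
        state = init_lattice(cfg, rng)
        deltas_seen = set()
        for _ in range(8000):
            n_alive = state.n_tc
            if n_alive == 0:
                break
            aid = state.alive[int(rng.random_sample() * n_alive) % n_alive]
            tc0, ec0 = state.n_tc, state.n_ec
            if rng.random_sample() < 0.7:
                out = attempt_move(state, aid, cfg, rng)
                dtc, dec = state.n_tc - tc0, state.n_ec - ec0
                expected = {"moved": (0, 1), "tip_tip": (-2, 2),
                            "tip_sprout": (-1, 1)}.get(out.kind, (0, 0))
                assert (dtc, dec) == expected
            else:
                out = attempt_branch(state, aid, cfg, rng)
                dtc = state.n_tc - tc0
                assert state.n_ec == ec0
                assert dtc == (1 if out == "branched" else 0)
            deltas_seen.add((state.n_tc - tc0, state.n_ec - ec0))
        assert len(deltas_seen) > 1


class TestSingleStepLaw:
    def test_outcome_distribution_matches_direction_probabilities(self):
        """For a lone TC the empirical law over move outcomes across 10^5
        trials matches P_m times the direction probabilities within 3 SE."""
        cfg = CAConfig(R=10, k=2.0, P_m=0.7, mode=1)
        taf = cfg.taf()
        probs = direction_probabilities(taf, cfg.k, (5, 5))
        n_trials = 100_000
        rng = np.random.RandomState(11)
        counts = {"x+": 0, "x-": 0, "y+": 0, "y-": 0, "none": 0}
        for _ in range(n_trials):
            state, (aid,) = make_state(cfg, [(5, 5)])
            out = attempt_move(state, aid, cfg, rng)
            if out.kind == "no_attempt":
                counts["none"] += 1
            else:
                di, dj = out.target[0] - 5, out.target[1] - 5
                counts[{(1, 0): "x+", (-1, 0): "x-", (0, 1): "y+", (0, -1): "y-"}[(di, dj)]] += 1
        expect = {"x+": cfg.P_m * probs[0], "x-": cfg.P_m * probs[1],
                  "y+": cfg.P_m * probs[2], "y-": cfg.P_m * probs[3],
                  "none": 1 - cfg.P_m}
        for key, p in expect.items():
            se = np.sqrt(p * (1 - p) / n_trials)
            assert abs(counts[key] / n_trials - p) < 3 * se + 1e-12, key


class TestSymmetricExclusionLimit:
    def test_column_marginal_matches_projected_walk(self):
        """With k=0, P_p=0, a_n=0 a lone TC's column occupancy over 10^4
        realizations matches the 1-D lazy-walk transition-matrix iterate
        within 3 SE (the linear-diffusion limit of the symmetric
        exclusion process).  A larger-M version of this check runs in the
        acceptance suite."""
        R, K = 20, 30
        cfg = CAConfig(R=R, k=0.0, P_m=1.0, P_p=0.0, a_n=0.0, mode=1,
                       K_IC=0, K_max=K)
        # transition matrix of the x-projection: left/right 1/4 each,
        # boundary exits aborted (self-loop weight added back)
        T = np.zeros((R + 1, R + 1))
        for i in range(R + 1):
            stay = 0.5
            if i > 0:
                T[i - 1, i] = 0.25
            else:
                stay += 0.25
            if i < R:
                T[i + 1, i] = 0.25
            else:
                stay += 0.25
            T[i, i] = stay
        p = np.zeros(R + 1)
        p[0] = 1.0
        for _ in range(K):
            p = T @ p
        M = 4_000
        counts = np.zeros(R + 1)
        # lone TC: strip the initial condition to one agent via run on R=20
        from snailtrail.ca import step as ca_step
        for m in range(M):
            rng = np.random.RandomState(50_000 + m)
            state, _ = make_state(cfg, [(0, 9)], rng_seed=0)
            state.rng = rng
            for _ in range(K):
                ca_step(state, cfg, rng)
            (ag,) = state.agents.values()
            counts[ag.i] += 1
        freq = counts / M
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / M)
        mask = p > 1e-4
        assert np.all(np.abs(freq[mask] - p[mask]) <= 3 * se[mask] + 5e-4)
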