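import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psohfs import datasets
from psohfs.cbpso import (
    Particle,
    SwarmConfig,
    chaotic_init,
    decode_solution,
    elitist_refresh,
    inertia_weight,
    logistic_series,
    make_fitness,
    maybe_reinitialize,
    mutate_gbest,
    random_init,
    reinit_probability,
    run,
    subset_fitness,
    update_particle,
)
from psohfs.lssvr import LSSVRConfig


def bit_count_fitness(target):
    """Toy deterministic fitness: Hamming distance to a target bitstring,
    with the empty subset penalized so it is never optimal."""
    target = np.asarray(target)

    def fn(pos):
        pos = np.asarray(pos).ravel()
        if not pos.any():
            return float("inf")
        return float(np.sum(pos != target))

    return fn


class TestLogisticSeries:
    def test_two_hand_iterations(self):
        q = logistic_series(0.3, 2, mu=4)
        assert q[0] == pytest.approx(0.84)
        assert q[1] == pytest.approx(0.5376)

    def test_degenerate_seed_rejected(self):
        for q0 in (0.25, 0.5, 0.75, 0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                logistic_series(q0, 5)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(1e-6, 1 - 1e-6).filter(lambda q: q not in (0.25, 0.5, 0.75)))
    def test_iterates_stay_in_unit_interval(self, q0):
        q = logistic_series(q0, 50)
        assert np.all((q >= 0) & (q <= 1))


class TestInertiaWeight:
    def test_starts_at_ws(self):
        assert inertia_weight(0, SwarmConfig(D=5)) == pytest.approx(1.2)

    def test_final_value_closed_form(self):
        cfg = SwarmConfig(D=5, t_max=100)
        expected = 0.4 * (1.2 / 0.4) ** (1 / 11)
        assert inertia_weight(100, cfg) == pytest.approx(expected, abs=1e-12)

    def test_non_increasing_over_schedule(self):
        cfg = SwarmConfig(D=5, t_max=50)
        ws = [inertia_weight(t, cfg) for t in range(51)]
        assert all(a >= b for a, b in zip(ws, ws[1:]))


class TestUpdateParticle:
    def test_velocity_always_clamped(self, rng):
        cfg = SwarmConfig(D=8, c1=50.0, c2=50.0)  # force huge raw velocities
        p = Particle(
            np.zeros(8, dtype=np.int8),
            np.full(8, 5.0),
            np.ones(8, dtype=np.int8),
            1.0,
        )
        update_particle(p, np.ones(8, dtype=np.int8), 1.2, cfg, rng)
        assert np.all(p.velocity <= 6.0) and np.all(p.velocity >= -6.0)

    def test_sigmoid_transfer_probabilities(self, rng):
        # S(0) = 0.5 and S(6) ~ 0.99753: at clamped velocity +6 nearly every
        # draw sets the bit
        cfg = SwarmConfig(D=1000, c1=1e6, c2=1e6)
        p = Particle(
            np.zeros(1000, dtype=np.int8),
            np.zeros(1000),
            np.ones(1000, dtype=np.int8),
            1.0,
        )
        update_particle(p, np.ones(1000, dtype=np.int8), 1.0, cfg, rng)
        assert np.all(p.velocity == 6.0)
        assert p.position.mean() == pytest.approx(1 / (1 + math.exp(-6)),
                                                  abs=0.01)


class TestFitness:
    def test_empty_subset_gets_infinite_sentinel(self, rng):
        X = rng.normal(size=(20, 3))
        fr = rng.random(3)
        cfg = LSSVRConfig(sigma2=1, gamma=1, folds=4, seed=0)
        assert subset_fitness(np.zeros(3), X, rng.random(20), fr, cfg, 0.5) \
            == float("inf")

    def test_zero_weight_reduces_to_prediction_error(self, rng):
        from psohfs.lssvr import cv_mse

        X = rng.normal(size=(20, 3))
        y = rng.random(20)
        cfg = LSSVRConfig(sigma2=1, gamma=1, folds=4, seed=0)
        pos = np.array([1, 0, 1])
        expected = cv_mse(X[:, [0, 2]], y, cfg)
        assert subset_fitness(pos, X, y, rng.random(3), cfg, 0.0) \
            == pytest.approx(expected, abs=1e-12)

    def test_planted_signal_feature_beats_noise_feature(self, rng):
        n = 80
        signal = rng.normal(size=n)
        X = np.column_stack([signal, rng.normal(size=n)])
        ps = 2 * signal + 0.05 * rng.normal(size=n)
        cfg = LSSVRConfig(sigma2=10, gamma=100, folds=5, seed=0)
        fr = np.array([0.1, 0.9])
        fit = make_fitness(X, ps, fr, cfg, 0.2)
        assert fit(np.array([1, 0])) < fit(np.array([0, 1]))

    def test_memoized_closure_matches_direct_computation(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.random(30)
        fr = rng.random(4)
        cfg = LSSVRConfig(sigma2=2.0, gamma=10.0, folds=5, seed=1)
        fit = make_fitness(X, y, fr, cfg, 0.3)
        for _ in range(8):
            pos = (rng.random(4) < 0.5).astype(np.int8)
            assert fit(pos) == pytest.approx(
                subset_fitness(pos, X, y, fr, cfg, 0.3), abs=1e-9
            )


class TestChaoticInit:
    def test_boundary_k_equals_n_keeps_all_candidates(self):
        cfg = SwarmConfig(N=8, D=4, k=8)
        fit = bit_count_fitness(np.ones(4))
        state = chaotic_init(cfg, fit, np.random.default_rng(0))
        assert len(state.particles) == 8

    def test_swarm_is_the_fittest_candidates(self):
        cfg = SwarmConfig(N=5, D=6, k=60)
        fit = bit_count_fitness(np.ones(6))
        state = chaotic_init(cfg, fit, np.random.default_rng(1))
        # every kept particle has at least 4 ones (the 5 best of 60)
        fits = sorted(p.pbest_fitness for p in state.particles)
        assert state.gbest_fitness == fits[0]
        assert all(f <= 3 for f in fits)

    def test_threshold_half_maps_to_one(self):
        # the transfer g(x) sets the bit for iterates >= 0.5 exactly
        from psohfs.cbpso import _chaotic_candidates

        rng = np.random.default_rng(2)
        cand = _chaotic_candidates(3, 20, 4.0, rng)
        assert set(np.unique(cand)) <= {0, 1}

    def test_fixed_seed_reproducible(self):
        cfg = SwarmConfig(N=6, D=5, k=30)
        fit = bit_count_fitness(np.ones(5))
        s1 = chaotic_init(cfg, fit, np.random.default_rng(3))
        s2 = chaotic_init(cfg, fit, np.random.default_rng(3))
        for p1, p2 in zip(s1.particles, s2.particles):
            assert np.array_equal(p1.position, p2.position)
            assert np.array_equal(p1.velocity, p2.velocity)


class TestReinitialization:
    def test_schedule_closed_forms(self):
        assert reinit_probability(1) == 0.0
        assert reinit_probability(3) == pytest.approx(
            1 - 1 / (1 + math.log(3)), abs=1e-12
        )
        vals = [reinit_probability(t) for t in range(1, 50)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_first_iteration_never_reinitializes(self):
        cfg = SwarmConfig(N=4, D=3, k=10)
        fit = bit_count_fitness(np.ones(3))
        state = chaotic_init(cfg, fit, np.random.default_rng(0))
        state.iteration = 1
        assert maybe_reinitialize(state, cfg, fit, np.random.default_rng(1)) == 0

    def test_zero_gate_disables_reinitialization(self):
        cfg = SwarmConfig(N=4, D=3, k=10, rk=0.0)
        fit = bit_count_fitness(np.ones(3))
        state = chaotic_init(cfg, fit, np.random.default_rng(0))
        state.iteration = 30
        before = [p.position.copy() for p in state.particles]
        assert maybe_reinitialize(state, cfg, fit, np.random.default_rng(1)) == 0
        for p, b in zip(state.particles, before):
            assert np.array_equal(p.position, b)

    def test_empirical_rate_matches_rk_times_schedule(self):
        # at currun=3, rk=0.3 the per-particle rate is ~0.157
        cfg = SwarmConfig(N=100, D=3, k=200, rk=0.3)
        fit = bit_count_fitness(np.ones(3))
        rng = np.random.default_rng(5)
        total = 0
        trials = 100
        for _ in range(trials):
            state = chaotic_init(cfg, fit, np.random.default_rng(0))
            state.iteration = 3
            total += maybe_reinitialize(state, cfg, fit, rng)
        rate = total / (trials * cfg.N)
        assert rate == pytest.approx(0.3 * reinit_probability(3), abs=0.01)

    def test_gbest_never_worsens(self):
        cfg = SwarmConfig(N=10, D=4, k=20)
        fit = bit_count_fitness(np.ones(4))
        state = chaotic_init(cfg, fit, np.random.default_rng(0))
        state.iteration = 50
        before = state.gbest_fitness
        maybe_reinitialize(state, cfg, fit, np.random.default_rng(1))
        assert state.gbest_fitness <= before


class TestGbestMutation:
    def _state(self, cfg, fit, seed=0):
        state = chaotic_init(cfg, fit, np.random.default_rng(seed))
        state.gbest_stagnation = cfg.stagnation_mutate
        return state

    def test_zero_probability_leaves_gbest_unchanged(self):
        cfg = SwarmConfig(N=4, D=3, k=10, pm=0.0)
        fit = bit_count_fitness(np.ones(3))
        state = self._state(cfg, fit)
        before = state.gbest_position.copy()
        assert not mutate_gbest(state, cfg, fit, np.random.default_rng(1))
        assert np.array_equal(state.gbest_position, before)

    def test_worse_candidate_rejected(self):
        # gbest already optimal: any mutation is worse and must be discarded
        cfg = SwarmConfig(N=2, D=3, k=4, pm=1.0)
        fit = bit_count_fitness(np.ones(3))
        state = self._state(cfg, fit)
        state.gbest_position = np.ones(3, dtype=np.int8)
        state.gbest_fitness = 0.0
        assert not mutate_gbest(state, cfg, fit, np.random.default_rng(1))
        assert state.gbest_fitness == 0.0

    def test_single_flip_reaches_planted_optimum(self):
        # gbest one bit away from the optimum: repeated 1/D-rate mutation
        # must find it
        target = np.array([1, 1, 1, 0], dtype=np.int8)
        cfg = SwarmConfig(N=2, D=4, k=4)
        fit = bit_count_fitness(target)
        state = self._state(cfg, fit)
        state.gbest_position = np.array([1, 1, 0, 0], dtype=np.int8)
        state.gbest_fitness = fit(state.gbest_position)
        rng = np.random.default_rng(7)
        adopted = any(mutate_gbest(state, cfg, fit, rng) for _ in range(100))
        assert adopted and state.gbest_fitness == 0.0


class TestElitism:
    def test_zero_fraction_is_noop(self):
        cfg = SwarmConfig(N=6, D=4, k=12, elite_fraction=0.0)
        fit = bit_count_fitness(np.ones(4))
        state = chaotic_init(cfg, fit, np.random.default_rng(0))
        assert elitist_refresh(state, cfg, fit, np.random.default_rng(1)) == 0

    def test_swarm_size_preserved_and_gbest_monotone(self):
        cfg = SwarmConfig(N=10, D=5, k=20, elite_fraction=0.3)
        fit = bit_count_fitness(np.ones(5))
        for seed in range(5):
            state = chaotic_init(cfg, fit, np.random.default_rng(seed))
            before = state.gbest_fitness
            elitist_refresh(state, cfg, fit, np.random.default_rng(seed + 50))
            assert len(state.particles) == 10
            assert state.gbest_fitness <= before

    def test_gbest_holder_survives(self):
        cfg = SwarmConfig(N=5, D=4, k=10, elite_fraction=0.8)
        fit = bit_count_fitness(np.ones(4))
        state = chaotic_init(cfg, fit, np.random.default_rng(2))
        holder_fit = state.gbest_fitness
        elitist_refresh(state, cfg, fit, np.random.default_rng(3))
        assert min(p.pbest_fitness for p in state.particles) <= holder_fit


class TestRun:
    def test_small_problem_matches_exhaustive_optimum(self):
        target = np.array([1, 0, 1], dtype=np.int8)
        fit = bit_count_fitness(target)
        cfg = SwarmConfig(N=8, D=3, k=16, t_max=20, seed=4)
        result = run(cfg, fit)
        brute = min(
            fit(np.array([(m >> i) & 1 for i in range(3)]))
            for m in range(1, 8)
        )
        assert result.best_fitness == brute

    def test_fixed_seed_gives_identical_traces(self):
        fit = bit_count_fitness(np.array([1, 1, 0, 1]))
        cfg = SwarmConfig(N=6, D=4, k=12, t_max=15, seed=9)
        r1, r2 = run(cfg, fit), run(cfg, fit)
        assert r1.trace == r2.trace
        assert r1.bitstring == r2.bitstring

    def test_trace_never_increases(self):
        fit = bit_count_fitness(np.array([0, 1, 1, 1, 0]))
        result = run(SwarmConfig(N=6, D=5, k=12, t_max=25, seed=2), fit)
        assert all(a >= b for a, b in zip(result.trace, result.trace[1:]))

    def test_disabled_devices_reduce_to_plain_bpso(self):
        """With chaos/reinit/mutation/elitism off, the engine must follow the
        textbook BPSO trajectory step for step (same RNG protocol)."""
        cfg = SwarmConfig(
            N=5, D=4, t_max=10, seed=11,
            use_chaos_init=False, use_reinit=False,
            use_mutation=False, use_elitism=False,
        )
        fit = bit_count_fitness(np.array([1, 0, 1, 1]))
        result = run(cfg, fit)

        # independent reference implementation
        rng = np.random.default_rng(cfg.seed)
        pos, vel, pb, pbf = [], [], [], []
        for _ in range(cfg.N):
            x = (rng.random(cfg.D) < 0.5).astype(np.int8)
            v = rng.uniform(cfg.V_min, cfg.V_max, cfg.D)
            pos.append(x); vel.append(v); pb.append(x.copy())
            pbf.append(fit(x))
        g = int(np.argmin(pbf))
        gb, gbf = pb[g].copy(), pbf[g]
        trace = []
        for t in range(cfg.t_max):
            w = cfg.wl * (cfg.ws / cfg.wl) ** (1 / (1 + cfg.c3 * t / cfg.t_max))
            for i in range(cfg.N):
                r1, r2 = rng.random(cfg.D), rng.random(cfg.D)
                v = (w * vel[i] + cfg.c1 * r1 * (pb[i] - pos[i])
                     + cfg.c2 * r2 * (gb - pos[i]))
                v = np.clip(v, cfg.V_min, cfg.V_max)
                vel[i] = v
                pos[i] = (rng.random(cfg.D) < 1 / (1 + np.exp(-v))).astype(np.int8)
                f = fit(pos[i])
                if f < pbf[i]:
                    pbf[i], pb[i] = f, pos[i].copy()
                    if f < gbf:
                        gbf, gb = f, pos[i].copy()
            trace.append(gbf)
        assert result.trace == trace
        assert np.array_equal(result.best_position, gb)


class TestDecode:
    def test_reference_bitstring_excludes_three_color_syndromes(self):
        names = list(datasets.load_ranking_reference()["name"])
        selected = decode_solution(datasets.OPTIMAL_SUBSET_BITSTRING, names)
        assert len(selected) == 24
        assert set(names) - set(selected) == {
            "Lip color", "Tongue color", "Coated tongue color",
        }

    def test_all_zero_and_all_one_vectors(self):
        names = ["a", "b", "c"]
        assert decode_solution(np.zeros(3), names) == []
        assert decode_solution(np.ones(3), names) == names

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_solution("101", ["a", "b"])


def test_random_init_respects_bounds():
    cfg = SwarmConfig(N=6, D=5, use_chaos_init=False)
    fit = bit_count_fitness(np.ones(5))
    state = random_init(cfg, fit, np.random.default_rng(0))
    for p in state.particles:
        assert np.all((p.velocity >= cfg.V_min) & (p.velocity <= cfg.V_max))
        assert set(np.unique(p.position)) <= {0, 1}
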