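import numpy as np
import pytest

from lungseg import (
    GCPSOState,
    PhantomSpec,
    SwarmConfig,
    SwarmSegmenter,
    SwarmState,
    fitness,
    gcpso_step,
    iwpso_step,
    make_phantom,
    pso_step,
    swarm_segment,
    update_rho,
)


def _state(x, v=None, fitness_fn=None):
    x = np.asarray(x, dtype=float)
    v = np.zeros_like(x) if v is None else np.asarray(v, dtype=float)
    f = np.array([fitness_fn(p) for p in x]) if fitness_fn else np.zeros(len(x))
    best = int(np.argmax(f))
    return SwarmState(
        x=x.copy(), v=v.copy(), pbest_x=x.copy(), pbest_f=f.copy(),
        gbest_x=x[best].copy(), gbest_f=float(f[best]),
    )


class TestFitness:
    def test_hand_value_three_pixels(self):
        img = np.array([[0.0, 0.5, 1.0]])
        # assignments: 0->0.25, 0.5->0.25 (tie, lowest), 1.0->0.75
        # global intra = (0.25+0.25+0.25)/3; inter_i = 0.5 each
        assert fitness(img, [0.25, 0.75]) == pytest.approx(4.0)

    def test_separation_limit_is_huge(self):
        img = np.array([[0.0] * 8 + [1.0] * 8])
        assert fitness(img, [0.0, 1.0]) > 1e8

    def test_invariant_to_center_permutation(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(8, 8))
        c = np.array([0.2, 0.9, 0.5])
        assert fitness(img, c) == pytest.approx(fitness(img, c[::-1]))

    def test_empty_cluster_contributes_zero(self):
        img = np.array([[0.0, 0.1]])
        # center 0.9 attracts nothing: only the occupied cluster's term
        # remains, inter = |0.9-0.05| = 0.85 over global intra 0.05
        assert fitness(img, [0.05, 0.9]) == pytest.approx(0.85 / 0.05)

    def test_histogram_mode_close_to_exact(self):
        img, _ = make_phantom(PhantomSpec(speckle_var=0.05, seed=2))
        c = [0.1, 0.4, 0.8]
        exact = fitness(img, c, exact=True)
        binned = fitness(img, c, exact=False)
        assert binned == pytest.approx(exact, rel=0.05)

    def test_single_center_rejected(self):
        with pytest.raises(ValueError):
            fitness(np.zeros((2, 2)) + 0.5, [0.5])


class TestUpdateRho:
    def test_expansion_after_sustained_success(self):
        cfg = SwarmConfig()
        assert update_rho(1.0, 16, 0, cfg) == 2.0

    def test_unchanged_in_between(self):
        cfg = SwarmConfig()
        assert update_rho(1.0, 3, 0, cfg) == 1.0
        assert update_rho(1.0, 0, 5, cfg) == 1.0

    def test_contraction_after_sustained_failure(self):
        cfg = SwarmConfig()
        assert update_rho(1.0, 0, 6, cfg) == 0.5

    def test_both_counters_nonzero_rejected(self):
        with pytest.raises(ValueError):
            update_rho(1.0, 1, 1, SwarmConfig())


class TestPsoStep:
    def test_particle_at_both_bests_with_zero_velocity_stays(self):
        fit = lambda p: 0.0
        st = _state([[0.5, 0.5], [0.2, 0.8]])
        out = pso_step(st, SwarmConfig(n_particles=2), fit, np.random.default_rng(0))
        # particle 0 sits at its pbest AND the gbest with v=0: both
        # attraction terms vanish, so it stays put exactly
        np.testing.assert_array_equal(out.x[0], st.x[0])

    def test_pure_drift_without_attraction(self):
        fit = lambda p: 0.0
        st = _state([[0.3, 0.3], [0.5, 0.5]], v=[[0.1, 0.1], [0.1, 0.1]])
        cfg = SwarmConfig(n_particles=2, c1=0.0, c2=0.0)
        out = pso_step(st, cfg, fit, np.random.default_rng(0))
        np.testing.assert_allclose(out.x, st.x + 0.1)

    def test_matches_replayed_random_draws(self):
        fit = lambda p: float(-np.sum((p - 0.5) ** 2))
        x0 = np.array([[0.1, 0.9], [0.4, 0.6], [0.8, 0.2]])
        st = _state(x0, fitness_fn=fit)
        cfg = SwarmConfig(n_particles=3)
        out = pso_step(st, cfg, fit, np.random.default_rng(42))
        # replay with the same generator sequence
        rng = np.random.default_rng(42)
        r1 = rng.uniform(size=x0.shape)
        r2 = rng.uniform(size=x0.shape)
        v = cfg.c1 * r1 * (st.pbest_x - x0) + cfg.c2 * r2 * (st.gbest_x - x0)
        v = np.clip(v, -cfg.v_max, cfg.v_max)
        np.testing.assert_allclose(out.x, np.clip(x0 + v, 0, 1))

    def test_pbest_updates_only_on_strict_improvement(self):
        fit = lambda p: float(p[0])
        st = _state([[0.2], [0.4]], fitness_fn=fit)
        out = pso_step(st, SwarmConfig(n_particles=2), fit,
                       np.random.default_rng(1))
        assert np.all(out.pbest_f >= st.pbest_f)
        assert out.gbest_f >= st.gbest_f


class TestIwpsoStep:
    def test_frozen_when_w_zero_at_bests(self):
        fit = lambda p: 0.0
        st = _state([[0.5], [0.3]], v=[[0.2], [0.2]])
        cfg = SwarmConfig(n_particles=2, w=0.0, c1=0.0, c2=0.0)
        out = iwpso_step(st, cfg, fit, np.random.default_rng(0))
        np.testing.assert_array_equal(out.x, st.x)

    def test_w_one_reproduces_plain_drift(self):
        fit = lambda p: 0.0
        st = _state([[0.3], [0.6]], v=[[0.1], [0.1]])
        cfg = SwarmConfig(n_particles=2, w=1.0, c1=0.0, c2=0.0)
        a = iwpso_step(st, cfg, fit, np.random.default_rng(0))
        b = pso_step(st, SwarmConfig(n_particles=2, c1=0.0, c2=0.0), fit,
                     np.random.default_rng(0))
        np.testing.assert_allclose(a.x, b.x)

    def test_geometric_velocity_decay(self):
        fit = lambda p: 0.0
        st = _state([[0.2], [0.4]], v=[[0.1], [0.1]])
        cfg = SwarmConfig(n_particles=2, w=0.7, c1=0.0, c2=0.0)
        rng = np.random.default_rng(0)
        expected = [0.07, 0.049, 0.0343]
        for step_v in expected:
            st = iwpso_step(st, cfg, fit, rng)
            np.testing.assert_allclose(st.v, step_v)

    def test_random_w_shared_within_iteration(self):
        fit = lambda p: 0.0
        st = _state([[0.3], [0.6]], v=[[0.1], [0.1]])
        cfg = SwarmConfig(n_particles=2, w_mode="random", c1=0.0, c2=0.0)
        out = iwpso_step(st, cfg, fit, np.random.default_rng(7))
        # both particles decayed by the same drawn w in [0.5, 1.0]
        ws = out.v / st.v
        assert np.allclose(ws, ws.ravel()[0])
        assert 0.5 <= ws.ravel()[0] <= 1.0


def _gc_state(x, fitness_fn, rho=1.0):
    base = _state(x, fitness_fn=fitness_fn)
    return GCPSOState(
        x=base.x, v=base.v, pbest_x=base.pbest_x, pbest_f=base.pbest_f,
        gbest_x=base.gbest_x, gbest_f=base.gbest_f,
        rho=rho, tau=int(np.argmax(base.pbest_f)),
    )


class TestGcpsoStep:
    def test_gbest_holder_lands_on_gbest_when_rho_vanishes(self):
        fit = lambda p: float(-np.sum((p - 0.5) ** 2))
        st = _gc_state([[0.5, 0.5], [0.1, 0.9]], fit, rho=1e-300)
        out = gcpso_step(st, SwarmConfig(n_particles=2), fit,
                         np.random.default_rng(0))
        np.testing.assert_allclose(out.x[st.tau], st.gbest_x, atol=1e-12)

    def test_counters_mutually_exclusive_and_rho_positive(self):
        fit = lambda p: float(np.sum(p))
        st = _gc_state([[0.2, 0.2], [0.6, 0.6], [0.4, 0.1]], fit)
        cfg = SwarmConfig(n_particles=3)
        rng = np.random.default_rng(3)
        for _ in range(30):
            st = gcpso_step(st, cfg, fit, rng)
            assert st.success_count == 0 or st.failure_count == 0
            assert st.rho > 0

    def test_rho_trace_replays_counter_rule(self):
        img, _ = make_phantom(PhantomSpec(speckle_var=0.05, seed=4))
        est = SwarmSegmenter(variant="gcpso", max_iter=60, random_state=4).fit(img)
        cfg = SwarmConfig()
        rho = cfg.rho0
        for r, s, f in zip(est.rho_trace_, est.success_trace_, est.failure_trace_):
            rho = update_rho(rho, s, f, cfg)
            assert r == pytest.approx(rho)


class TestSwarmSegmenter:
    @pytest.mark.parametrize("variant", ["pso", "iwpso", "gcpso"])
    def test_recovers_two_level_phantom_centers(self, variant, two_level_image):
        img, _ = two_level_image
        model = swarm_segment(img, variant=variant, k=2,
                              config=SwarmConfig(seed=0))
        np.testing.assert_allclose(model.centers, [0.2, 0.8], atol=0.05)

    @pytest.mark.parametrize("variant", ["pso", "iwpso", "gcpso"])
    def test_gbest_trace_nondecreasing(self, variant, speckled_phantom):
        img, _ = speckled_phantom
        est = SwarmSegmenter(variant=variant, max_iter=40, random_state=1).fit(img)
        trace = np.array(est.fitness_trace_)
        assert np.all(np.diff(trace) >= 0)

    def test_same_seed_identical_model(self, speckled_phantom):
        img, _ = speckled_phantom
        a = SwarmSegmenter(max_iter=30, random_state=5).fit(img)
        b = SwarmSegmenter(max_iter=30, random_state=5).fit(img)
        np.testing.assert_array_equal(a.centers_, b.centers_)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        assert a.fitness_trace_ == b.fitness_trace_

    def test_positions_in_bounds_velocities_clamped(self):
        img, _ = make_phantom(PhantomSpec(speckle_var=0.05, seed=6))
        cfg = SwarmConfig(seed=6)
        from lungseg.swarm import _init_state, _make_fitness, iwpso_step

        rng = np.random.default_rng(6)
        fit = _make_fitness(img)
        st = _init_state(img, 3, cfg, rng, fit, "iwpso")
        for _ in range(20):
            st = iwpso_step(st, cfg, fit, rng)
            assert st.x.min() >= 0.0 and st.x.max() <= 1.0
            assert np.all(np.abs(st.v) <= cfg.v_max + 1e-12)

    def test_exact_and_histogram_fitness_agree_on_centers(self):
        img, _ = make_phantom(PhantomSpec(speckle_var=0.05, seed=8))
        a = SwarmSegmenter(max_iter=60, random_state=8,
                           exact_fitness=False).fit(img)
        b = SwarmSegmenter(max_iter=60, random_state=8,
                           exact_fitness=True).fit(img)
        np.testing.assert_allclose(a.centers_, b.centers_, atol=0.02)

    @pytest.mark.parametrize("variant", ["pso", "iwpso", "gcpso"])
    def test_class_recovery_across_seeds(self, variant):
        """The gbest centers must induce the true three-region partition
        on nearly all pixels for at least 9 of 10 seeds. Recovery is
        judged on the segmentation rather than raw center proximity: the
        validity fitness legitimately places the small bright cluster's
        center slightly beyond its class mean (the intercluster gain
        outweighs the tiny intracluster cost)."""
        hits = 0
        for seed in range(10):
            spec = PhantomSpec(height=48, width=48,
                               lung_ellipses=[((24.0, 24.0), (17.0, 15.0), 0.35)],
                               tumor_disc=((22.0, 22.0), 5.0, 0.85),
                               speckle_var=0.01, seed=seed)
            img, _ = make_phantom(spec)
            clean, _ = make_phantom(
                PhantomSpec(**{**spec.__dict__, "speckle_var": 0.0})
            )
            true_label = np.searchsorted([0.2, 0.6], clean)  # 0/1/2 regions
            model = swarm_segment(img, variant=variant, k=3,
                                  config=SwarmConfig(seed=seed, max_iter=60))
            if (model.labels == true_label).mean() >= 0.98:
                hits += 1
        assert hits >= 9

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            SwarmSegmenter(variant="abc").fit(np.zeros((4, 4)) + 0.5)
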