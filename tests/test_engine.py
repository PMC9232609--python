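import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permwalk.domain import DomainError, build_domain
from permwalk.engine import (
    SimConfig,
    WalkerEnsemble,
    compartment_fractions,
    density_histogram,
    run_simulation,
    seed_walkers,
    step_ensemble,
    transit_probability_hybrid,
    transit_probability_reference,
)


class TestTransitProbabilities:
    def test_reference_impermeable_and_limit(self):
        assert transit_probability_reference(0.5, 0.0, 1.0) == 0.0
        assert transit_probability_reference(0.5, 1e12, 1.0) == \
            pytest.approx(1.0, abs=1e-10)

    def test_reference_hand_value(self):
        dx = np.sqrt(2 * 0.5 * 1.5)
        p = transit_probability_reference(0.5, 0.05, dx)
        assert p == pytest.approx(2 * 0.05 * dx / (0.5 + 2 * 0.05 * dx))
        assert p == pytest.approx(0.1967, abs=2e-4)

    def test_reference_rejects_negative_distance(self):
        with pytest.raises(DomainError):
            transit_probability_reference(0.5, 0.05, -0.1)

    def test_hybrid_equals_reference_for_uniform_D(self):
        for dx in (0.1, 0.7, 2.0):
            assert transit_probability_hybrid(0.5, 0.5, 0.05, dx) == \
                transit_probability_reference(0.5, 0.05, dx)

    def test_hybrid_fast_to_slow_infinite_permeability(self):
        """κ → ∞ recovers the bare diffusivity-step acceptance
        sqrt(D_j/D_i)."""
        p = transit_probability_hybrid(2.5, 0.5, 1e12, 1.0)
        assert p == pytest.approx(np.sqrt(0.2), rel=1e-9)

    def test_hybrid_slow_to_fast_equals_membrane_only(self):
        for dx in (0.05, 1.2):
            assert transit_probability_hybrid(0.5, 2.5, 0.05, dx) == \
                transit_probability_reference(0.5, 0.05, dx)

    @given(Di=st.floats(0.1, 5.0), Dj=st.floats(0.1, 5.0),
           kappa=st.floats(0.0, 10.0), dx=st.floats(0.0, 3.0))
    @settings(max_examples=200, deadline=None)
    def test_probabilities_in_unit_interval(self, Di, Dj, kappa, dx):
        for p in (transit_probability_reference(Di, kappa, dx),
                  transit_probability_hybrid(Di, Dj, kappa, dx)):
            assert 0.0 <= p < 1.0 + 1e-15

    def test_hybrid_detailed_balance_integral(self):
        """At uniform density the κ-weighted crossing rates balance exactly:
        ∫ p(i→j) over incident positions equals ∫ p(j→i), for any κ and δt.
        (Integrals by fine quadrature, positions within one step of the
        membrane.)"""
        from scipy.integrate import quad
        Di, Dj, dt = 0.5, 2.5, 1.5
        for kappa in (0.01, 0.05, 0.5, 5.0, 1e6):
            si = np.sqrt(2 * Di * dt)
            sj = np.sqrt(2 * Dj * dt)
            lhs = quad(lambda x: transit_probability_hybrid(Di, Dj, kappa, x),
                       0, si)[0]
            rhs = quad(lambda x: transit_probability_hybrid(Dj, Di, kappa, x),
                       0, sj)[0]
            assert lhs == pytest.approx(rhs, rel=1e-8)


def _manual_ensemble(domain, positions):
    positions = np.asarray(positions, dtype=float)
    comp = np.asarray(domain.locate(positions), dtype=np.int64) - 1
    return WalkerEnsemble(positions.copy(), positions.copy(), comp, 0.0,
                          np.random.default_rng(0))


class TestStepMechanics:
    """Hand-traced single steps with injected random draws."""

    def test_free_step(self):
        dom = build_domain([20, 20], [0.5, 0.5], [0.05])
        ens = _manual_ensemble(dom, [5.0])
        cfg = SimConfig(dt=1.5, T=1.5, Np=1, model="hybrid")
        step_ensemble(ens, dom, cfg, signs=np.array([True]),
                      uniforms=np.array([0.999]))
        assert ens.positions[0] == pytest.approx(5.0 + np.sqrt(1.5))

    def test_reflection(self):
        # step 2 from x=19 toward barrier 20: δx_i = 1, δx_j = 1, rejected
        dom = build_domain([20, 20], [2.0 / 3, 2.0 / 3], [0.01])
        cfg = SimConfig(dt=3.0, T=3.0, Np=1, model="hybrid")  # step = 2.0
        ens = _manual_ensemble(dom, [19.0])
        lr, rl = step_ensemble(ens, dom, cfg, signs=np.array([True]),
                               uniforms=np.array([0.9999]))
        assert ens.positions[0] == pytest.approx(19.0)
        assert ens.compartment[0] == 0
        assert lr.sum() == 0

    def test_transmission_rescales_step(self):
        # accepted transit into 4x slower medium: remainder shrinks by 1/2
        Dl = 2.0 / 3
        dom = build_domain([20, 20], [Dl, Dl / 4], [50.0])
        cfg = SimConfig(dt=3.0, T=3.0, Np=1, model="hybrid")  # step = 2.0
        ens = _manual_ensemble(dom, [19.0])
        lr, rl = step_ensemble(ens, dom, cfg, signs=np.array([True]),
                               uniforms=np.array([1e-12]))
        assert ens.positions[0] == pytest.approx(20.0 + 1.0 * 0.5)
        assert ens.compartment[0] == 1
        assert lr[1] == 1 and rl[1] == 0

    def test_end_barriers_always_reflect(self):
        dom = build_domain([20, 20], [0.5, 0.5], [0.05])
        cfg = SimConfig(dt=1.5, T=1.5, Np=1)
        ens = _manual_ensemble(dom, [0.5])
        step_ensemble(ens, dom, cfg, signs=np.array([False]),
                      uniforms=np.array([1e-12]))
        # δx_i = 0.5, δx_j = sqrt(1.5) - 0.5, reflected to 0 + δx_j
        assert ens.positions[0] == pytest.approx(np.sqrt(1.5) - 0.5)
        assert ens.compartment[0] == 0


class TestSeeding:
    def test_delta(self, benchmark_domain, rng):
        pos = seed_walkers(("delta", 24.75), 3,
                           build_domain([49.5], [1.0], []), rng)
        np.testing.assert_allclose(pos, 24.75)

    def test_interval(self, benchmark_domain, rng):
        pos = seed_walkers(("uniform", (6.0, 14.0)), 5000, benchmark_domain,
                           rng)
        assert pos.min() >= 6.0 and pos.max() <= 14.0

    def test_uniform_full_moments(self, benchmark_domain, rng):
        Np = 40_000
        pos = seed_walkers(("uniform", None), Np, benchmark_domain, rng)
        se = (40 / np.sqrt(12)) / np.sqrt(Np)
        assert abs(pos.mean() - 20.0) < 3 * se

    def test_out_of_domain_interval(self, benchmark_domain, rng):
        with pytest.raises(DomainError):
            seed_walkers(("uniform", (-1.0, 10.0)), 10, benchmark_domain, rng)


class TestDensityHistogram:
    def test_single_bin_mass(self, benchmark_domain):
        pos = np.full(1000, 3.0)
        centers, rho = density_histogram(pos, 2.0, benchmark_domain)
        assert rho[1] == pytest.approx(0.5)
        assert np.sum(rho > 0) == 1

    def test_normalization(self, benchmark_domain, rng):
        pos = rng.uniform(0, 40, 5000)
        centers, rho = density_histogram(pos, 1.0, benchmark_domain)
        assert np.sum(rho * 1.0) == pytest.approx(1.0)


class TestSimulation:
    def test_impermeable_membrane_no_crossings(self):
        dom = build_domain([20, 20], [0.5, 2.5], [0.0])
        cfg = SimConfig(dt=1.5, T=150, Np=2000, seed=2, record_flux=True,
                        seeding=("uniform", (0.0, 20.0)))
        res = run_simulation(dom, cfg)
        assert res.ledger.count_lr.sum() == 0
        assert res.ledger.count_rl.sum() == 0
        assert res.ensemble.positions.max() < 20.0

    def test_walkers_stay_in_domain(self, benchmark_domain):
        cfg = SimConfig(dt=10.0, T=2000, Np=5000, seed=3, model="reference")
        res = run_simulation(benchmark_domain, cfg)
        assert res.ensemble.positions.size == 5000
        assert res.ensemble.positions.min() >= 0.0
        assert res.ensemble.positions.max() <= 40.0

    def test_models_identical_for_uniform_diffusivity(self):
        dom = build_domain([20, 20], [1.2, 1.2], [0.3])
        kw = dict(dt=2.0, T=200, Np=4000, seed=9, record_flux=True)
        ref = run_simulation(dom, SimConfig(model="reference", **kw))
        hyb = run_simulation(dom, SimConfig(model="hybrid", **kw))
        np.testing.assert_array_equal(ref.ensemble.positions,
                                      hyb.ensemble.positions)
        np.testing.assert_array_equal(ref.ledger.count_lr,
                                      hyb.ledger.count_lr)

    def test_numpy_and_numba_kernels_bit_identical(self, benchmark_domain):
        kw = dict(dt=1.5, T=75, Np=3000, seed=4, model="hybrid",
                  seeding=("delta", 10.0), record_flux=True)
        a = run_simulation(benchmark_domain, SimConfig(kernel="numba", **kw))
        b = run_simulation(benchmark_domain, SimConfig(kernel="numpy", **kw))
        np.testing.assert_array_equal(a.ensemble.positions,
                                      b.ensemble.positions)
        np.testing.assert_array_equal(a.ensemble.compartment,
                                      b.ensemble.compartment)
        np.testing.assert_array_equal(a.ledger.count_rl, b.ledger.count_rl)

    def test_free_diffusion_displacement_variance(self):
        dom = build_domain([4000.0], [1.0], [])
        cfg = SimConfig(dt=1.0, T=100, Np=400_000, seed=6,
                        seeding=("delta", 2000.0))
        res = run_simulation(dom, cfg)
        disp = res.ensemble.positions - res.ensemble.initial_positions
        assert disp.var() == pytest.approx(2 * 1.0 * 100, rel=0.01)

    def test_hybrid_detailed_balance_at_equilibrium(self, benchmark_domain):
        cfg = SimConfig(dt=1.5, T=300, Np=200_000, seed=8, model="hybrid",
                        record_flux=True)
        res = run_simulation(benchmark_domain, cfg)
        lr = res.ledger.count_lr[:, 1].sum()
        rl = res.ledger.count_rl[:, 1].sum()
        mean = 0.5 * (lr + rl)
        assert abs(lr - rl) < 3 * np.sqrt(2 * mean)

    def test_rejects_oversized_step(self, benchmark_domain):
        with pytest.raises(DomainError, match="dt"):
            run_simulation(benchmark_domain,
                           SimConfig(dt=100.0, T=200.0, Np=10))

    def test_snapshot_times(self, benchmark_domain):
        cfg = SimConfig(dt=1.5, T=15, Np=100, seed=1,
                        snapshot_times=(3.0, 15.0))
        res = run_simulation(benchmark_domain, cfg)
        assert set(res.snapshots) == {3.0, 15.0}
        np.testing.assert_array_equal(res.snapshots[15.0],
                                      res.ensemble.positions)
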