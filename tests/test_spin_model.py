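import math

import numpy as np
import pytest
from scipy.linalg import expm as scipy_expm

from hybridqmt.lineshape import get_default_interpolator
from hybridqmt.spin_model import (QMTParams, RFPulse, SequenceSchedule,
                                  cycle_propagator, cyclic_steady_state,
                                  default_schedule, equilibrium_state,
                                  evolution_matrix, expm_batch, propagate,
                                  simulate_fingerprint, single_pool_fingerprint)

from _oracles import bloch_mcconnell_rhs, rk4_propagate


def random_params(rng):
    return QMTParams(m0s=rng.uniform(0.05, 0.35), R1f=rng.uniform(0.3, 2.0),
                     R2f=rng.uniform(5, 25), Rx=rng.uniform(5, 100),
                     R1s=rng.uniform(0.2, 5), T2s=rng.uniform(5e-6, 20e-6))


class TestEvolutionMatrix:
    def test_equilibrium_is_null_vector(self, midrange_params):
        A = evolution_matrix(midrange_params, None, 0.0, None)
        assert np.max(np.abs(A @ equilibrium_state(midrange_params))) < 1e-14

    def test_decoupled_zf_row_is_T1_recovery(self):
        p = QMTParams(m0s=0.2, R1f=0.7, R2f=15, Rx=1e-9, R1s=2, T2s=10e-6)
        A = evolution_matrix(p, None, 0.0, None)
        s = np.array([0.0, 0.0, 0.3, 0.0, 0.0, 1.0])
        dzf = (A @ s)[2]
        assert dzf == pytest.approx(-p.R1f * 0.3 + p.m0f * p.R1f, rel=1e-6)

    def test_matvec_matches_componentwise_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = random_params(rng)
            wy, wz, r2s = rng.uniform(0, 2e4), rng.uniform(-100, 100), rng.uniform(1e4, 2e5)
            A = evolution_matrix(p, RFPulse(alpha=wy * 1e-4, TRF=1e-4), wz, r2s)
            s = np.append(rng.standard_normal(5), 1.0)
            rhs = bloch_mcconnell_rhs(s, p, wy, wz, r2s)
            scale = max(np.max(np.abs(rhs)), 1.0)
            assert np.max(np.abs(A @ s - rhs)) / scale < 1e-14


class TestPropagate:
    def test_zero_duration_is_identity(self, midrange_params):
        A = evolution_matrix(midrange_params, None, 0.0, None)
        s = np.array([0.1, 0.0, 0.4, 0.0, 0.1, 1.0])
        assert np.array_equal(propagate(s, A, 0.0), s)

    def test_closed_form_inversion_recovery(self):
        # decoupled free pool from zf(0) = -m0f: zf(t) = m0f (1 - 2 e^{-R1f t})
        p = QMTParams(m0s=0.2, R1f=0.8, R2f=15, Rx=1e-12, R1s=2, T2s=10e-6)
        A = evolution_matrix(p, None, 0.0, None)
        s0 = np.array([0.0, 0.0, -p.m0f, 0.0, p.m0s, 1.0])
        for t in (0.05, 0.3, 1.0):
            zf = propagate(s0, A, t)[2]
            assert zf == pytest.approx(p.m0f * (1 - 2 * math.exp(-p.R1f * t)), abs=1e-10)

    def test_matches_rk4_oracle(self):
        rng = np.random.default_rng(21)
        p = random_params(rng)
        A = evolution_matrix(p, RFPulse(alpha=1.2, TRF=5e-4), 30.0, 2e4)
        s0 = np.append(0.3 * rng.standard_normal(5), 1.0)
        t = 5e-4
        assert np.max(np.abs(propagate(s0, A, t)
                             - rk4_propagate(s0, A, t, n_steps=20_000))) < 1e-8

    def test_propagator_composition(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            p = random_params(rng)
            A = evolution_matrix(p, None, 10.0, None)
            a, b = rng.uniform(1e-4, 1e-2, 2)
            lhs = expm_batch(A * (a + b))
            rhs = expm_batch(A * a) @ expm_batch(A * b)
            assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_exchange_conserves_total_z_without_relaxation(self):
        p = QMTParams(m0s=0.3, R1f=1e-14, R2f=15, Rx=50, R1s=1e-14, T2s=10e-6)
        A = evolution_matrix(p, None, 0.0, None)
        s0 = np.array([0.0, 0.0, 0.5, 0.0, 0.05, 1.0])
        for t in (1e-3, 0.02, 0.1):
            s = propagate(s0, A, t)
            assert s[2] + s[4] == pytest.approx(0.55, abs=1e-12)


class TestExpmBatch:
    def test_matches_scipy_on_random_stacks(self):
        rng = np.random.default_rng(41)
        mats = rng.standard_normal((8, 6, 6)) * rng.uniform(0.1, 50)
        out = expm_batch(mats)
        for i in range(8):
            assert np.allclose(out[i], scipy_expm(mats[i]), atol=1e-10 * np.abs(
                scipy_expm(mats[i])).max() + 1e-12)


class TestCyclicSteadyState:
    def test_relaxation_dominated_limit_is_equilibrium(self, midrange_params):
        sched = SequenceSchedule(alpha=[0.0], TRF=[1e-4], TR=[50.0], inversion=None)
        css = cyclic_steady_state(midrange_params, sched)
        assert np.max(np.abs(css - equilibrium_state(midrange_params))) < 1e-8

    def test_fixed_point_equals_power_iteration(self, midrange_params, schedule):
        css = cyclic_steady_state(midrange_params, schedule)
        P = cycle_propagator(midrange_params, schedule)
        s = equilibrium_state(midrange_params)
        for _ in range(60):
            s = P @ s
        assert np.max(np.abs(css - s)) < 1e-9

    def test_equilibrium_preserved_through_idle_cycle(self, midrange_params):
        sched = SequenceSchedule(alpha=np.zeros(20), TRF=np.full(20, 1e-4),
                                 TR=np.full(20, 0.01), inversion=None)
        P = cycle_propagator(midrange_params, sched)
        eq = equilibrium_state(midrange_params)
        assert np.max(np.abs(P @ eq - eq)) < 1e-12


class TestFingerprint:
    def test_bounded_by_free_pool_size(self, midrange_params, schedule):
        fp = simulate_fingerprint(midrange_params, schedule)
        assert np.all(np.abs(fp) <= midrange_params.m0f + 1e-9)
        assert len(fp) == schedule.n_reps

    def test_vanishing_semisolid_matches_single_pool(self, schedule):
        p = QMTParams(m0s=1e-6, R1f=0.5, R2f=15, Rx=40, R1s=2.5, T2s=10e-6)
        fp = simulate_fingerprint(p, schedule)
        sp = single_pool_fingerprint(0.5, 15.0, schedule)
        assert np.max(np.abs(fp - sp)) < 1e-4

    def test_continuity_under_small_perturbation(self, midrange_params, schedule):
        fp0 = simulate_fingerprint(midrange_params, schedule)
        x = midrange_params.as_array() * 1.01
        fp1 = simulate_fingerprint(QMTParams.from_array(x), schedule)
        rel = np.linalg.norm(fp1 - fp0) / np.linalg.norm(fp0)
        assert 0 < rel < 0.5  # smooth response, no chaotic jump

    def test_interp_and_exact_rates_agree(self, midrange_params, schedule):
        a = simulate_fingerprint(midrange_params, schedule, r2sl="interp")
        b = simulate_fingerprint(midrange_params, schedule, r2sl="exact")
        assert np.max(np.abs(a - b)) < 1e-6


class TestDefaultSchedule:
    def test_deterministic(self):
        s1 = default_schedule(n_reps=50, seed=9)
        s2 = default_schedule(n_reps=50, seed=9)
        assert np.array_equal(s1.alpha, s2.alpha) and np.array_equal(s1.TRF, s2.TRF)

    def test_bookkeeping(self):
        s = default_schedule(n_reps=100, cycle_s=3.5)
        assert s.n_reps == 100
        assert s.cycle_duration == pytest.approx(3.5, rel=1e-12)

    def test_smooth_flip_train(self):
        s = default_schedule(n_reps=200)
        assert np.max(np.abs(np.diff(s.alpha))) < math.radians(5)

    def test_fisher_information_full_rank(self, midrange_params, schedule):
        # numerical Jacobian of the fingerprint wrt the six log-parameters
        x0 = midrange_params.as_array()
        f0 = simulate_fingerprint(midrange_params, schedule)
        J = np.empty((2 * len(f0), 6))
        for j in range(6):
            dx = np.zeros(6)
            dx[j] = 1e-6 * x0[j]
            f1 = simulate_fingerprint(QMTParams.from_array(x0 + dx), schedule)
            d = (f1 - f0) / 1e-6  # relative sensitivity df/dlog(x_j)
            J[:, j] = np.concatenate([d.real, d.imag])
        s = np.linalg.svd(J, compute_uv=False)
        assert s[5] / s[0] > 1e-6  # all six parameters encoded

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            default_schedule(n_reps=5)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        QMTParams(m0s=1.2, R1f=0.5, R2f=15, Rx=40, R1s=2.5, T2s=10e-6)
    with pytest.raises(ValueError):
        QMTParams(m0s=0.1, R1f=0.5, R2f=15, Rx=40, R1s=2.5, T2s=0.1)  # T2s > T2f
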