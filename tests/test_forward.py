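import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from genembed.design import build_nback_design, design_from_events
from genembed.forward import (
    DivergenceError,
    integrate_bold,
    integrate_neuronal,
    neuronal_derivative,
    simulate_subject,
    stability_check,
)
from genembed.network import (
    BoldRecord,
    HemodynamicParams,
    NeuronalParams,
    default_hemodynamics,
)

KAPPA, GAMMA, TAU, ALPHA, RHO = 0.64, 0.32, 2.0, 0.32, 0.32


def _toy_params(A=None, B=None, C=None):
    A = np.array([[-1.0, 0.0], [0.0, -1.0]]) if A is None else A
    B = [np.zeros((2, 2))] if B is None else B
    C = np.zeros((2, 1)) if C is None else C
    return NeuronalParams(A=A, B=B, C=C)


class TestStability:
    def test_negative_identity_stable(self):
        assert stability_check(-np.eye(3))

    def test_positive_identity_unstable(self):
        assert not stability_check(np.eye(3))

    def test_cluster_profiles_stable(self, table1, spec):
        for prof in table1.clusters:
            A = NeuronalParams.from_vector(prof.mean, spec).A
            assert stability_check(A)


class TestNeuronalDerivative:
    def test_zero_fixed_point(self):
        p = _toy_params()
        assert np.allclose(neuronal_derivative(np.zeros(2), np.zeros(1), p), 0)

    def test_identity_decay(self):
        p = _toy_params()
        x0 = np.array([1.5, -0.3])
        assert np.allclose(neuronal_derivative(x0, np.array([0.7]), p), -x0)

    def test_three_region_hand_expansion(self, spec, cluster2_params):
        p = cluster2_params
        x = np.array([0.1, -0.2, 0.3])
        u = np.array([1.0, 1.0])
        got = neuronal_derivative(x, u, p)
        # element-wise expansion of (A + u2*B_wm) x + C u done by hand
        expected = np.empty(3)
        for t in range(3):
            acc = 0.0
            for s in range(3):
                acc += (p.A[t, s] + u[1] * p.B[1][t, s]) * x[s]
            acc += p.C[t, 0] * u[0] + p.C[t, 1] * u[1]
            expected[t] = acc
        assert np.allclose(got, expected, atol=1e-14)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            neuronal_derivative(np.zeros(3), np.zeros(1), _toy_params())


class TestIntegrateNeuronal:
    def test_zero_input_zero_state(self, tiny_design, cluster2_params):
        import dataclasses

        quiet = dataclasses.replace(tiny_design, u=np.zeros_like(tiny_design.u))
        traj = integrate_neuronal(cluster2_params, quiet)
        assert np.all(traj == 0)

    def test_scalar_exponential_decay(self):
        d = design_from_events([("u", 0.0, 0.0, 0.0)], TR=1.0, n_scans=5,
                               micro_dt=0.05, input_names=["u"])
        p = NeuronalParams(A=-np.eye(3), B=[np.zeros((3, 3))], C=np.zeros((3, 1)))
        traj = integrate_neuronal(p, d, x0=np.array([1.0, 0.0, 0.0]))
        t = np.arange(d.n_micro + 1) * d.micro_dt
        assert np.allclose(traj[0], np.exp(-t), atol=1e-8)
        assert np.all(traj[1:] == 0)

    def test_matches_adaptive_reference(self, cluster2_params):
        p = cluster2_params
        d = build_nback_design(1, 4, 500, 900, 8.0, 2.0, 0.0125)
        traj = integrate_neuronal(p, d)

        grid = np.arange(d.n_micro) * d.micro_dt

        def rhs(t, x):
            i = min(int(t / d.micro_dt), d.n_micro - 1)
            u = d.u[:, i]
            return (p.A + u[1] * p.B[1]) @ x + p.C @ u

        # integrate piecewise between input switches to keep the reference exact
        switches = np.flatnonzero(np.any(np.diff(d.u, axis=1) != 0, axis=0)) + 1
        times = np.concatenate([[0], switches * d.micro_dt, [d.n_micro * d.micro_dt]])
        x = np.zeros(3)
        for a, b in zip(times[:-1], times[1:]):
            sol = solve_ivp(rhs, (a, b), x, rtol=1e-11, atol=1e-13,
                            t_eval=[b], max_step=(b - a))
            x = sol.y[:, -1]
        scale = np.abs(x).max()
        assert np.abs(traj[:, -1] - x).max() / scale < 1e-6

    def test_unstable_requires_override(self, tiny_design):
        p = NeuronalParams.__new__(NeuronalParams)
        p.A = np.array([[0.5]])
        p.B = [np.zeros((1, 1))]
        p.C = np.ones((1, 1))
        p.spec = None
        with pytest.raises(ValueError, match="unstable"):
            integrate_neuronal(p, tiny_design)

    def test_superposition_when_linear(self, spec, tiny_design):
        base = NeuronalParams(
            A=np.array([[-1.0, 0.0, 0.0], [0.1, -1.0, 0.0], [0.1, 0.0, -1.0]]),
            B=[np.zeros((3, 3)), np.zeros((3, 3))],
            C=np.array([[0.1, 0.0], [0.0, 0.0], [0.0, 0.0]]),
        )
        double = NeuronalParams(A=base.A, B=base.B, C=2 * base.C)
        t1 = integrate_neuronal(base, tiny_design)
        t2 = integrate_neuronal(double, tiny_design)
        assert np.allclose(t2, 2 * t1, atol=1e-12)


class TestIntegrateBold:
    def test_resting_state_exact_fixed_point(self, tiny_design, hemo):
        traj = np.zeros((3, tiny_design.n_micro + 1))
        rec = integrate_bold(traj, hemo, tiny_design)
        assert np.all(rec.y == 0)

    def test_constant_activity_steady_state(self, hemo):
        c = 0.05
        d = design_from_events([("u", 0.0, 0.0, 0.0)], TR=2.0, n_scans=120,
                               micro_dt=0.125, input_names=["u"])
        traj = np.full((1, d.n_micro + 1), c)
        one = HemodynamicParams(
            signal_decay=[KAPPA], autoregulation=[GAMMA], transit_time=[TAU],
            stiffness=[ALPHA], oxygen_extraction=[RHO],
        )
        rec = integrate_bold(traj, one, d)
        # equilibrium: s=0, f = 1 + c/gamma, v = f**alpha, q from outflow balance
        f = 1 + c / GAMMA
        v = f ** ALPHA
        q = f * (1 - (1 - RHO) ** (1 / f)) / RHO * v / (v ** (1 / ALPHA))
        k1, k2, k3 = 7 * RHO, 2.0, 2 * RHO - 0.2
        y_eq = 100 * 0.02 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))
        assert rec.y[-1, 0] == pytest.approx(y_eq, rel=1e-5)

    def test_matches_adaptive_reference(self, cluster2_params, hemo):
        p = cluster2_params
        d = build_nback_design(1, 4, 500, 900, 8.0, 2.0, 0.0125)
        traj = integrate_neuronal(p, d)
        rec = integrate_bold(traj, hemo, d)

        from scipy.interpolate import CubicSpline

        grid = np.arange(d.n_micro + 1) * d.micro_dt
        spline = CubicSpline(grid, traj, axis=1)

        def rhs(t, state):
            s, f, v, q = state.reshape(4, 3)
            x = spline(t)
            fv = v ** (1 / ALPHA)
            ds = x - KAPPA * s - GAMMA * (f - 1)
            df = s
            dv = (f - fv) / TAU
            dq = (f * (1 - (1 - RHO) ** (1 / f)) / RHO - fv * q / v) / TAU
            return np.concatenate([ds, df, dv, dq])

        y0 = np.concatenate([np.zeros(3), np.ones(9)])
        t_scans = d.scan_sample_indices * d.micro_dt
        sol = solve_ivp(rhs, (0, grid[-1]), y0, rtol=1e-11, atol=1e-13,
                        t_eval=t_scans)
        v = sol.y[6:9]
        q = sol.y[9:12]
        k1, k2, k3 = 7 * RHO, 2.0, 2 * RHO - 0.2
        ref = 100 * 0.02 * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))
        scale = np.abs(ref).max()
        assert np.abs(rec.y - ref.T).max() / scale < 1e-6


class TestSimulateSubject:
    def test_zero_noise_equals_deterministic_path(self, cluster2_params, hemo,
                                                  tiny_design):
        a = simulate_subject(cluster2_params, hemo, tiny_design, noise_sd=0.0)
        traj = integrate_neuronal(cluster2_params, tiny_design)
        b = integrate_bold(traj, hemo, tiny_design)
        assert np.array_equal(a.y, b.y)

    def test_seed_reproducibility(self, cluster2_params, hemo, tiny_design):
        a = simulate_subject(cluster2_params, hemo, tiny_design, 0.3, seed=7)
        b = simulate_subject(cluster2_params, hemo, tiny_design, 0.3, seed=7)
        c = simulate_subject(cluster2_params, hemo, tiny_design, 0.3, seed=8)
        assert np.array_equal(a.y, b.y)
        assert not np.array_equal(a.y, c.y)

    def test_noise_sd_law_of_large_numbers(self, hemo):
        # resting design sampled at every micro step: noise dominates exactly
        d = design_from_events([("u", 0.0, 0.0, 0.0)], TR=2.0, n_scans=10_000,
                               micro_dt=2.0, input_names=["u"])
        p = NeuronalParams(A=-np.eye(3), B=[np.zeros((3, 3))], C=np.zeros((3, 1)))
        rec = simulate_subject(p, hemo, d, noise_sd=0.5, seed=0)
        assert rec.y.std() == pytest.approx(0.5, rel=0.02)

    def test_negative_noise_rejected(self, cluster2_params, hemo, tiny_design):
        with pytest.raises(ValueError):
            simulate_subject(cluster2_params, hemo, tiny_design, noise_sd=-0.1)


class TestIntegratorProperties:
    def test_halving_micro_dt_converged(self, cluster2_params, hemo):
        # event durations are multiples of both step sizes, so the realised
        # stimulus train is identical and only integration error remains;
        # 1e-3 (percent-signal units) is the declared integrator tolerance
        recs = []
        for dt in (0.2, 0.1):
            d = build_nback_design(1, 4, 600, 800, 8.0, 2.0, dt)
            recs.append(simulate_subject(cluster2_params, hemo, d, 0.0).y)
        assert np.abs(recs[0] - recs[1]).max() < 1e-3

    def test_region_permutation_consistency(self, spec, cluster2_params, hemo,
                                            tiny_design):
        p = cluster2_params
        perm = [2, 0, 1]
        P = np.eye(3)[perm]
        permuted = NeuronalParams(
            A=P @ p.A @ P.T, B=[P @ b @ P.T for b in p.B], C=P @ p.C
        )
        a = simulate_subject(p, hemo, tiny_design, 0.0)
        b = simulate_subject(permuted, hemo, tiny_design, 0.0)
        assert np.allclose(b.y, a.y[:, perm], atol=1e-12)
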