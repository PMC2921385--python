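"""Analysis machinery: maxima, stability, continuation, oscillations, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import root as scipy_root

from reflectedflow import (
    AuxinTransportParams,
    Profile1D,
    compare_profile,
    coordinate_descent_fit,
    count_solutions_at,
    detect_oscillation,
    find_maxima,
    perturbation_tolerance,
    stability,
    zero_profile,
)
from reflectedflow.analysis import (
    ContinuationBranch,
    _continue_arclength,
    continue_branch,
    oscillation_metrics,
)
from reflectedflow.minimal1d import jacobian_1d, rhs_flat_1d, steady_state_1d
from reflectedflow.params import load_reference_profile


def brute_force_maxima(a, eps):
    """Definition-checking oracle for find_maxima (exhaustive scan)."""
    a = np.asarray(a, dtype=float)
    n = a.size
    out = []
    for i in range(n):
        if i > 0 and a[i - 1] > a[i]:
            continue
        if i + 1 < n and a[i + 1] > a[i]:
            continue
        if i > 0 and a[i - 1] == a[i]:
            continue  # plateau: only the first index reports
        j = i
        while j + 1 < n and a[j + 1] == a[i]:
            j += 1
        if j + 1 < n and a[j + 1] > a[i]:
            continue
        if i == 0 and j == n - 1:
            continue
        mins = []
        if i > 0:
            k = i - 1
            m = a[i]
            while k >= 0 and a[k] <= a[i]:
                m = min(m, a[k])
                k -= 1
            mins.append(m)
        if j < n - 1:
            k = j + 1
            m = a[i]
            while k < n and a[k] <= a[i]:
                m = min(m, a[k])
                k += 1
            mins.append(m)
        if a[i] - max(mins) >= eps:
            out.append(i + 1)
    return out


class TestFindMaxima:
    @pytest.mark.parametrize(
        "profile,eps,expected",
        [
            ([1, 2, 3, 2, 1], 0.1, [3]),
            ([2, 2, 2, 2], 0.0, []),
            ([1, 5, 1, 4, 1], 0.1, [2, 4]),
            ([5, 1, 1, 1], 0.1, [1]),
            ([1, 2, 3, 4, 5], 0.1, [5]),
            ([1, 3, 3, 2, 4, 1], 0.0, [2, 5]),
            ([1, 5, 1, 4, 1], 2.0, [2, 4]),
            ([1, 5, 3, 4, 1], 2.0, [2]),
        ],
    )
    def test_examples(self, profile, eps, expected):
        assert find_maxima(profile, eps) == expected

    @given(
        a=st.lists(st.integers(0, 8).map(float), min_size=2, max_size=20),
        eps=st.sampled_from([0.0, 0.5, 1.5]),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_exhaustive_definition(self, a, eps):
        assert find_maxima(a, eps) == brute_force_maxima(a, eps)

    def test_rejects_negative_prominence(self):
        with pytest.raises(ValueError):
            find_maxima([1, 2, 1], -0.1)


class TestStability:
    def test_decoupled_decay_leading_eigenvalue(self):
        # no transport, no influx: a* = 0, PIN* = 0; the auxin block is
        # -Kd I and the PIN block -k2 I, so with Kd < k2 the leading
        # eigenvalue is exactly -Kd
        p = AuxinTransportParams(alpha=0.0, Kd=0.05, D=0.0, K0=0.0, k1=1.0,
                                 q1=0.1, q2=1.0, h1=1.0, k2=0.2, q3=2.0, h2=6.0)
        prof = zero_profile(6)
        assert stability(p, prof) == pytest.approx(-p.Kd, abs=1e-12)

    def test_basic_pattern_is_stable(self, basic_auxin, basic_steady50):
        lam = stability(basic_auxin, basic_steady50.profile)
        assert lam < 0

    def test_rejects_non_stationary_state(self, basic_auxin):
        with pytest.raises(ValueError):
            stability(basic_auxin, Profile1D(np.ones(10), np.ones(10)))

    def test_flagged_stable_state_attracts(self, basic_auxin, basic_steady50):
        from reflectedflow.minimal1d import integrate_1d, perturb_cell

        pert = perturb_cell(basic_steady50.profile, 25, 0.1)
        traj = integrate_1d(pert, basic_auxin, 1500.0)
        assert np.abs(traj.final.a - basic_steady50.profile.a).max() < 1e-3


class TestContinuation:
    def test_linear_system_branch_recovered_exactly(self):
        """On a linear system F = A y - b*lam the stationary branch is the
        closed-form line y(lam) = lam * A^-1 b; the arclength engine must
        retrace it to solver precision."""
        A = np.array([[-2.0, 1.0], [0.5, -3.0]])
        b = np.array([1.0, 2.0])
        F = lambda y, lam: A @ y - b * lam
        J = lambda y, lam: A
        y0 = np.zeros(2)
        vals, ys, folds, diag = _continue_arclength(
            F, J, y0, 0.0, 2.0, ds0=0.1, ds_max=0.5, max_points=500
        )
        assert folds == []
        sol = np.linalg.solve(A, b)
        for lam, y in zip(vals, ys):
            assert y == pytest.approx(lam * sol, abs=1e-8)
        assert max(vals) > 1.9

    def test_small_system_branch_matches_multistart(self, basic_auxin):
        """N=4 basic set: the stationary solutions the branch crosses at
        alpha=1 coincide with reduced-system multistart Newton roots."""
        p = basic_auxin
        N = 4

        def pin_of_a(a):
            x = a**p.h1
            syn = p.k1 * x * x / ((p.q1**p.h1 + x) * (p.q2**p.h1 + x))
            return syn / (p.k2 * (1.0 + (a / p.q3) ** p.h2))

        def G(a):
            PIN = pin_of_a(np.maximum(a, 0))
            da = -p.Kd * a
            da[-1] += p.alpha
            fl = p.D * np.diff(a)
            da[:-1] += fl
            da[1:] -= fl
            pm = p.K0 * PIN[1:] * np.maximum(a[1:], 0)
            da[:-1] += pm
            da[1:] -= pm
            return da

        rng = np.random.default_rng(7)
        oracle = []
        for _ in range(1000):
            s = scipy_root(G, rng.uniform(0.01, 25.0, N), method="hybr")
            if s.success and np.max(np.abs(G(s.x))) < 1e-10 and s.x.min() > 0:
                if not any(np.allclose(s.x, u, rtol=1e-5) for u in oracle):
                    oracle.append(s.x)
        assert oracle

        br = continue_branch(p, "alpha", (0.01, 1.5), N=N, ds0=0.05,
                             ds_max=0.3, state_scale=5.0, max_points=3000)
        vals = np.array(br.values)
        crossing_solutions = []
        for i in range(len(vals) - 1):
            if (vals[i] - 1.0) * (vals[i + 1] - 1.0) <= 0:
                y0 = 0.5 * (br.states[i].pack() + br.states[i + 1].pack())
                s = scipy_root(lambda y: rhs_flat_1d(y, p), y0,
                               jac=lambda y: jacobian_1d(y, p), method="hybr")
                if (s.success and np.max(np.abs(rhs_flat_1d(s.x, p))) < 1e-9
                        and s.x.min() > -1e-9):
                    if not any(np.allclose(s.x, u, rtol=1e-5)
                               for u in crossing_solutions):
                        crossing_solutions.append(s.x)
        assert crossing_solutions
        # every continuation-derived solution appears in the multistart set,
        # and the counts agree (set equivalence to 1e-6)
        for c in crossing_solutions:
            assert any(np.allclose(c[:N], u, rtol=1e-5, atol=1e-6) for u in oracle)
        assert len(crossing_solutions) == len(oracle)

    def test_count_crossings_geometry(self):
        mono = ContinuationBranch("alpha", values=[0.0, 0.5, 1.5, 2.0])
        assert count_solutions_at(mono, 1.0) == 1
        s_curve = ContinuationBranch("alpha", values=[0.0, 1.2, 0.8, 2.0])
        assert count_solutions_at(s_curve, 1.0) == 3


class TestOscillation:
    def test_sinusoid_period_recovered(self):
        t = np.linspace(0.0, 100.0, 4000)
        amp, period = oscillation_metrics(t, 2.0 + 0.7 * np.sin(2 * np.pi * t / 12.5))
        assert amp == pytest.approx(1.4, rel=0.01)
        assert period == pytest.approx(12.5, rel=0.01)

    def test_stable_pattern_is_quiescent(self, basic_auxin, basic_steady50):
        rep = detect_oscillation(basic_auxin, basic_steady50.profile,
                                 t_transient=50.0, t_measure=300.0)
        assert not rep.oscillating
        assert rep.amplitudes.max() < 1e-3

    def test_supercritical_influx_oscillates_mid_root(self, basic_auxin):
        """Above the critical influx the stationary pattern gives way to
        sustained oscillations with the high-amplitude zone in the middle
        of the file."""
        rep = detect_oscillation(basic_auxin.replace(alpha=1.3),
                                 zero_profile(50), t_transient=1500.0,
                                 t_measure=1500.0)
        assert rep.oscillating
        cell = int(np.argmax(rep.amplitudes)) + 1
        assert 8 <= cell <= 42
        assert rep.period is not None and 5.0 < rep.period < 200.0


class TestPerturbationTolerance:
    def test_sentinel_when_grid_exhausted(self, basic_auxin, basic_steady50):
        thr = perturbation_tolerance(basic_auxin, basic_steady50.profile,
                                     basic_steady50.profile.max_cell(),
                                     grid_max=0.5, t_relax=500.0)
        assert thr == np.inf

    def test_bisection_agrees_with_fine_scan(self):
        """Small-file case: the bisection threshold brackets the first
        maximum-shifting bolus found by an independent fine-grid scan."""
        p = AuxinTransportParams(alpha=0.5, Kd=0.05, D=0.5, K0=0.1, k1=1.0,
                                 q1=0.1, q2=1.0, h1=1.0, k2=0.02, q3=2.0,
                                 h2=6.0)
        base = steady_state_1d(p, N=10)
        assert base.converged
        cell = base.profile.max_cell()
        thr = perturbation_tolerance(p, base.profile, cell, grid_max=6.0,
                                     grid_step=0.5, refine_step=0.1,
                                     t_relax=1500.0)

        from reflectedflow.minimal1d import integrate_1d, perturb_cell

        def shifted(delta):
            pert = perturb_cell(base.profile, cell, delta)
            relaxed = integrate_1d(pert, p, 1500.0).final
            res = steady_state_1d(p, relaxed, t_relax=1500.0)
            return (not res.converged) or res.profile.max_cell() != base.profile.max_cell()

        if np.isfinite(thr):
            scan = next((d for d in np.arange(0.1, 6.01, 0.1) if shifted(d)), None)
            assert scan is not None
            assert abs(thr - scan) <= 0.2
        else:
            assert all(not shifted(d) for d in np.arange(0.5, 6.01, 0.5))


class TestProfileComparison:
    def test_exact_affine_copy_has_zero_rmse(self, basic_steady50):
        model = basic_steady50.profile.a
        ref = 3.0 * model + 2.0
        rmse, scale, offset = compare_profile(model, ref)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert scale == pytest.approx(3.0)
        assert offset == pytest.approx(2.0)

    def test_known_noise_level_recovered(self, basic_steady50, rng):
        model = basic_steady50.profile.a
        sigma = 0.3
        ref = 2.0 * model + 1.0 + rng.normal(0.0, sigma, model.size)
        rmse, _, _ = compare_profile(model, ref)
        assert rmse == pytest.approx(sigma, rel=0.35)

    def test_bundled_reference_profile_fits(self, basic_steady50):
        """The basic-set stationary profile matches the bundled (synthetic)
        digitized staining profile after affine scaling."""
        ref = load_reference_profile()
        rmse, scale, offset = compare_profile(basic_steady50.profile.a, ref)
        spread = ref[:, 1].max() - ref[:, 1].min()
        assert rmse < 0.08 * spread
        assert scale > 0
        assert offset >= 0


class TestCoordinateDescent:
    def test_separable_quadratic_exact_in_one_cycle(self):
        fn = lambda x: (x[0] - 1.5) ** 2 + (x[1] + 0.5) ** 2
        res = coordinate_descent_fit(fn, [0.0, 0.0], [(-5, 5), (-5, 5)], tol=1e-12)
        assert res.converged
        assert res.x == pytest.approx([1.5, -0.5], abs=1e-6)
        assert res.n_cycles <= 2

    def test_recovers_transport_parameters_from_profile(self, basic_auxin):
        """(Kd, K0) recovered to <5% from a synthetic stationary profile
        generated at known values, other parameters fixed."""
        true = basic_auxin.replace(Kd=0.02, K0=0.12)
        target = steady_state_1d(true, N=10).profile

        def objective(x):
            try:
                res = steady_state_1d(
                    basic_auxin.replace(Kd=x[0], K0=x[1]), init=target,
                    max_relax_rounds=1, t_relax=500.0,
                )
            except Exception:
                return 1e6
            if not res.converged:
                return 1e6
            return float(np.mean((res.profile.a - target.a) ** 2))

        fit = coordinate_descent_fit(objective, [0.03, 0.08],
                                     [(0.005, 0.08), (0.02, 0.4)], tol=1e-10,
                                     max_cycles=15)
        assert abs(fit.x[0] - 0.02) / 0.02 < 0.05
        assert abs(fit.x[1] - 0.12) / 0.12 < 0.05

    def test_nonidentifiable_product_reports_flat_direction(self):
        """An objective depending only on the product of two parameters has
        a flat valley: the fit must flag it instead of claiming convergence."""
        fn = lambda x: (x[0] * x[1] - 1.0) ** 2
        res = coordinate_descent_fit(fn, [0.5, 1.5], [(0.1, 10), (0.1, 10)],
                                     tol=1e-12)
        assert res.fun < 1e-10
        assert res.flat_directions
        assert not res.converged

    def test_rejects_non_finite_start(self):
        with pytest.raises(ValueError):
            coordinate_descent_fit(lambda x: np.nan, [0.0], [(-1, 1)])
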