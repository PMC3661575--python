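"""Equilibrium structure, bifurcation and viability classification."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from metabotaxis import (
    MetabolismParams,
    SystemState,
    bifurcation_point,
    bifurcation_scan,
    classify_state,
    equilibria,
    metabolic_rate,
)
from metabotaxis.metabolism import RegionLabel, _rate
from metabotaxis.simulate import integrate_batch


def random_params(rng, with_boundaries=True):
    kf, kb, kd = rng.uniform(0.1, 3.0, size=3)
    if with_boundaries:
        return MetabolismParams(kf, kb, kd, A_death_low=0.1, A_death_high=50.0)
    return MetabolismParams(kf, kb, kd)


class TestRate:
    def test_origin_is_always_an_equilibrium(self, params):
        for F in (0.0, 0.5, 2.0, 10.0):
            assert metabolic_rate(SystemState(0.0, F), params) == 0.0

    def test_zero_at_closed_form_roots(self, rng):
        for _ in range(200):
            p = random_params(rng)
            F_bif = bifurcation_point(p)
            F = rng.uniform(0.0, 3.0 * F_bif)
            for root in equilibria(F, p).roots:
                assert abs(metabolic_rate(SystemState(root, F), p)) < 1e-10

    def test_sign_structure_around_unstable_root(self, params):
        # growth above the separatrix, decay below it (bistable regime)
        F = 2.0
        eq = equilibria(F, params)
        delta = 1e-3
        above = metabolic_rate(SystemState(eq.unstable_root + delta, F), params)
        below = metabolic_rate(SystemState(eq.unstable_root - delta, F), params)
        assert above > 0 > below

    def test_rejects_invalid_states(self, params):
        with pytest.raises(ValueError):
            SystemState(-1.0, 1.0)
        with pytest.raises(ValueError):
            SystemState(float("nan"), 1.0)


class TestEquilibria:
    def test_no_positive_roots_without_resources(self, params):
        eq = equilibria(0.0, params)
        assert eq.roots == [0.0]

    def test_roots_match_numeric_root_finder(self, rng):
        # closed-form roots vs brentq on the raw rate law
        found = 0
        while found < 50:
            p = random_params(rng)
            F = rng.uniform(0.0, 3.0 * bifurcation_point(p))
            eq = equilibria(F, p)
            if eq.unstable_root is None or eq.stable_root - eq.unstable_root < 1e-3:
                continue
            found += 1
            f = lambda a: _rate(a, F, p)  # noqa: E731
            mid = 0.5 * (eq.unstable_root + eq.stable_root)
            lo = brentq(f, 1e-12, mid, xtol=1e-14)
            hi = brentq(f, mid, 10 * eq.stable_root, xtol=1e-14)
            assert lo == pytest.approx(eq.unstable_root, abs=1e-10)
            assert hi == pytest.approx(eq.stable_root, abs=1e-10)

    def test_double_root_at_bifurcation(self, rng):
        for _ in range(20):
            p = random_params(rng)
            F_bif = bifurcation_point(p)
            eq = equilibria(F_bif, p)
            expected = p.k_forward * F_bif / (2.0 * p.k_backward)
            # root location at a tangency is sqrt(eps)-sensitive
            assert eq.unstable_root == pytest.approx(expected, rel=1e-6)
            assert eq.stable_root == pytest.approx(expected, rel=1e-6)

    def test_branch_monotonicity_in_resource_level(self, params):
        F = np.linspace(bifurcation_point(params) + 1e-6, 6.0, 300)
        stable = np.array([equilibria(f, params).stable_root for f in F])
        unstable = np.array([equilibria(f, params).unstable_root for f in F])
        assert np.all(np.diff(stable) >= 0)
        assert np.all(np.diff(unstable) <= 0)

    def test_stability_signs_from_numeric_derivative(self, params):
        F = 2.5
        eq = equilibria(F, params)
        h = 1e-6

        def drate(a):
            return (_rate(a + h, F, params) - _rate(a - h, F, params)) / (2 * h)

        assert drate(eq.dead_root) < 0
        assert drate(eq.stable_root) < 0
        assert drate(eq.unstable_root) > 0


class TestBifurcationPoint:
    def test_closed_form_unit_constants(self):
        p = MetabolismParams(1.0, 1.0, 1.0, 0.1, 50.0)
        assert bifurcation_point(p) == pytest.approx(2.0)

    def test_homogeneity_in_decay_rate(self, params):
        p4 = MetabolismParams(
            params.k_forward,
            params.k_backward,
            4.0 * params.k_decay,
            params.A_death_low,
            params.A_death_high,
        )
        assert bifurcation_point(p4) == pytest.approx(2.0 * bifurcation_point(params))

    def test_root_count_switches_at_bifurcation_by_bisection(self, rng):
        # numeric oracle: positive roots exist iff the quadratic factor
        # dips below zero on a dense A-grid
        for _ in range(5):
            p = random_params(rng)
            F_bif = bifurcation_point(p)
            A = np.linspace(1e-9, 5 * p.k_forward * (2 * F_bif) / p.k_backward, 200001)

            def has_positive_roots(F):
                q = p.k_backward * A**2 - p.k_forward * F * A + p.k_decay
                return bool(np.min(q) <= 0)

            lo, hi = 0.5 * F_bif, 2.0 * F_bif
            assert not has_positive_roots(lo) and has_positive_roots(hi)
            while hi - lo > 1e-8:
                mid = 0.5 * (lo + hi)
                if has_positive_roots(mid):
                    hi = mid
                else:
                    lo = mid
            assert abs(0.5 * (lo + hi) - F_bif) < 1e-7


class TestClassify:
    def test_death_boundaries_are_closed(self, params):
        assert classify_state(SystemState(0.0, 2.0), params) is RegionLabel.DEAD_LOW
        assert (
            classify_state(SystemState(params.A_death_low, 2.0), params)
            is RegionLabel.DEAD_LOW
        )
        assert (
            classify_state(SystemState(params.A_death_high, 2.0), params)
            is RegionLabel.DEAD_HIGH
        )

    def test_stable_root_is_viable(self, params):
        F = 1.5
        eq = equilibria(F, params)
        assert params.A_death_low < eq.stable_root < params.A_death_high
        assert classify_state(SystemState(eq.stable_root, F), params) is RegionLabel.VIABLE

    def test_subcritical_resource_level_is_precarious(self, params):
        F = 0.5 * bifurcation_point(params)
        assert classify_state(SystemState(3.0, F), params) is RegionLabel.PRECARIOUS

    def test_agrees_with_fixed_resource_integration(self, params):
        # brute-force oracle: integrate with F frozen, read off the fate
        n = 21
        F = np.linspace(0.0, 4.0, n)
        A = np.linspace(0.0, params.A_death_high, n)
        FF, AA = np.meshgrid(F, A, indexing="ij")
        F0, A0 = FF.ravel(), AA.ravel()
        res = integrate_batch(
            A0, F0, None, params, dt=1e-3, t_end=100.0,
            rate_fn=lambda a, f, da: np.zeros_like(a),
        )
        for i in range(F0.size):
            eq = equilibria(float(F0[i]), params)
            if eq.unstable_root is not None and abs(A0[i] - eq.unstable_root) <= 1e-3:
                continue  # separatrix band
            label = classify_state(SystemState(float(A0[i]), float(F0[i])), params)
            code = int(res["outcome"][i])
            if label is RegionLabel.VIABLE:
                assert code == 0
            elif label is RegionLabel.PRECARIOUS:
                assert code != 0
            elif label is RegionLabel.DEAD_LOW:
                assert code == 1
            else:
                assert code == 2


class TestParamsAndScan:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MetabolismParams(k_forward=-1.0)
        with pytest.raises(ValueError):
            MetabolismParams(A_death_low=9.0, A_death_high=8.0)

    def test_default_preset_is_reachable_bistable(self, params):
        F_bif = bifurcation_point(params)
        assert 0 < F_bif < 4.0  # inside the explorable resource window

    def test_scan_brackets_bifurcation(self, params):
        scan = bifurcation_scan(params, 0.0, 4.0, n=81)
        assert list(scan.columns) == ["F", "dead_root", "unstable_root", "stable_root"]
        below = scan[scan.F < bifurcation_point(params) - 0.1]
        above = scan[scan.F > bifurcation_point(params) + 0.1]
        assert below.stable_root.isna().all()
        assert above.stable_root.notna().all()
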