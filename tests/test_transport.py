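import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from conftest import delta, disjoint_library, mix_of, random_measure
from otkin.library import ComponentLibrary
from otkin.spectra import Spectrum, normalize
from otkin.transport import build_problem, solve, w1_closed_form


def _w1(s1, s2):
    return w1_closed_form(s1.axis, s1.intensity, s2.axis, s2.intensity)


class TestW1ClosedForm:
    def test_identity(self, rng):
        s = random_measure(rng, 10)
        assert _w1(s, s) == 0.0

    def test_two_deltas(self):
        assert _w1(delta(1.0), delta(3.0)) == pytest.approx(2.0)

    def test_split_mass(self):
        a = Spectrum(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        b = Spectrum(np.array([0.0, 2.0]), np.array([0.5, 0.5]))
        assert _w1(a, b) == pytest.approx(0.5)

    def test_symmetry_and_scipy_cross_check(self, rng):
        for _ in range(20):
            a = random_measure(rng, int(rng.integers(1, 30)))
            b = random_measure(rng, int(rng.integers(1, 30)))
            d = _w1(a, b)
            assert d == pytest.approx(_w1(b, a), abs=1e-12)
            ref = wasserstein_distance(a.axis, b.axis, a.intensity, b.intensity)
            assert d == pytest.approx(ref, abs=1e-10)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="unit-mass"):
            w1_closed_form([0.0], [2.0], [1.0], [1.0])


class TestBuildProblem:
    def test_all_pairs_without_pruning(self):
        mix = normalize(Spectrum(np.array([1.0, 2.0]), np.array([1.0, 1.0])))
        lib = ComponentLibrary((("A", normalize(
            Spectrum(np.array([1.1, 1.9]), np.array([1.0, 1.0])))),))
        prob = build_problem(mix, lib, 0.5, 0.5, prune=False)
        assert prob.n_arcs == 4

    def test_expensive_arc_pruned(self):
        mix = normalize(Spectrum(np.array([1.0, 2.0]), np.array([1.0, 1.0])))
        lib = ComponentLibrary((("A", normalize(
            Spectrum(np.array([1.1, 4.0]), np.array([1.0, 1.0])))),))
        prob = build_problem(mix, lib, 0.5, 0.5, prune=True)
        costs = sorted(prob.arc_cost)
        assert all(c <= 1.0 for c in costs)
        assert prob.n_arcs < 4  # the 1.0 -> 4.0 arc (3 ppm) is gone

    def test_pruning_preserves_optimum(self, rng):
        for _ in range(10):
            mix = random_measure(rng, int(rng.integers(2, 15)))
            lib = ComponentLibrary(tuple(
                (f"C{j}", random_measure(rng, int(rng.integers(2, 10))))
                for j in range(int(rng.integers(1, 3)))))
            o_pruned = solve(build_problem(mix, lib, 0.4, 0.3)).objective
            o_full = solve(build_problem(mix, lib, 0.4, 0.3, prune=False)).objective
            assert o_pruned == pytest.approx(o_full, abs=1e-9)

    def test_unnormalized_mixture_rejected(self):
        mix = Spectrum(np.array([1.0]), np.array([2.0]))
        lib = ComponentLibrary((("A", delta(1.0)),))
        with pytest.raises(ValueError, match="normalized"):
            build_problem(mix, lib, 0.5, 0.5)

    def test_bad_kappas_rejected(self):
        mix, lib = delta(1.0), ComponentLibrary((("A", delta(1.0)),))
        with pytest.raises(ValueError):
            build_problem(mix, lib, 0.0, 0.5)
        with pytest.raises(ValueError):
            build_problem(mix, lib, 0.5, -0.1)


def _check_solution_invariants(prob, sol, tol=1e-9):
    assert np.all(sol.p >= -tol)
    assert sol.p.sum() <= 1 + tol
    assert sol.p0 == pytest.approx(1 - sol.p.sum(), abs=tol)
    assert sol.objective >= -tol
    # mixture mass balance: plan out of atom i plus discarded equals a_i
    out = np.bincount(prob.arc_mix, weights=sol.plan, minlength=prob.n)
    np.testing.assert_allclose(out + sol.mixture_noise, prob.mix_mass, atol=tol)
    # component balance: plan into atom f plus discarded equals p_j b_f
    inc = np.bincount(prob.arc_comp, weights=sol.plan, minlength=prob.n_comp_atoms)
    np.testing.assert_allclose(
        inc + sol.component_noise,
        sol.p[prob.comp_of_atom] * prob.comp_mass, atol=tol)


class TestSolve:
    def test_perfect_two_component_reconstruction(self, rng):
        lib = disjoint_library(rng, 2)
        mix = mix_of(lib, [0.3, 0.7])
        prob = build_problem(mix, lib, 0.5, 0.5)
        sol = solve(prob)
        np.testing.assert_allclose(sol.p, [0.3, 0.7], atol=1e-9)
        assert sol.p0 == pytest.approx(0.0, abs=1e-9)
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        _check_solution_invariants(prob, sol)

    @pytest.mark.parametrize("d,exp_p,exp_p0,exp_obj", [
        (0.2, 1.0, 0.0, 0.2),   # transporting beats discarding (0.2 < kappa_m)
        (0.8, 0.0, 1.0, 0.5),   # discarding at kappa_m beats transporting 0.8
    ])
    def test_delta_denoising_thresholds(self, d, exp_p, exp_p0, exp_obj):
        lib = ComponentLibrary((("A", delta(1.0 + d)),))
        sol = solve(build_problem(delta(1.0), lib, 0.5, 0.5))
        assert sol.p[0] == pytest.approx(exp_p, abs=1e-9)
        assert sol.p0 == pytest.approx(exp_p0, abs=1e-9)
        assert sol.objective == pytest.approx(exp_obj, abs=1e-9)

    def test_disjoint_degenerate_full_discard(self):
        # single mixture atom with no admissible arc: all mass is noise
        lib = ComponentLibrary((("A", delta(9.0)),))
        prob = build_problem(delta(1.0), lib, 0.5, 0.5)
        sol = solve(prob)
        assert sol.p[0] == pytest.approx(0.0, abs=1e-12)
        assert sol.p0 == pytest.approx(1.0, abs=1e-12)
        assert sol.objective == pytest.approx(0.5, abs=1e-12)
        _check_solution_invariants(prob, sol)

    def test_single_component_large_kappa_equals_w1(self, rng):
        # with penalties above the axis diameter, discarding never pays:
        # the LP must reproduce the closed-form Wasserstein distance
        for _ in range(20):
            mix = random_measure(rng, int(rng.integers(1, 50)))
            comp = random_measure(rng, int(rng.integers(1, 50)))
            lib = ComponentLibrary((("A", comp),))
            sol = solve(build_problem(mix, lib, 6.0, 6.0))
            assert sol.objective == pytest.approx(_w1(mix, comp), abs=1e-8)
            assert sol.p[0] == pytest.approx(1.0, abs=1e-8)

    def test_objective_monotone_in_kappas(self, rng):
        mix = random_measure(rng, 12)
        lib = disjoint_library(rng, 2)
        objs = [solve(build_problem(mix, lib, km, kc)).objective
                for km, kc in [(0.1, 0.1), (0.3, 0.1), (0.3, 0.4), (0.9, 0.9)]]
        assert objs == sorted(objs)

    def test_zero_objective_iff_in_convex_hull(self, rng):
        lib = disjoint_library(rng, 3)
        inside = mix_of(lib, [0.2, 0.5, 0.3])
        assert solve(build_problem(inside, lib, 0.5, 0.5)).objective == \
            pytest.approx(0.0, abs=1e-10)
        # perturb one atom position: no exact representation remains
        axis = inside.axis.copy()
        axis[0] += 0.05
        outside = Spectrum(axis, inside.intensity)
        assert solve(build_problem(outside, lib, 0.5, 0.5)).objective > 1e-4

    def test_translation_invariance(self, rng):
        mix = random_measure(rng, 10)
        lib = disjoint_library(rng, 2)
        sol = solve(build_problem(mix, lib, 0.5, 0.5))
        shift = 3.7
        mix2 = Spectrum(mix.axis + shift, mix.intensity)
        lib2 = ComponentLibrary(tuple(
            (n, Spectrum(s.axis + shift, s.intensity)) for n, s in lib.components))
        sol2 = solve(build_problem(mix2, lib2, 0.5, 0.5))
        assert sol2.objective == pytest.approx(sol.objective, abs=1e-9)
        np.testing.assert_allclose(sol2.p, sol.p, atol=1e-7)

    def test_invariants_on_random_solves(self, rng):
        for _ in range(10):
            mix = random_measure(rng, int(rng.integers(2, 25)))
            lib = ComponentLibrary(tuple(
                (f"C{j}", random_measure(rng, int(rng.integers(2, 12))))
                for j in range(int(rng.integers(1, 4)))))
            prob = build_problem(mix, lib, 0.5, 0.5)
            _check_solution_invariants(prob, solve(prob))


class TestWarmStart:
    def test_warm_equals_cold_same_problem(self, rng):
        mix = random_measure(rng, 30)
        lib = disjoint_library(rng, 2, atoms_per_comp=10)
        prob = build_problem(mix, lib, 0.5, 0.5)
        cold = solve(prob)
        warm = solve(prob, warm=cold.basis)
        assert warm.warm_started
        assert warm.objective == pytest.approx(cold.objective, abs=1e-9)

    def test_warm_equals_cold_perturbed_problem(self, rng):
        mix = random_measure(rng, 30)
        lib = disjoint_library(rng, 2, atoms_per_comp=10)
        prev = solve(build_problem(mix, lib, 0.5, 0.5))
        drifted = normalize(Spectrum(mix.axis + 0.02,
                                     mix.intensity * rng.uniform(0.9, 1.1, 30)))
        prob2 = build_problem(drifted, lib, 0.5, 0.5)
        cold = solve(prob2)
        warm = solve(prob2, warm=prev.basis)
        assert warm.objective == pytest.approx(cold.objective, abs=1e-9)

    def test_stale_basis_dimensions_fall_back(self, rng):
        mix = random_measure(rng, 8)
        lib = disjoint_library(rng, 2)
        prob = build_problem(mix, lib, 0.5, 0.5)
        cold = solve(prob)
        # basis from an unrelated, bigger problem
        warm = solve(prob, warm=[(999, 999), (5, 3)])
        assert warm.objective == pytest.approx(cold.objective, abs=1e-9)

    def test_empty_basis_warm_start(self, rng):
        mix = random_measure(rng, 8)
        lib = disjoint_library(rng, 2)
        prob = build_problem(mix, lib, 0.5, 0.5)
        warm = solve(prob, warm=[])
        assert warm.objective == pytest.approx(solve(prob).objective, abs=1e-9)

    def test_solution_serializes(self, rng):
        import json
        mix = random_measure(rng, 5)
        lib = disjoint_library(rng, 1)
        sol = solve(build_problem(mix, lib, 0.5, 0.5))
        blob = json.loads(sol.to_json())
        assert set(blob) >= {"p", "p0", "objective", "status"}
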