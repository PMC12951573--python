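"""RDF computation, finite-size correction, KBIs and extrapolation."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import quad

import kbsolv as kb


def curve_from_analytic(ar):
    return kb.RDFCurve(r=ar.r, g=ar.g, bin_width=ar.bin_width)


class TestComputeRDF:
    def test_two_fixed_particles_single_bin(self):
        coords = np.array([[[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]])
        topo = kb.monatomic_topology({"p": 2})
        traj = kb.Trajectory(coords, [0.0], kb.Box([4.0] * 3), topo)
        sel = kb.Selection("p", "atom")
        rdf = kb.compute_rdf(traj, sel, sel, bin_width=0.05)
        occupied = np.flatnonzero(rdf.g > 0)
        assert len(occupied) == 1
        assert rdf.r[occupied[0]] == pytest.approx(0.525)  # bin containing 0.5

    def test_matches_brute_force_pair_counts(self, rng):
        """Tree-based histogram equals a direct O(N^2) double loop."""
        N, frames, bw, r_max = 40, 5, 0.1, 1.9
        box = kb.Box([4.0] * 3)
        coords = rng.uniform(0, 4, size=(frames, N, 3))
        topo = kb.monatomic_topology({"a": 20, "b": 20})
        traj = kb.Trajectory(coords, np.arange(float(frames)), box, topo)
        sel_a, sel_b = kb.Selection("a", "atom"), kb.Selection("b", "atom")
        rdf = kb.compute_rdf(traj, sel_a, sel_b, bin_width=bw, r_max=r_max)

        edges = np.arange(int(round(r_max / bw)) + 1) * bw
        counts = np.zeros(len(edges) - 1)
        for f in range(frames):
            for i in range(20):
                for j in range(20, 40):
                    d = kb.minimum_image_distance(coords[f, i], coords[f, j], box)
                    if d < edges[-1]:
                        counts[np.searchsorted(edges, d, side="right") - 1] += 1
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected_g = (counts / frames) / (20 * (20 / box.volume) * shell)
        assert np.allclose(rdf.g, expected_g, atol=1e-12)

    def test_same_species_excludes_self_pairs(self, rng):
        coords = rng.uniform(0, 4, size=(3, 30, 3))
        topo = kb.monatomic_topology({"a": 30})
        traj = kb.Trajectory(coords, np.arange(3.0), kb.Box([4.0] * 3), topo)
        sel = kb.Selection("a", "atom")
        rdf = kb.compute_rdf(traj, sel, sel, bin_width=0.1)
        assert rdf.g[0] == 0.0  # no self-distance artefacts at r ~ 0
        assert rdf.same_selection

    def test_selection_swap_symmetry(self, rng):
        coords = rng.uniform(0, 4, size=(3, 30, 3))
        topo = kb.monatomic_topology({"a": 14, "b": 16})
        traj = kb.Trajectory(coords, np.arange(3.0), kb.Box([4.0] * 3), topo)
        g_ab = kb.compute_rdf(traj, kb.Selection("a", "atom"),
                              kb.Selection("b", "atom"), bin_width=0.1)
        g_ba = kb.compute_rdf(traj, kb.Selection("b", "atom"),
                              kb.Selection("a", "atom"), bin_width=0.1)
        assert np.allclose(g_ab.g, g_ba.g, atol=1e-12)
        run_ab, run_ba = kb.running_kbi(g_ab), kb.running_kbi(g_ba)
        assert np.allclose(run_ab.G, run_ba.G, atol=1e-12)

    def test_r_max_beyond_half_box_names_bound(self, tiny_trajectory):
        sel = kb.Selection("alpha", "atom")
        with pytest.raises(ValueError, match="half the smallest box length"):
            kb.compute_rdf(tiny_trajectory, sel, sel, bin_width=0.1, r_max=3.0)


class TestVdvCorrect:
    def test_five_bin_hand_formula(self):
        """Independent arithmetic re-implementation of the rescaling."""
        r = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        g = np.array([0.0, 0.4, 1.7, 1.2, 0.95])
        n_j, volume = 50, 125.0
        rdf = kb.RDFCurve(r=r, g=g, bin_width=0.2, n_i=50, n_j=n_j,
                          volume=volume, same_selection=True)
        corrected = kb.vdv_correct(rdf)

        rho = n_j / volume
        expected = np.empty(5)
        excess = 0.0
        v_sph = 0.0
        for k in range(5):
            lo, hi = r[k] - 0.1, r[k] + 0.1
            shell = 4.0 / 3.0 * np.pi * (hi**3 - max(lo, 0.0) ** 3)
            excess += rho * (g[k] - 1.0) * shell
            v_sph += shell
            bulk = n_j * (1.0 - v_sph / volume)
            expected[k] = g[k] * bulk / (bulk - excess - 1.0)
        assert np.allclose(corrected.g, expected, atol=1e-12)
        assert np.array_equal(corrected.g_raw, g)

    def test_ideal_gas_closure_small_n(self):
        traj = kb.gen_ideal_gas(100, kb.Box([4.0] * 3), 200, seed=0)
        sel = kb.Selection("ideal", "atom")
        rdf = kb.compute_rdf(traj, sel, sel, bin_width=0.04)
        tail = rdf.g[len(rdf.g) // 2:]
        assert tail.mean() == pytest.approx(99 / 100, abs=0.01)  # closed-system dip
        corrected = kb.vdv_correct(rdf)
        assert np.abs(corrected.g[len(corrected.g) // 2:].mean() - 1.0) < 0.01

    def test_open_system_limit_unchanged(self):
        r = np.arange(0.05, 1.0, 0.1)
        rdf = kb.RDFCurve(r=r, g=np.ones_like(r), bin_width=0.1, n_i=10**9,
                          n_j=10**9, volume=1e12, same_selection=False)
        corrected = kb.vdv_correct(rdf)
        assert np.allclose(corrected.g, 1.0, atol=1e-9)

    def test_denominator_crossing_flags_bin(self):
        r = np.array([0.25, 0.75])
        rdf = kb.RDFCurve(r=r, g=np.array([80.0, 1.0]), bin_width=0.5, n_i=4,
                          n_j=4, volume=8.0, same_selection=False)
        with pytest.raises(ValueError, match="bin"):
            kb.vdv_correct(rdf)


class TestKBIQuadrature:
    def test_unit_form_is_zero_everywhere(self):
        ar = kb.gen_analytic_rdf("unit", {}, 1.0, 0.002)
        curve = curve_from_analytic(ar)
        assert np.abs(kb.running_kbi(curve).G).max() == 0.0
        assert np.abs(kb.kruger_kbi(curve).G).max() == 0.0

    def test_hard_step_running_exact(self):
        ar = kb.gen_analytic_rdf("hard-step", {"sigma": 0.3}, 1.5, 0.002)
        run = kb.running_kbi(curve_from_analytic(ar))
        beyond = run.R >= 0.3
        assert np.abs(run.G[beyond] - ar.G_infinity).max() < 1e-12

    def test_kruger_weight_endpoints(self):
        assert kb.kruger_weight(0.0) == 1.0
        assert kb.kruger_weight(1.0) == 0.0

    def test_kruger_hard_step_symbolic(self):
        """Symbolic finite-volume integral of the step fixture."""
        ar = kb.gen_analytic_rdf("hard-step", {"sigma": 0.3}, 1.5, 0.002)
        kru = kb.kruger_kbi(curve_from_analytic(ar))
        r, R = sp.symbols("r R", positive=True)
        w = 1 - sp.Rational(3, 2) * (r / R) + sp.Rational(1, 2) * (r / R) ** 3
        G_V = sp.lambdify(R, sp.integrate(-4 * sp.pi * r**2 * w, (r, 0, sp.Rational(3, 10))))
        beyond = kru.R >= 0.3
        assert np.abs(kru.G[beyond] - G_V(kru.R[beyond])).max() < 1e-10

    def test_damped_oscillation_vs_adaptive_quadrature(self):
        params = {"sigma": 0.3, "A": 0.6, "lam": 0.3, "d": 0.31}
        ar = kb.gen_analytic_rdf("damped-oscillation", params, 3.0, 0.002)
        run = kb.running_kbi(curve_from_analytic(ar))

        def integrand(x):
            return 4 * np.pi * x * x * (ar.evaluate(np.array([x]))[0] - 1.0)

        for R_target in (0.5, 1.0, 1.8, 3.0):
            k = int(np.argmin(np.abs(run.R - R_target)))
            exact = quad(integrand, 0, run.R[k], limit=500)[0]
            assert abs(run.G[k] - exact) < 1e-4

    def test_both_methods_converge_to_G_infinity(self):
        params = {"sigma": 0.3, "A": 0.6, "lam": 0.3, "d": 0.31}
        ar = kb.gen_analytic_rdf("damped-oscillation", params, 3.0, 0.002)
        curve = curve_from_analytic(ar)
        assert kb.running_kbi(curve).G[-1] == pytest.approx(ar.G_infinity, abs=2e-4)
        kru = kb.kruger_kbi(curve)
        n = len(kru.R)
        est = kb.extrapolate_kbi(kru, kb.LinearRegime.from_range(int(0.6 * n), n))
        assert est.G_infinity == pytest.approx(ar.G_infinity, abs=5e-4)

    def test_kruger_linear_in_inverse_R_for_hard_step(self):
        """G_V(R) approaches G_inf linearly in 1/R; the 1/R fit over the far
        tail recovers the closed form much better than the raw tail value."""
        ar = kb.gen_analytic_rdf("hard-step", {"sigma": 0.3}, 3.0, 0.002)
        kru = kb.kruger_kbi(curve_from_analytic(ar))
        n = len(kru.R)
        est = kb.extrapolate_kbi(kru, kb.LinearRegime.from_range(int(0.8 * n), n))
        raw_tail_err = abs(kru.G[-1] - ar.G_infinity)
        assert abs(est.G_infinity - ar.G_infinity) < 1e-4
        assert abs(est.G_infinity - ar.G_infinity) < raw_tail_err / 10


class TestLinearRegime:
    def _dual_cutoff_fixture(self):
        """100-point curves with a hand-traced regime: g slopes settle at
        index 40 (start = 46 after the 7-point window), G slope breaks at 80."""
        n = 100
        r = (np.arange(n) + 0.5) * 0.01
        g = np.ones(n)
        g[:40] += 0.05 * (-1.0) ** np.arange(40)  # slope swings ~10 per nm
        # G linear through index 80; the first deviating slope is s_80
        G = np.where(np.arange(n) <= 80,
                     0.05 * r,
                     0.05 * r[80] + 0.3 * (r - r[80]))
        rdf = kb.RDFCurve(r=r, g=g, bin_width=0.01)
        kbi = kb.KBICurve(R=r, G=G)
        return rdf, kbi

    def test_hand_traced_dual_cutoff_indices(self):
        rdf, kbi = self._dual_cutoff_fixture()
        regime = kb.detect_linear_regime(rdf, kbi)
        assert not regime.absent
        assert (regime.start, regime.end) == (46, 80)

    def test_oscillating_slopes_yield_absent_regime(self):
        n = 60
        r = (np.arange(n) + 0.5) * 0.01
        g = 1.0 + 0.05 * (-1.0) ** np.arange(n)
        rdf = kb.RDFCurve(r=r, g=g, bin_width=0.01)
        kbi = kb.KBICurve(R=r, G=np.zeros(n))
        regime = kb.detect_linear_regime(rdf, kbi)
        assert regime.absent
        with pytest.raises(kb.RegimeAbsentError):
            kb.extrapolate_kbi(kbi, regime)

    def test_flat_fixture_spans_tail_and_extrapolates_exactly(self):
        n = 200
        r = np.linspace(1.0, 3.0, n)
        G_inf, c = -0.5, 0.01
        rdf = kb.RDFCurve(r=r, g=np.ones(n), bin_width=r[1] - r[0])
        kbi = kb.KBICurve(R=r, G=G_inf + c / r)
        regime = kb.detect_linear_regime(rdf, kbi)
        assert not regime.absent
        assert regime.end == n  # no G-slope break: regime runs to the grid end
        est = kb.extrapolate_kbi(kbi, regime)
        assert est.G_infinity == pytest.approx(G_inf, abs=1e-10)


class TestExtrapolate:
    def test_exact_inverse_R_model(self):
        R = np.linspace(1.0, 2.0, 50)
        kbi = kb.KBICurve(R=R, G=-0.5 + 0.3 / R)
        est = kb.extrapolate_kbi(kbi, kb.LinearRegime.from_range(0, 50))
        assert est.G_infinity == pytest.approx(-0.5, abs=1e-10)
        assert est.sigma == 0.0 and est.n_replicates == 1

    def test_identical_replicates_zero_sigma(self):
        R = np.linspace(1.0, 2.0, 50)
        kbi = kb.KBICurve(R=R, G=1.0 + 0.1 / R)
        reps = [kb.KBICurve(R=R, G=1.0 + 0.1 / R) for _ in range(5)]
        est = kb.extrapolate_kbi(kbi, kb.LinearRegime.from_range(0, 50), reps)
        assert est.sigma == 0.0 and est.n_replicates == 5

    def test_replicate_spread_sample_std(self):
        R = np.linspace(1.0, 2.0, 50)
        reps = [kb.KBICurve(R=R, G=np.full(50, float(v))) for v in (1, 2, 3, 4, 5)]
        est = kb.extrapolate_kbi(reps[0], kb.LinearRegime.from_range(0, 50), reps)
        assert est.G_infinity == pytest.approx(3.0, abs=1e-12)
        assert est.sigma == pytest.approx(1.5811, abs=1e-4)


class TestAutoDetectionOnSampledData:
    def test_ideal_gas_n1000_auto_regime(self):
        """With production-like statistics the dual-cutoff rule triggers and
        the extrapolated KBI is consistent with zero."""
        traj = kb.gen_ideal_gas(1000, kb.Box([5.0] * 3), 60, seed=12)
        sel = kb.Selection("ideal", "atom")
        corrected = kb.vdv_correct(kb.compute_rdf(traj, sel, sel, bin_width=0.04))
        kbi = kb.kruger_kbi(corrected)
        regime = kb.detect_linear_regime(corrected, kbi)
        assert not regime.absent
        est = kb.extrapolate_kbi(kbi, regime)
        assert abs(est.G_infinity) < 0.05
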