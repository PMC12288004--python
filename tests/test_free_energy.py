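import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlmm.dynamics import SimulationPlan
from mlmm.free_energy import (
    LambdaProtocol,
    TIResult,
    WindowEstimate,
    exact_window_averages,
    gas_phase_system,
    gauss_legendre_nodes_weights,
    integrate_quadrature,
    oracle_bar,
    oracle_exact,
    reorganization_energy,
    sample_window,
    trapezoid_weights,
    window_mean_sem,
)
from mlmm.synthetic_fixtures import make_harmonic_1d
from mlmm.units import kT

T_REF = 300.0


def _fast_protocol(n_lam=3, n_steps=300, form="linear"):
    plan = SimulationPlan(ensemble="NVT", dt=1.0, n_steps=n_steps, temperature=T_REF,
                          friction=0.1, report_interval=5, init_temperature=T_REF)
    return LambdaProtocol(lambdas=np.linspace(0, 1, n_lam), plan=plan,
                          coupling_form=form)


class TestQuadrature:
    def test_trapezoid_weights_three_nodes(self):
        np.testing.assert_allclose(trapezoid_weights(np.array([0.0, 0.5, 1.0])),
                                   [0.25, 0.5, 0.25])

    def test_hand_arithmetic(self):
        wins = [WindowEstimate(l, m, 0.1, 10)
                for l, m in zip([0.0, 0.5, 1.0], [-10.0, -8.0, -6.0])]
        dG, sem, _ = integrate_quadrature(wins)
        assert dG == pytest.approx(-8.0, rel=1e-12)
        assert sem == pytest.approx(0.1 * math.sqrt(0.25**2 + 0.5**2 + 0.25**2))

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8, unique=True),
           st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_trapezoid_exact_for_linear_integrands(self, interior, a, b):
        lam = np.array(sorted([0.0, *interior, 1.0]))
        wins = [WindowEstimate(l, a + b * l, 0.0, 10) for l in lam]
        dG, _, _ = integrate_quadrature(wins)
        assert dG == pytest.approx(a + b / 2.0, abs=1e-9)

    def test_gauss_matches_dense_trapezoid_on_smooth_integrand(self):
        p0, p1, _ = make_harmonic_1d(1.0, 4.0, T_REF)
        nodes, _ = gauss_legendre_nodes_weights(8)
        g_wins = [WindowEstimate(l, m, 0.0, 10)
                  for l, m in zip(nodes, exact_window_averages(p0, p1, T_REF, nodes))]
        dG_g, _, _ = integrate_quadrature(g_wins, "gauss_legendre")
        lam_d = np.linspace(0, 1, 201)
        d_wins = [WindowEstimate(l, m, 0.0, 10)
                  for l, m in zip(lam_d, exact_window_averages(p0, p1, T_REF, lam_d))]
        dG_t, _, _ = integrate_quadrature(d_wins)
        assert dG_g == pytest.approx(dG_t, abs=2e-4)

    def test_antisymmetry_under_path_reversal(self):
        lam = np.linspace(0, 1, 5)
        wins = [WindowEstimate(l, math.sin(3 * l) - 2, 0.0, 10) for l in lam]
        fwd, _, _ = integrate_quadrature(wins)
        rev, _, _ = integrate_quadrature(wins[::-1])
        assert rev == pytest.approx(-fwd, rel=1e-12)

    def test_gauss_node_mismatch_rejected(self):
        wins = [WindowEstimate(l, 0.0, 0.0, 10) for l in np.linspace(0, 1, 4)]
        with pytest.raises(ValueError, match="Gauss"):
            integrate_quadrature(wins, "gauss_legendre")


class TestWindowStatistics:
    def test_constant_series(self):
        est = window_mean_sem(np.full(100, 3.7))
        assert est.mean_dvdl == 3.7
        assert est.sem == 0.0

    def test_white_noise_sem(self, rng):
        series = rng.standard_normal(10000)
        est = window_mean_sem(series)
        assert est.sem == pytest.approx(1.0 / math.sqrt(10000), rel=0.2)

    def test_equilibration_discard_counts(self):
        series = np.array([100.0] * 5 + [1.0, 2.0, 3.0, 4.0, 5.0])
        est = window_mean_sem(series, equilibration_fraction=0.5)
        assert est.mean_dvdl == pytest.approx(3.0)
        assert est.n_samples == 5

    def test_too_short_after_discard(self):
        with pytest.raises(ValueError, match="too short"):
            window_mean_sem(np.array([1.0, 2.0]), equilibration_fraction=0.6)

    def test_correlated_series_inflates_sem(self, rng):
        # AR(1) with strong positive correlation: block SEM >> naive SEM
        n, phi = 20000, 0.95
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        est = window_mean_sem(x)
        naive = x.std(ddof=1) / math.sqrt(n)
        assert est.sem > 2 * naive
        assert est.statistical_inefficiency > 4


class TestReorganization:
    def test_identical_series(self, rng):
        s = rng.standard_normal(500)
        dg, sem = reorganization_energy(s, s)
        assert dg == 0.0

    def test_constant_offset(self):
        dg, sem = reorganization_energy(np.full(10, -3.0), np.full(10, -5.0))
        assert dg == pytest.approx(2.0)
        assert sem == 0.0


class TestOracles:
    def test_bar_identical_states(self):
        dg, sem = oracle_bar(np.zeros(100), np.zeros(100), T_REF)
        assert dg == pytest.approx(0.0, abs=1e-10)

    def test_bar_shifted_harmonic_wells(self, rng):
        """Same stiffness, shifted minima: equal partition functions, dG = 0."""
        k, b = 2.0, kT(T_REF)
        x0 = rng.normal(0.0, math.sqrt(b / k), 4000)
        x1 = rng.normal(1.5, math.sqrt(b / k), 4000)
        wf = 0.5 * k * (x0 - 1.5) ** 2 - 0.5 * k * x0**2
        wr = 0.5 * k * x1**2 - 0.5 * k * (x1 - 1.5) ** 2
        dg, sem = oracle_bar(wf, wr, T_REF)
        assert abs(dg) < 3 * sem

    def test_bar_stiffness_change_closed_form(self, rng):
        k0, k1, b = 1.0, 4.0, kT(T_REF)
        x0 = rng.normal(0, math.sqrt(b / k0), 6000)
        x1 = rng.normal(0, math.sqrt(b / k1), 6000)
        wf = 0.5 * (k1 - k0) * x0**2
        wr = 0.5 * (k0 - k1) * x1**2
        dg, sem = oracle_bar(wf, wr, T_REF)
        expected = 0.5 * b * math.log(k1 / k0)
        assert abs(dg - expected) < 3 * sem

    def test_bar_one_sided_reduces_to_exp_averaging(self, rng):
        k0, k1, b = 1.0, 2.0, kT(T_REF)
        x0 = rng.normal(0, math.sqrt(b / k0), 20000)
        dg, _ = oracle_bar(0.5 * (k1 - k0) * x0**2, np.array([]), T_REF)
        assert dg == pytest.approx(0.5 * b * math.log(k1 / k0), abs=0.02)

    def test_exact_identical_potentials(self):
        p0, _, _ = make_harmonic_1d(2.0, 2.0, T_REF)
        assert oracle_exact(p0, p0, T_REF) == pytest.approx(0.0, abs=1e-12)

    def test_exact_harmonic_closed_form(self):
        p0, p1, dg_ref = make_harmonic_1d(1.0, 4.0, T_REF)
        assert oracle_exact(p0, p1, T_REF) == pytest.approx(dg_ref, abs=1e-9)
        assert dg_ref == pytest.approx(0.5 * kT(T_REF) * math.log(4.0), rel=1e-12)

    def test_exact_2d_separable(self):
        b = kT(T_REF)

        def v0(x, y):
            return 0.5 * (x**2 + y**2)

        def v1(x, y):
            return 0.5 * (4.0 * x**2 + y**2)

        dg = oracle_exact(v0, v1, T_REF, bounds=(-30, 30), ndim=2)
        assert dg == pytest.approx(0.5 * b * math.log(4.0), abs=1e-6)

    def test_ti_with_exact_averages_matches_exact_oracle(self):
        """Cross-oracle consistency: 21-window trapezoid over quadrature-exact
        window means reproduces the configurational-integral dG to
        discretization error."""
        p0, p1, dg_ref = make_harmonic_1d(1.0, 4.0, T_REF)
        lam = np.linspace(0, 1, 21)
        wins = [WindowEstimate(l, m, 0.0, 10)
                for l, m in zip(lam, exact_window_averages(p0, p1, T_REF, lam))]
        dG, _, _ = integrate_quadrature(wins)
        assert dG == pytest.approx(dg_ref, abs=2e-3)


class TestSampling:
    def test_identical_seeds_identical_series(self, ti_system):
        system, frame = ti_system
        proto = _fast_protocol(n_steps=100)
        a = sample_window(system, proto, 1, "water", seed=9, frame0=frame)
        b = sample_window(system, proto, 1, "water", seed=9, frame0=frame)
        np.testing.assert_array_equal(a.dvdl, b.dvdl)
        np.testing.assert_array_equal(a.e_ml, b.e_ml)

    def test_lambda_zero_linear_dvdl_is_unscaled_coupling(self, ti_system):
        from mlmm.potentials import coupling_energy_forces

        system, frame = ti_system
        proto = _fast_protocol(n_steps=100, form="linear")
        s = sample_window(system, proto, 0, "water", seed=3, frame0=frame,
                          keep_trajectory=True)
        assert s.lam == 0.0
        for value, f in zip(s.dvdl, s.trajectory):
            full = coupling_energy_forces(system, f, 1.0, "linear")[0]
            assert value == pytest.approx(full, rel=1e-10)

    def test_gas_phase_of_rigid_solute_is_constant(self, rigid_ti_system):
        system, frame = rigid_ti_system
        proto = _fast_protocol(n_steps=150)
        gas = sample_window(system, proto, 0, "gas", seed=5,
                            frame0=type(frame)(frame.coordinates[system.ml_indices]))
        assert np.ptp(gas.e_ml) < 1e-9
        assert np.all(gas.dvdl == 0.0)

    def test_gas_phase_system_strips_solvent(self, ti_system):
        system, _ = ti_system
        gas = gas_phase_system(system)
        assert gas.n_atoms == len(system.ml_indices)
        assert len(gas.mm_indices) == 0
        assert gas.ml_potential is system.ml_potential


class TestTIResult:
    def test_identity_enforced(self):
        wins = [WindowEstimate(l, 0.0, 0.0, 10) for l in (0.0, 1.0)]
        with pytest.raises(ValueError, match="exactly"):
            TIResult(windows=wins, dG_coupling=-1.0, dG_coupling_sem=0.1,
                     dG_reorg=0.5, dG_reorg_sem=0.1, dG_solvation=0.0,
                     uncertainty=0.2)

    def test_protocol_requires_increasing_lambdas(self):
        with pytest.raises(ValueError, match="increasing"):
            LambdaProtocol(lambdas=np.array([0.0, 0.6, 0.4, 1.0]))

    def test_trapezoid_protocol_requires_endpoints(self):
        with pytest.raises(ValueError, match="endpoints"):
            LambdaProtocol(lambdas=np.array([0.1, 0.5, 1.0]))
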