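import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlmm.potentials import (
    EnergyReport,
    SingularityError,
    coupling_energy_forces,
    mm_energy_forces,
    ml_energy_forces,
    surrogate_ml_energy_forces,
    total_energy_report,
)
from mlmm.synthetic_fixtures import (
    combine_solute_bath,
    make_solvent_bath,
    make_toy_solute,
)
from mlmm.system_model import Atom, BondedTerm, Frame, System
from mlmm.units import COULOMB_CONSTANT


def _mm_system(atoms, **kw):
    return System(atoms=atoms, **kw)


def _five_point_gradient(energy_fn, coords, h=1e-4):
    grad = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for d in range(3):
            vals = []
            for mult in (-2, -1, 1, 2):
                x = coords.copy()
                x[i, d] += mult * h
                vals.append(energy_fn(x))
            grad[i, d] = (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h)
    return grad


@pytest.fixture(scope="module")
def hybrid():
    """Small perturbed solvated system exercising every potential term."""
    solute, _, sframe = make_toy_solute(5, seed=1)
    bath, bframe = make_solvent_bath(6, 9.0, seed=2, cavity_radius=3.0)
    system, frame = combine_solute_bath(solute, sframe, bath, bframe)
    rng = np.random.default_rng(0)
    coords = frame.coordinates + 0.05 * rng.standard_normal(frame.coordinates.shape)
    return system, Frame(coords)


class TestMMEnergy:
    def test_single_harmonic_bond(self):
        atoms = [Atom(0, "C", 12.0, 0.0), Atom(1, "C", 12.0, 0.0)]
        s = _mm_system(atoms, bonded_terms=[BondedTerm("bond", (0, 1), 100.0, 1.0)],
                       exclusions={(0, 1)})
        e, f = mm_energy_forces(s, Frame(np.array([[0.0, 0, 0], [1.1, 0, 0]])))
        assert e == pytest.approx(0.5 * 100.0 * 0.01, rel=1e-12)

    def test_empty_potential_is_zero(self):
        atoms = [Atom(i, "Ar", 39.9, 0.0) for i in range(3)]
        e, f = mm_energy_forces(_mm_system(atoms), Frame(np.eye(3) * 3.0))
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_coulomb_pair_matches_constant(self):
        atoms = [Atom(0, "Na", 23.0, 1.0), Atom(1, "Cl", 35.5, -1.0)]
        e, _ = mm_energy_forces(_mm_system(atoms),
                                Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]])))
        assert e == pytest.approx(-COULOMB_CONSTANT / 2.0, rel=1e-12)

    def test_overlapping_pair_raises(self):
        atoms = [Atom(0, "Na", 23.0, 1.0), Atom(1, "Cl", 35.5, -1.0)]
        with pytest.raises(SingularityError):
            mm_energy_forces(_mm_system(atoms),
                             Frame(np.array([[0.0, 0, 0], [1e-8, 0, 0]])))


class TestGradientConsistency:
    """Analytic forces vs 5-point central finite differences, every term."""

    def test_mm_forces(self, hybrid):
        system, frame = hybrid
        e, forces = mm_energy_forces(system, frame)
        num = _five_point_gradient(lambda x: mm_energy_forces(system, Frame(x))[0],
                                   frame.coordinates)
        np.testing.assert_allclose(forces, -num, rtol=1e-6, atol=1e-7)

    def test_surrogate_ml_forces(self, hybrid):
        system, frame = hybrid
        e, forces = ml_energy_forces(system, frame)
        num = _five_point_gradient(lambda x: ml_energy_forces(system, Frame(x))[0],
                                   frame.coordinates)
        np.testing.assert_allclose(forces, -num, rtol=1e-6, atol=1e-7)

    @pytest.mark.parametrize("form,lam", [("linear", 0.7), ("softcore", 0.35),
                                          ("softcore", 1.0)])
    def test_coupling_forces(self, hybrid, form, lam):
        system, frame = hybrid
        _, forces, _ = coupling_energy_forces(system, frame, lam, form)
        num = _five_point_gradient(
            lambda x: coupling_energy_forces(system, Frame(x), lam, form)[0],
            frame.coordinates)
        np.testing.assert_allclose(forces, -num, rtol=1e-6, atol=1e-7)

    @pytest.mark.parametrize("form,lam", [("linear", 0.3), ("linear", 0.9),
                                          ("softcore", 0.3), ("softcore", 0.9)])
    def test_dvdl_matches_finite_difference(self, hybrid, form, lam):
        system, frame = hybrid
        _, _, dvdl = coupling_energy_forces(system, frame, lam, form)
        dl = 1e-5
        num = (coupling_energy_forces(system, frame, lam + dl, form)[0]
               - coupling_energy_forces(system, frame, lam - dl, form)[0]) / (2 * dl)
        assert dvdl == pytest.approx(num, rel=1e-7)


class TestSymmetries:
    def test_charge_conjugation_invariance(self, hybrid):
        system, frame = hybrid
        flipped = System(
            atoms=[Atom(a.index, a.element, a.mass, -a.charge, a.lj_A, a.lj_B, a.region)
                   for a in system.atoms],
            bonded_terms=system.bonded_terms, exclusions=system.exclusions,
            pairs14=system.pairs14, box=system.box, ml_potential=system.ml_potential)
        e0, _ = mm_energy_forces(system, frame)
        e1, _ = mm_energy_forces(flipped, frame)
        assert e1 == pytest.approx(e0, rel=1e-12)
        c0 = coupling_energy_forces(system, frame, 1.0)[0]
        c1 = coupling_energy_forces(flipped, frame, 1.0)[0]
        assert c1 == pytest.approx(c0, rel=1e-12)

    @given(shift=st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    @settings(max_examples=20, deadline=None)
    def test_translational_invariance(self, hybrid, shift):
        system, frame = hybrid
        moved = Frame(frame.coordinates + np.array(shift))
        e0 = total_energy_report(system, frame, 0.8).E_total
        e1 = total_energy_report(system, moved, 0.8).E_total
        assert abs(e1 - e0) < 1e-9


class TestCoupling:
    def _pair(self, q=(1.0, -1.0), lj=((0.0, 0.0), (0.0, 0.0))):
        atoms = [Atom(0, "C", 12.0, q[0], *lj[0], "ML"),
                 Atom(1, "C", 12.0, q[1], *lj[1], "MM")]

        class Dummy:
            def evaluate(self, elements, coords):
                return 0.0, np.zeros_like(coords)

        return System(atoms=atoms, ml_potential=Dummy())

    def test_full_coupling_matches_coulomb(self):
        s = self._pair()
        f = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        e, _, _ = coupling_energy_forces(s, f, 1.0)
        assert e == pytest.approx(-COULOMB_CONSTANT / 2.0, rel=1e-12)

    @pytest.mark.parametrize("form", ["linear", "softcore"])
    def test_decoupled_endpoint_exactly_zero(self, form):
        s = self._pair()
        f = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        e, forces, _ = coupling_energy_forces(s, f, 0.0, form)
        assert e == 0.0
        assert np.all(forces == 0.0)

    def test_linear_midpoint(self):
        s = self._pair()
        f = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        e, _, dvdl = coupling_energy_forces(s, f, 0.5, "linear")
        assert e == pytest.approx(-COULOMB_CONSTANT / 4.0, rel=1e-12)
        assert dvdl == pytest.approx(-COULOMB_CONSTANT / 2.0, rel=1e-12)

    def test_forms_agree_at_full_coupling(self):
        sigma, eps = 3.2, 0.2
        s6 = sigma**6
        s = self._pair(q=(0.5, -0.3), lj=((4 * eps * s6 * s6, 4 * eps * s6),) * 2)
        f = Frame(np.array([[0.0, 0, 0], [3.1, 0.4, -0.2]]))
        e_lin = coupling_energy_forces(s, f, 1.0, "linear")[0]
        e_sc = coupling_energy_forces(s, f, 1.0, "softcore")[0]
        assert e_sc == pytest.approx(e_lin, abs=1e-10)

    def test_lj_zero_crossing_at_sigma(self):
        sigma, eps = 3.0, 0.5
        s6 = sigma**6
        s = self._pair(q=(0.0, 0.0), lj=((4 * eps * s6 * s6, 4 * eps * s6),) * 2)
        f = Frame(np.array([[0.0, 0, 0], [sigma, 0, 0]]))
        e, _, _ = coupling_energy_forces(s, f, 1.0)
        assert e == pytest.approx(0.0, abs=1e-10)

    def test_lambda_out_of_range(self):
        s = self._pair()
        f = Frame(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        with pytest.raises(ValueError, match="lambda"):
            coupling_energy_forces(s, f, 1.2)


class TestSurrogateML:
    def test_single_atom_no_terms(self, rng):
        from mlmm.potentials import SurrogateMLParams

        p = SurrogateMLParams(elements=["C"], charges=[0.0], lj_A=[0.0], lj_B=[0.0])
        e, f = surrogate_ml_energy_forces(p, ["C"], np.zeros((1, 3)))
        assert e == 0.0

    def test_diatomic_at_equilibrium(self):
        from mlmm.potentials import SurrogateMLParams

        p = SurrogateMLParams(elements=["C", "C"], charges=[0.0, 0.0],
                              lj_A=[0.0, 0.0], lj_B=[0.0, 0.0],
                              bonded_terms=[BondedTerm("bond", (0, 1), 300.0, 1.5)],
                              exclusions={(0, 1)})
        e, f = surrogate_ml_energy_forces(p, ["C", "C"],
                                          np.array([[0.0, 0, 0], [1.5, 0, 0]]))
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() < 1e-10

    def test_cross_implementation_against_mm(self):
        """A displaced diatomic scores identically through the surrogate and
        through the MM force field with the same parameters."""
        from mlmm.potentials import SurrogateMLParams

        coords = np.array([[0.0, 0, 0], [1.73, 0.2, -0.1]])
        p = SurrogateMLParams(elements=["C", "C"], charges=[0.2, -0.2],
                              lj_A=[1e5, 1e5], lj_B=[500.0, 500.0],
                              bonded_terms=[BondedTerm("bond", (0, 1), 300.0, 1.5)])
        e_ml, f_ml = surrogate_ml_energy_forces(p, ["C", "C"], coords)
        atoms = [Atom(0, "C", 12.0, 0.2, 1e5, 500.0), Atom(1, "C", 12.0, -0.2, 1e5, 500.0)]
        mm = System(atoms=atoms, bonded_terms=[BondedTerm("bond", (0, 1), 300.0, 1.5)])
        e_mm, f_mm = mm_energy_forces(mm, Frame(coords))
        assert e_ml == pytest.approx(e_mm, rel=1e-12)
        np.testing.assert_allclose(f_ml, f_mm, rtol=1e-12)

    def test_element_mismatch_rejected(self):
        from mlmm.potentials import SurrogateMLParams

        p = SurrogateMLParams(elements=["C", "C"], charges=[0.0, 0.0],
                              lj_A=[0.0, 0.0], lj_B=[0.0, 0.0])
        with pytest.raises(ValueError, match="element mismatch"):
            surrogate_ml_energy_forces(p, ["C", "N"], np.zeros((2, 3)))

    def test_contract_returns_single_scalar_and_forces(self, hybrid):
        system, frame = hybrid
        out = system.ml_potential.evaluate(system.ml_elements(),
                                           frame.coordinates[system.ml_indices])
        assert len(out) == 2
        energy, forces = out
        assert np.isscalar(energy) or np.ndim(energy) == 0
        assert forces.shape == (len(system.ml_indices), 3)


class TestEnergyReport:
    def test_zero_velocities_zero_kinetic(self, hybrid):
        system, frame = hybrid
        rep = total_energy_report(system, frame, 0.5)
        assert rep.E_kinetic == 0.0

    def test_summation_invariant_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EnergyReport(1.0, 1.0, 1.0, 1.0, 5.0)

    def test_report_components_sum(self, hybrid, rng):
        system, frame = hybrid
        f = Frame(frame.coordinates, 0.01 * rng.standard_normal(frame.coordinates.shape))
        rep = total_energy_report(system, f, 0.9, "softcore")
        assert rep.E_total == pytest.approx(
            rep.E_ML + rep.E_MM + rep.E_coupling + rep.E_kinetic, rel=1e-12)
        assert rep.E_kinetic > 0
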