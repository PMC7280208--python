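"""SE-AUC equilibrium model, global K_D fit, mass action, complex decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aucsas import equilibrium as eq
from aucsas import synthetic
from aucsas.profiles_io import ComponentTable, ScatteringProfile


@pytest.fixture()
def system():
    return synthetic.default_equilibrium_system(KD_uM=10.0)


RADII = np.linspace(6.90, 7.15, 100)


class TestSeModel:
    def test_zero_speed_is_flat(self, system):
        a = eq.se_model(RADII, 0.0 + 1e-30, system, 1e-4, 1e-4, 1e-5)
        np.testing.assert_allclose(a, a[0], rtol=1e-12)
        # and equals the sum of the three reference terms
        ab = system.AB
        expected = (system.A.epsilon * 1e-4 + system.B.epsilon * 1e-4
                    + ab.epsilon * 1e-4 * 1e-4 / 1e-5)
        assert a[0] == pytest.approx(expected, rel=1e-12)

    def test_neutral_buoyancy_is_flat(self):
        sp = eq.Species("X", M=10000.0, vbar=1.0, epsilon=1000.0)
        system = eq.EquilibriumSystem(A=sp, B=sp, solvent_density=1.0)
        a = eq.se_model(RADII, 30000.0, system, 1e-4, 1e-4, 1e-5)
        np.testing.assert_allclose(a, a[0], rtol=1e-12)

    def test_infinite_kd_removes_complex_term(self, system):
        a_two = eq.se_model(RADII, 20000.0, system, 1e-4, 1e-4, 1e30)
        ab = system.AB
        dr2 = RADII ** 2 - RADII[0] ** 2
        manual = sum(
            sp.epsilon * 1e-4 * np.exp(
                eq._reduced_buoyancy(2 * np.pi * 20000 / 60, sp.M, sp.vbar,
                                     system.solvent_density, system.temperature) * dr2)
            for sp in (system.A, system.B))
        np.testing.assert_allclose(a_two, manual, rtol=1e-10)

    def test_higher_speed_steeper_gradient(self, system):
        ratios = []
        for rpm in (20000.0, 30000.0, 35000.0):
            a = eq.se_model(RADII, rpm, system, 1e-4, 1e-4, 1e-5)
            ratios.append(a[-1] / a[0])
        assert ratios[0] < ratios[1] < ratios[2]

    def test_negative_reference_concentration_rejected(self, system):
        with pytest.raises(ValueError):
            eq.se_model(RADII, 20000.0, system, -1e-4, 1e-4, 1e-5)


class TestMassAction:
    def test_tight_binding_limit(self):
        fa, fb, ab = eq.mass_action(1e-12, 100.0, 100.0)
        assert ab == pytest.approx(100.0, rel=1e-6)
        assert fa == pytest.approx(0.0, abs=1e-4)

    def test_no_binding_limit(self):
        fa, fb, ab = eq.mass_action(1e12, 100.0, 100.0)
        assert ab == pytest.approx(0.0, abs=1e-6)
        assert fa == pytest.approx(100.0, rel=1e-6)

    def test_reference_point(self):
        """Equimolar 100 µM at K_D = 10 µM: the quadratic's physical root."""
        fa, fb, ab = eq.mass_action(10.0, 100.0, 100.0)
        assert fa == pytest.approx(27.016, abs=1e-3)
        assert ab == pytest.approx(72.984, abs=1e-3)

    @given(st.floats(0.01, 1e4), st.floats(0.0, 1e3), st.floats(0.0, 1e3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conservation_and_kd_relation(self, kd, ta, tb):
        fa, fb, ab = eq.mass_action(kd, ta, tb)
        assert fa >= -1e-12 and fb >= -1e-12 and ab >= -1e-12
        assert fa + ab == pytest.approx(ta, rel=1e-9, abs=1e-9)
        assert fb + ab == pytest.approx(tb, rel=1e-9, abs=1e-9)
        if ab > 1e-12:
            assert fa * fb / ab == pytest.approx(kd, rel=1e-9)


class TestGlobalFitKd:
    def test_noiseless_single_scan_exact(self, system):
        scans, truth = synthetic.make_se_scans(
            system, speeds_rpm=(20000.0,), loadings_uM=((100.0, 100.0),),
            noise_AU=0.0)
        fit = eq.global_fit_kd(scans, system)
        assert fit.KD_uM == pytest.approx(10.0, rel=1e-6)

    def test_three_by_three_design_within_ten_percent(self, system):
        scans, truth = synthetic.make_se_scans(system, seed=1)
        fit = eq.global_fit_kd(scans, system, sigma_AU=0.005)
        assert fit.KD_uM == pytest.approx(10.0, rel=0.10)
        assert fit.KD_err_uM > 0
        assert len(fit.per_scan) == 9

    def test_wrong_species_masses_inflate_chi2(self, system):
        """Fitting with halved molecular weights cannot reproduce the radial
        gradients; the misfit shows as a grossly elevated chi-square."""
        scans, _ = synthetic.make_se_scans(system, seed=2)
        good = eq.global_fit_kd(scans, system, sigma_AU=0.005)
        wrong = eq.EquilibriumSystem(
            A=eq.Species("A", M=0.5 * system.A.M, vbar=system.A.vbar,
                         epsilon=system.A.epsilon),
            B=eq.Species("B", M=0.5 * system.B.M, vbar=system.B.vbar,
                         epsilon=system.B.epsilon),
            solvent_density=system.solvent_density,
            temperature=system.temperature)
        bad = eq.global_fit_kd(scans, wrong, sigma_AU=0.005)
        assert good.chi2_reduced < 1.5
        assert bad.chi2_reduced > 100 * good.chi2_reduced

    def test_estimator_consistency_and_coverage(self, system):
        """Forward simulation -> inverse fit is consistent: small bias and
        roughly nominal 68% coverage of the 1-sigma interval."""
        rels, hits = [], 0
        n_rep = 200
        noise = 0.001  # precise optics: second-order estimator bias negligible
        for k in range(n_rep):
            scans, _ = synthetic.make_se_scans(system, noise_AU=noise,
                                               seed=10_000 + k, n_r=60)
            fit = eq.global_fit_kd(scans, system, sigma_AU=noise)
            rels.append(fit.KD_uM / 10.0 - 1.0)
            if abs(fit.KD_uM - 10.0) <= fit.KD_err_uM:
                hits += 1
        assert abs(np.mean(rels)) < 0.02
        assert 0.55 <= hits / n_rep <= 0.85


class TestDecomposeComplex:
    def test_pure_complex_identity(self, system):
        iA, iB, iAB = synthetic.default_equilibrium_profiles(system)
        c = 1.3
        i_exp = ScatteringProfile(iAB.q, iAB.intensity * c, iAB.sigma * c,
                                  concentration=c)
        conc = eq.Concentrations(c_A=0.0, c_B=0.0, c_AB=c)
        out = eq.decompose_complex(i_exp, iA, iB, conc)
        np.testing.assert_allclose(out.i_AB.intensity, iAB.intensity, rtol=1e-12)

    def test_zero_complex_concentration_rejected(self, system):
        iA, iB, iAB = synthetic.default_equilibrium_profiles(system)
        with pytest.raises(ValueError):
            eq.decompose_complex(iAB, iA, iB, eq.Concentrations(0.1, 0.1, 0.0))

    def test_generator_round_trip_within_sigma(self, system):
        iA, iB, iAB = synthetic.default_equilibrium_profiles(system)
        i_exp, truth = synthetic.make_equilibrium_saxs(
            iA, iB, iAB, system, KD_uM=10.0, loading_uM=(100.0, 100.0), seed=3)
        out = eq.decompose_complex(i_exp, iA, iB, truth["concentrations"])
        z = (out.i_AB.intensity - iAB.intensity) / out.i_AB.sigma
        assert np.max(np.abs(z)) < 4.0
        assert np.sqrt(np.mean(z ** 2)) < 1.5

    def test_reconstruction_identity(self, system):
        """Recomposing c*i_exp from the decomposed parts is exact."""
        iA, iB, iAB = synthetic.default_equilibrium_profiles(system)
        i_exp, truth = synthetic.make_equilibrium_saxs(
            iA, iB, iAB, system, KD_uM=10.0, loading_uM=(100.0, 100.0), seed=4)
        cc = truth["concentrations"]
        out = eq.decompose_complex(i_exp, iA, iB, cc)
        recon = (cc.c_A * iA.intensity + cc.c_B * iB.intensity
                 + cc.c_AB * out.i_AB.intensity)
        c = i_exp.concentration
        np.testing.assert_allclose(recon, c * i_exp.per_mass().intensity, rtol=1e-12)

    def test_linearity(self, system):
        iA, iB, iAB = synthetic.default_equilibrium_profiles(system)
        i_exp, truth = synthetic.make_equilibrium_saxs(
            iA, iB, iAB, system, KD_uM=10.0, loading_uM=(100.0, 100.0), seed=5)
        cc = truth["concentrations"]
        one = eq.decompose_complex(i_exp, iA, iB, cc)
        two = eq.decompose_complex(i_exp.scaled(2.0), iA.scaled(2.0),
                                   iB.scaled(2.0), cc)
        np.testing.assert_allclose(two.i_AB.intensity, 2.0 * one.i_AB.intensity,
                                   rtol=1e-12)


class TestAggregationCheck:
    def test_expected_species_pass(self, system):
        table = ComponentTable.from_fractions({1: 0.4, 2: 0.35, 3: 0.25})
        # masses matching A, B, AB
        from aucsas.profiles_io import ComponentEntry
        table = ComponentTable((
            ComponentEntry(1, 0.4, mass=system.A.M),
            ComponentEntry(2, 0.35, mass=system.B.M),
            ComponentEntry(3, 0.25, mass=system.M_AB)))
        out = eq.check_aggregation_free(table, system)
        assert out.passed and out.extra_fraction == 0.0

    def test_five_percent_extra_fails(self, system):
        from aucsas.profiles_io import ComponentEntry
        table = ComponentTable((
            ComponentEntry(1, 0.60, mass=system.A.M),
            ComponentEntry(2, 0.35, mass=system.B.M),
            ComponentEntry(3, 0.05, mass=5 * system.M_AB)))
        assert not eq.check_aggregation_free(table, system).passed

    def test_one_percent_extra_warns_but_passes(self, system):
        from aucsas.profiles_io import ComponentEntry
        table = ComponentTable((
            ComponentEntry(1, 0.64, mass=system.A.M),
            ComponentEntry(2, 0.35, mass=system.B.M),
            ComponentEntry(3, 0.01, mass=5 * system.M_AB)))
        out = eq.check_aggregation_free(table, system)
        assert out.passed and out.warnings
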