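"""Monomer-extraction pipeline: forward fraction, stitching, refinement, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aucsas
from aucsas import synthetic
from aucsas.guinier import GuinierError
from aucsas.monomer_extraction import (ExtractionConfig, assign_high_q,
                                       connect_low_q, extract_monomer,
                                       forward_fraction,
                                       monomer_forward_intensity, refine)
from aucsas.profiles_io import ComponentTable, ScatteringProfile


class TestForwardFraction:
    def test_pure_monomer(self):
        assert forward_fraction(ComponentTable.from_fractions({1: 1.0})) == 1.0

    def test_ten_percent_dimer(self):
        t = ComponentTable.from_fractions({1: 0.9, 2: 0.1})
        assert forward_fraction(t) == pytest.approx(0.9 / 1.1, rel=1e-12)

    def test_matches_bruteforce_forward_intensities(self, q_grid):
        """t1 equals c1*i1(0)/(c*i_mix(0)) computed from simulated forward
        intensities, where the j-mer per-mass forward intensity is j*i1(0)."""
        fractions = {1: 0.90, 2: 0.06, 3: 0.03, 4: 0.01}
        table = ComponentTable.from_fractions(fractions)
        i1_0 = 0.734  # arbitrary per-mass forward intensity
        mix_0 = sum(w * j * i1_0 for j, w in fractions.items())
        expected = fractions[1] * i1_0 / mix_0
        assert forward_fraction(table) == pytest.approx(expected, abs=1e-10)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_unit_invariance(self, scale):
        """t1 depends only on concentration ratios."""
        base = {1: 0.9, 2: 0.07, 3: 0.03}
        scaled = ComponentTable.from_fractions(
            {j: w * scale for j, w in base.items()}, normalize=True)
        assert forward_fraction(scaled) == pytest.approx(
            forward_fraction(ComponentTable.from_fractions(base)), rel=1e-12)


class TestMonomerForwardIntensity:
    def test_monomer_only_identity(self):
        t = ComponentTable.from_fractions({1: 1.0})
        i1_0, agg = monomer_forward_intensity(5.0, 2.0, t)
        assert i1_0 == pytest.approx(5.0)
        assert agg == 0.0

    def test_aggregate_share_arithmetic(self):
        """c*i_exp(0) = 110 with 10% dimer: monomer keeps 90, aggregates 20."""
        t = ComponentTable.from_fractions({1: 0.9, 2: 0.1})
        c = 1.0
        i1_0, agg = monomer_forward_intensity(110.0, c, t)
        assert 0.9 * c * i1_0 == pytest.approx(90.0, rel=1e-12)
        assert agg == pytest.approx(20.0, rel=1e-12)


class TestAssignHighQ:
    def test_monomer_only_matches_curve(self, sphere_profile):
        out = assign_high_q(sphere_profile, q_star=0.05)
        mask = sphere_profile.q > 0.05
        np.testing.assert_array_equal(out.intensity, sphere_profile.intensity[mask])

    def test_q_star_beyond_range_errors(self, sphere_profile):
        with pytest.raises(ValueError):
            assign_high_q(sphere_profile, q_star=0.5)

    def test_dimer_mixture_stays_within_model_bound(self):
        spec = synthetic.GeneratorSpec(fractions={1: 0.94, 2: 0.06},
                                       noise_rel=0.0, noise_floor=0.0)
        i_exp, truth = synthetic.make_mixture(spec)
        q_star = 1.0 / truth.Rg1
        high = assign_high_q(i_exp.per_mass(), q_star)
        i1_true = truth.i1.restrict(q_min=q_star, inclusive=False)
        dev = np.max(np.abs(high.intensity / i1_true.intensity - 1.0))
        assert dev < 0.02  # the Debye-model working bound


class TestConnectLowQ:
    def test_exact_guinier_self_consistency(self, guinier_profile):
        q_star = 1.0 / 27.2
        high = guinier_profile.restrict(q_min=q_star, inclusive=False)
        conn = connect_low_q(1.0, high, q_star, q_full=guinier_profile.q)
        assert conn.Rg1_star == pytest.approx(27.2, rel=1e-3)
        np.testing.assert_allclose(conn.stitched.intensity,
                                   guinier_profile.intensity, rtol=2e-4)

    def test_sphere_tail_recovers_true_curve(self, sphere_profile):
        rg1 = np.sqrt(3.0 / 5.0) * 35.1
        q_star = 1.0 / rg1
        high = sphere_profile.restrict(q_min=q_star, inclusive=False)
        conn = connect_low_q(1.0, high, q_star, q_full=sphere_profile.q)
        # pre-refinement candidate: slope matching alone gets within ~1.5%
        np.testing.assert_allclose(conn.stitched.intensity,
                                   sphere_profile.intensity, rtol=0.015)

    def test_inconsistent_forward_intensity_warns(self, sphere_profile):
        rg1 = np.sqrt(3.0 / 5.0) * 35.1
        q_star = 1.0 / rg1
        high = sphere_profile.restrict(q_min=q_star, inclusive=False)
        conn = connect_low_q(2.0, high, q_star, q_full=sphere_profile.q)
        assert conn.mismatch > 0.05
        assert conn.warnings

    def test_rising_curve_has_no_connection(self, q_grid):
        prof = ScatteringProfile(q_grid, 1.0 + q_grid, np.full_like(q_grid, 0.01))
        with pytest.raises(GuinierError):
            connect_low_q(1.0, prof, q_star=q_grid[0], q_full=q_grid)


class TestRefine:
    def test_consistent_input_converges_immediately(self, guinier_profile):
        q_star = 1.0 / 27.2
        high = guinier_profile.restrict(q_min=q_star, inclusive=False)
        conn = connect_low_q(1.0, high, q_star, q_full=guinier_profile.q)
        _, fit, n_iter, _, _ = refine(conn.stitched, 1.0, conn.q_c,
                                      rg_init=conn.Rg1_star)
        assert n_iter <= 2
        assert fit.Rg == pytest.approx(conn.Rg1_star, rel=5e-3)


class TestExtractMonomer:
    def test_monomer_only_is_identity_up_to_noise(self):
        spec = synthetic.GeneratorSpec(fractions={1: 1.0}, seed=11)
        i_exp, truth = synthetic.make_mixture(spec)
        res = extract_monomer(i_exp, ComponentTable.from_fractions({1: 1.0}))
        assert res.t1 == 1.0
        assert res.Rg1 == pytest.approx(truth.Rg1, rel=0.01)
        # above the connection point the output is the measurement itself
        high = res.i1.q >= res.q_c
        np.testing.assert_allclose(res.i1.intensity[high],
                                   i_exp.per_mass().intensity[high], rtol=1e-12)

    def test_six_percent_dimer_recovery(self):
        spec = synthetic.GeneratorSpec(fractions={1: 0.94, 2: 0.06}, seed=4)
        i_exp, truth = synthetic.make_mixture(spec)
        res = extract_monomer(i_exp, ComponentTable.from_fractions({1: 0.94, 2: 0.06}))
        assert res.Rg1 == pytest.approx(truth.Rg1, rel=0.01)
        assert res.i1_0 == pytest.approx(truth.i1_0, rel=0.02)
        # aggregate residual is positive at low q where aggregates dominate
        low = res.aggregate_intensity.q < res.q_star
        assert np.all(res.aggregate_intensity.intensity[low] > 0)

    def test_conservation_identity(self, default_mixture):
        """c1*i1(q) + c_a*i_a(q) = c*i_exp(q) exactly on the grid."""
        i_exp, truth, table = default_mixture
        res = extract_monomer(i_exp, table)
        c = i_exp.concentration
        w1 = table.monomer_fraction
        recon = w1 * c * res.i1.intensity + res.aggregate_intensity.intensity
        np.testing.assert_allclose(recon, c * i_exp.per_mass().intensity, rtol=1e-12)

    def test_forward_conservation(self, default_mixture):
        i_exp, truth, table = default_mixture
        res = extract_monomer(i_exp, table)
        c = i_exp.concentration
        ci_exp0 = c * res.guinier_exp.I0
        c1_i1_0 = table.monomer_fraction * c * res.i1_0
        assert c1_i1_0 == pytest.approx(res.t1 * ci_exp0, rel=1e-12)

    def test_extracted_rg_below_apparent_rg(self, default_mixture):
        """Aggregates inflate the apparent size; extraction removes that."""
        i_exp, truth, table = default_mixture
        res = extract_monomer(i_exp, table)
        assert res.Rg1 < res.guinier_exp.Rg

    def test_q_star_not_beyond_connection_point(self, default_mixture):
        i_exp, truth, table = default_mixture
        res = extract_monomer(i_exp, table)
        assert 0 < res.q_star <= res.q_c
        assert 0 < res.t1 <= 1.0

    def test_heavy_aggregation_warns(self):
        fr = {1: 0.80, 2: 0.20}
        spec = synthetic.GeneratorSpec(fractions=fr, seed=5)
        i_exp, _ = synthetic.make_mixture(spec)
        res = extract_monomer(i_exp, ComponentTable.from_fractions(fr))
        assert any("validity boundary" in w for w in res.warnings)

    def test_extreme_aggregation_refused(self):
        fr = {1: 0.70, 2: 0.30}
        spec = synthetic.GeneratorSpec(fractions=fr, seed=5)
        i_exp, _ = synthetic.make_mixture(spec)
        with pytest.raises(ValueError, match="hard cap"):
            extract_monomer(i_exp, ComponentTable.from_fractions(fr))

    def test_upturn_blocks_unless_overridden(self, q_grid):
        i = np.exp(-(q_grid * 27.2) ** 2 / 3.0) + 0.1 * (q_grid[0] / q_grid) ** 2
        prof = ScatteringProfile(q_grid, i, 0.01 * i, concentration=1.0)
        table = ComponentTable.from_fractions({1: 0.95, 2: 0.05})
        with pytest.raises(GuinierError, match="upturn"):
            extract_monomer(prof, table)
        res = extract_monomer(prof, table, ExtractionConfig(allow_upturn=True))
        assert any("upturn" in w for w in res.warnings)

    def test_report_is_serializable(self, default_mixture):
        import json
        i_exp, truth, table = default_mixture
        rep = extract_monomer(i_exp, table).report()
        assert json.loads(json.dumps(rep))["t1"] == pytest.approx(rep["t1"])
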