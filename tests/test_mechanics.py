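"""Thin-wall extension–inflation analysis: stresses, stretches, in vivo
stretch estimation, MAP interpolation, tangent modulus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from arterymech import mechanics as mech
from arterymech.errors import (
    ExtrapolationRefusedError,
    InfeasibleDeformationError,
    InsufficientDataError,
    InvalidGeometryError,
)

MMHG = mech.MMHG_TO_KPA


class TestGeometry:
    @pytest.mark.parametrize(
        "oc, ic, do, di",
        [
            (math.pi, 0.8 * math.pi, 1.0, 0.8),
            (2 * math.pi, math.pi, 2.0, 1.0),
        ],
    )
    def test_from_ring_circumferences(self, oc, ic, do, di):
        g = mech.geometry_from_ring_circumferences(oc, ic)
        assert g.outer_diameter == pytest.approx(do, rel=1e-12)
        assert g.inner_diameter == pytest.approx(di, rel=1e-12)
        assert g.wall_thickness == pytest.approx((do - di) / 2, rel=1e-12)

    @pytest.mark.parametrize("oc, ic", [(1.0, 1.2), (0.0, -1.0), (-2.0, -3.0)])
    def test_invalid_circumferences(self, oc, ic):
        with pytest.raises(InvalidGeometryError):
            mech.geometry_from_ring_circumferences(oc, ic)


class TestKinematics:
    def test_identity_configuration(self, simple_geometry):
        di = mech.inner_diameter(simple_geometry.outer_diameter, simple_geometry, 1.0)
        assert di == pytest.approx(simple_geometry.inner_diameter, abs=1e-12)

    def test_inner_diameter_direct_evaluation(self, simple_geometry):
        # sqrt(1.1^2 - 0.36/2), incompressible wall under axial stretch 2
        di = mech.inner_diameter(1.1, simple_geometry, 2.0)
        assert di == pytest.approx(1.0148891565092219, rel=1e-12)

    def test_infeasible_deformation(self, simple_geometry):
        with pytest.raises(InfeasibleDeformationError):
            mech.inner_diameter(0.5, simple_geometry, 1.0)

    def test_circumferential_stretch_conventions(self, simple_geometry):
        assert mech.circumferential_stretch(1.0, 0.8, simple_geometry) == 1.0
        lt = mech.circumferential_stretch(1.1, 1.0148891565092219, simple_geometry)
        assert lt == pytest.approx(2.114889156509222 / 1.8, rel=1e-12)
        inner = mech.circumferential_stretch(
            1.1, 1.0148891565092219, simple_geometry, convention="inner-wall"
        )
        assert inner == pytest.approx(1.0148891565092219 / 0.8, rel=1e-12)

    @given(scale=hst.floats(min_value=0.5, max_value=3.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_stretch_homogeneity(self, scale):
        # doubling both diameters doubles the mid-wall stretch
        g = mech.UnloadedGeometry(1.0, 0.8)
        base = mech.circumferential_stretch(1.2, 1.1, g)
        assert mech.circumferential_stretch(1.2 * scale, 1.1 * scale, g) == (
            pytest.approx(base * scale, rel=1e-12)
        )


class TestCauchyStresses:
    def test_unloaded_state_is_stress_free(self):
        assert mech.cauchy_stresses(0.0, 0.45, 0.09, 0.0) == (0.0, 0.0)

    def test_circumferential_stress_hand_value(self):
        # σθ = P·ri/h with P = 120 mmHg = 15.998688 kPa
        st, _ = mech.cauchy_stresses(120.0, 0.45, 0.09, 0.0)
        assert st == pytest.approx(120 * MMHG * 0.45 / 0.09, rel=1e-12)
        assert st == pytest.approx(79.99, abs=0.01)

    def test_axial_stress_hand_value(self):
        # σz = (f + P·π·ri²)/(π·h·(2ri + h)), unit-checked in N/m²
        _, sz = mech.cauchy_stresses(100.0, 0.45, 0.09, 8.0)
        p_pa = 100 * MMHG * 1e3
        expect = (8e-3 + p_pa * math.pi * 0.45e-3**2) / (
            math.pi * 0.09e-3 * (2 * 0.45e-3 + 0.09e-3)
        )
        assert sz == pytest.approx(expect / 1e3, rel=1e-9)
        assert sz == pytest.approx(58.9, abs=0.1)


def _record(lz, rows):
    return mech.InflationRecord(axial_stretch=lz, samples=tuple(rows))


class TestProcessRecord:
    def test_cardinality_and_incompressibility(self, simple_geometry):
        rows = [(p, 1.05 + 0.001 * p, 2.0) for p in range(0, 121, 10)]
        curve = mech.process_record(_record(1.5, rows), simple_geometry)
        assert len(curve.states) == len(rows)
        for s in curve.states:
            resid = mech.incompressibility_residual(s, simple_geometry)
            assert abs(resid) <= 1e-9

    def test_empty_record_rejected(self, simple_geometry):
        with pytest.raises((InsufficientDataError, ValueError)):
            mech.process_record(_record(1.5, []), simple_geometry)

    def test_infeasible_sample_reports_index(self, simple_geometry):
        rows = [(0.0, 1.05, 0.0), (10.0, 0.3, 0.0)]
        with pytest.raises(InfeasibleDeformationError, match="sample 1"):
            mech.process_record(_record(1.0, rows), simple_geometry)


class TestInVivoStretch:
    def _dataset(self, geometry, force_patterns):
        recs = []
        for lz, forces in force_patterns:
            rows = [
                (10.0 * i, 1.05 + 0.002 * i, f) for i, f in enumerate(forces)
            ]
            recs.append(_record(lz, rows))
        return mech.BiaxialDataset(
            geometry=geometry, records=tuple(recs), map_pressure=100.0
        )

    def test_constructed_plateau(self, simple_geometry):
        ds = self._dataset(
            simple_geometry,
            [
                (1.71, [5.0, 4.0, 3.0, 2.0]),   # decreasing
                (1.80, [4.0, 4.01, 4.0, 4.01]),  # constant
                (1.89, [4.0, 5.0, 6.0, 7.0]),   # increasing
            ],
        )
        est = mech.estimate_in_vivo_stretch(ds)
        assert est.value == 1.80
        assert est.within_threshold

    def test_no_plateau_flagged(self, simple_geometry):
        ds = self._dataset(
            simple_geometry,
            [(1.7, [0.0, 1.0, 2.0]), (1.8, [0.0, 0.5, 1.0]), (1.9, [0, 2, 4])],
        )
        est = mech.estimate_in_vivo_stretch(ds)
        assert est.value == 1.8
        assert not est.within_threshold

    def test_requires_two_records(self, simple_geometry):
        ds = mech.BiaxialDataset(
            geometry=simple_geometry,
            records=(_record(1.8, [(0, 1.05, 1), (10, 1.06, 1)]),),
            map_pressure=100.0,
        )
        with pytest.raises(InsufficientDataError):
            mech.estimate_in_vivo_stretch(ds)

    def test_std_metric_option(self, simple_geometry):
        ds = self._dataset(
            simple_geometry,
            [(1.7, [0.0, 1.0]), (1.8, [2.0, 2.0]), (1.9, [0, 3])],
        )
        est = mech.estimate_in_vivo_stretch(ds, metric="std")
        assert est.value == 1.8
        assert est.force_variation == 0.0


class TestStateAtPressure:
    @pytest.fixture()
    def curve(self, simple_geometry):
        rows = [(p, 1.05 + 0.002 * p, 2.0 + 0.01 * p) for p in range(0, 121, 10)]
        return mech.process_record(_record(1.5, rows), simple_geometry)

    def test_exact_sample_returned(self, curve):
        st = mech.state_at_pressure(curve, 50.0)
        assert st is curve.states[5]

    def test_midpoint_is_mean(self, curve):
        st = mech.state_at_pressure(curve, 55.0)
        a, b = curve.states[5], curve.states[6]
        assert st.circ_stress == pytest.approx((a.circ_stress + b.circ_stress) / 2)
        assert st.outer_diameter == pytest.approx(
            (a.outer_diameter + b.outer_diameter) / 2
        )

    def test_extrapolation_refused(self, curve):
        with pytest.raises(ExtrapolationRefusedError):
            mech.state_at_pressure(curve, 130.0)


class TestTangentModulus:
    def _curve_from_function(self, sigma_of_lt, geometry, lz=1.5):
        # build states directly so σθ(λθ) follows the prescribed function
        states = []
        for i, p in enumerate(range(0, 121, 10)):
            lt = 1.0 + 0.005 * i
            states.append(
                mech.DeformedState(
                    pressure=float(p), outer_diameter=1.0, inner_diameter=0.9,
                    wall_thickness=0.05, circ_stretch=lt, axial_stretch=lz,
                    circ_stress=sigma_of_lt(lt), axial_stress=0.0,
                )
            )
        return mech.StressStrainCurve(axial_stretch=lz, states=tuple(states))

    def test_linear_curve_exact(self, simple_geometry):
        curve = self._curve_from_function(
            lambda lt: 450.0 * (lt - 1.0), simple_geometry
        )
        assert mech.tangent_modulus(curve, 60.0) == pytest.approx(0.45, rel=1e-9)

    def test_quadratic_curve_exact(self, simple_geometry):
        a = 300.0
        curve = self._curve_from_function(lambda lt: a * lt**2, simple_geometry)
        lt60 = 1.0 + 0.005 * 6
        assert mech.tangent_modulus(curve, 60.0) == pytest.approx(
            2 * a * lt60 / 1000.0, rel=1e-9
        )

    def test_finite_difference_option(self, simple_geometry):
        curve = self._curve_from_function(
            lambda lt: 450.0 * (lt - 1.0), simple_geometry
        )
        fd = mech.tangent_modulus(curve, 60.0, method="finite-difference")
        assert fd == pytest.approx(0.45, rel=1e-9)

    def test_needs_three_states(self, simple_geometry):
        rows = [(0.0, 1.05, 1.0), (10.0, 1.06, 1.0)]
        curve = mech.process_record(_record(1.5, rows), simple_geometry)
        with pytest.raises(InsufficientDataError):
            mech.tangent_modulus(curve, 5.0)


class TestThinWallConsistency:
    def test_mean_stress_matches_thick_wall_solution(self):
        """Eq.-1-style σθ = P·ri/h agrees with the through-wall mean
        circumferential stress of an incompressible neo-Hookean cylinder
        (radial equilibrium integrated numerically) within 5% for
        h/ri ≤ 0.15."""
        c = 30.0  # kPa
        lz = 1.6
        geo = mech.UnloadedGeometry(1.0, 0.9)  # thin unloaded wall
        Ri, Ro = geo.inner_diameter / 2, geo.outer_diameter / 2
        for ri in (0.55, 0.65, 0.8):
            # incompressible mapping r(R) and stretches
            R = np.linspace(Ri, Ro, 4001)
            r = np.sqrt(ri**2 + (R**2 - Ri**2) / lz)
            lt = r / R
            lr = 1.0 / (lt * lz)
            dev = c * (lt**2 - lr**2)  # σθ − σr for neo-Hookean
            # pressure from radial equilibrium: P = ∫ (σθ−σr)/r dr
            dr = np.gradient(r)
            p_kpa = np.sum(dev / r * dr)
            # through-wall σθ(r): σr(r) = −P + ∫ri^r (σθ−σr)/r dr
            sr = -p_kpa + np.cumsum(dev / r * dr)
            sθ = sr + dev
            mean_sθ = np.sum(sθ * dr) / (r[-1] - r[0])
            h = r[-1] - r[0]
            assert h / ri <= 0.16
            thin = p_kpa * ri / h
            assert thin == pytest.approx(mean_sθ, rel=0.05)
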