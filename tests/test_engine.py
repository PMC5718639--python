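"""TG-43 engine: geometry functions, interpolation, forward/inverse identities."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import selectron43 as s
from selectron43.engine import VALIDITY_FLOOR_CM

POINT = s.GeometryModel("point")
LINE = s.GeometryModel("line", 0.15)


class TestBetaAngle:
    def test_transverse_value(self):
        # closed form on the transverse axis: beta = 2 arctan(L/2r)
        assert s.beta_angle(s.DosePoint(1, 90), 0.15) == pytest.approx(
            2 * math.atan(0.075), rel=1e-12
        )
        assert s.beta_angle(s.DosePoint(1, 90), 0.15) == pytest.approx(0.1497198, abs=1e-6)

    @given(
        r=st.floats(0.3, 10),
        theta=st.floats(1, 89),
        L=st.floats(0.01, 0.5),
    )
    def test_mirror_symmetry(self, r, theta, L):
        a = s.beta_angle(s.DosePoint(r, theta), L)
        b = s.beta_angle(s.DosePoint(r, 180 - theta), L)
        assert a == pytest.approx(b, rel=1e-12)
        assert 0 < a < math.pi

    @given(r=st.floats(0.5, 10), theta=st.floats(5, 175))
    def test_small_length_limit(self, r, theta):
        """beta/L -> sin(theta)/r as the line source shrinks to a point."""
        L = 1e-6
        beta = s.beta_angle(s.DosePoint(r, theta), L)
        assert beta / L == pytest.approx(
            math.sin(math.radians(theta)) / r, rel=1e-6
        )

    def test_axis_is_domain_error(self):
        with pytest.raises(s.DomainError, match="theta=0"):
            s.beta_angle(s.DosePoint(1, 0), 0.15)


class TestGeometryFactor:
    def test_point_inverse_square(self):
        assert s.geometry_factor(s.DosePoint(2, 37.0), POINT) == 0.25

    def test_line_values(self):
        assert s.geometry_factor(s.DosePoint(1, 90), LINE) == pytest.approx(
            0.998132, abs=1e-6
        )
        assert s.geometry_factor(s.DosePoint(1, 0), LINE) == pytest.approx(
            1.0056568, abs=1e-7
        )

    def test_continuous_across_axis(self):
        """Line model at theta just off 0 agrees with the axial branch to 0.1%."""
        for r in (0.5, 1.0, 5.0):
            on = s.geometry_factor(s.DosePoint(r, 0), LINE)
            near = s.geometry_factor(s.DosePoint(r, 0.05), LINE)
            assert near == pytest.approx(on, rel=1e-3)

    @given(r=st.floats(0.5, 10), theta=st.floats(0, 180))
    def test_converges_to_point_model(self, r, theta):
        tiny = s.GeometryModel("line", 1e-3)
        gl = s.geometry_factor(s.DosePoint(r, theta), tiny)
        gp = s.geometry_factor(s.DosePoint(r, theta), POINT)
        assert abs(gl / gp - 1) < 1e-4

    def test_axial_singularity(self):
        with pytest.raises(s.DomainError, match="singular"):
            s.geometry_factor(s.DosePoint(0.05, 0), LINE)


class TestRadialDose:
    def test_exact_at_nodes(self, bare):
        assert s.radial_dose(bare, 3.5) == 0.979
        assert s.radial_dose(bare, 1.0) == 1.0

    def test_missing_cell_bridged_linearly(self, bare):
        # bare table is blank at 2.5; neighbours are 0.998 (r=2) and 0.985 (r=3)
        assert s.radial_dose(bare, 2.5) == pytest.approx(0.9915, abs=1e-12)

    def test_normalisation_everywhere(self, library):
        for label in library.labels():
            assert s.radial_dose(library[label], 1.0) == 1.0

    def test_out_of_range(self, bare):
        with pytest.raises(s.RangeError, match="outside"):
            s.radial_dose(bare, 12.0)
        extrap = s.radial_dose(bare, 12.0, extrapolate=True)
        expected = 0.893 + (0.870 - 0.893) / 1.0 * (12.0 - 9.0)
        assert extrap == pytest.approx(expected, rel=1e-12)


class TestAnisotropy:
    def test_exact_at_nodes_and_normalised(self, measured):
        assert s.anisotropy(measured, s.DosePoint(3, 135)) == 0.948
        assert s.anisotropy(measured, s.DosePoint(3, 90)) == 1.0

    def test_linear_in_r_between_columns(self, measured):
        assert s.anisotropy(measured, s.DosePoint(4, 150)) == pytest.approx(
            0.9485, abs=1e-12
        )

    def test_theta_clamps_to_measured_span(self, measured):
        # below 15 deg the grid is clamped to the 15-degree row
        assert s.anisotropy(measured, s.DosePoint(3, 5)) == 0.903
        assert s.anisotropy(measured, s.DosePoint(3, 178)) == 0.902
        # at 2 cm the 30-degree cell is missing: interpolation bridges 15-45 deg
        assert s.anisotropy(measured, s.DosePoint(2, 20)) == pytest.approx(
            0.892 + (0.998 - 0.892) * 5 / 30, rel=1e-12
        )

    def test_radius_clamps(self, measured):
        assert s.anisotropy(measured, s.DosePoint(0.5, 45)) == 0.973
        assert s.anisotropy(measured, s.DosePoint(9, 165)) == 0.938

    def test_missing_grid_is_capability_error(self, bare):
        with pytest.raises(s.CapabilityError, match="anisotropy"):
            s.anisotropy(bare, s.DosePoint(3, 45))


class TestDoseRate:
    def test_reference_point_identity(self, library):
        for label in ("bare", "pos1", "measured"):
            ds = library[label]
            res = s.dose_rate(ds, 1.0, s.DosePoint(1, 90))
            assert res.dose_rate == ds.Lambda

    def test_hand_product(self, pos1):
        res = s.dose_rate(pos1, 1.0, s.DosePoint(2, 90), POINT)
        assert res.dose_rate == pytest.approx(1.095 * 0.25 * 0.997, rel=1e-12)
        assert res.dose_rate == pytest.approx(0.27293, abs=2e-5)

    @given(sk=st.floats(0.01, 100))
    def test_linear_in_source_strength(self, sk):
        bare = s.packaged_dataset("bare")
        p = s.DosePoint(4, 60)
        unit = s.dose_rate(bare, 1.0, p)
        scaled = s.dose_rate(bare, sk, p)
        assert scaled.dose_rate == pytest.approx(sk * unit.dose_rate, rel=1e-12)
        assert scaled.per_unit_sk == unit.per_unit_sk

    def test_validity_floor(self, bare):
        with pytest.raises(s.DomainError, match="validity"):
            s.dose_rate(bare, 1.0, s.DosePoint(VALIDITY_FLOOR_CM, 90))

    def test_range_error_names_failing_factor(self, bare):
        with pytest.raises(s.RangeError, match="radial dose function"):
            s.dose_rate(bare, 1.0, s.DosePoint(15, 90))

    def test_continuity_across_grid_nodes(self, measured):
        """No interpolation jumps at table nodes beyond float rounding."""
        for r in (2.0, 3.0, 5.0):
            for theta in (45.0, 135.0):
                at = s.dose_rate(measured, 1.0, s.DosePoint(r, theta)).dose_rate
                lo = s.dose_rate(measured, 1.0, s.DosePoint(r - 1e-9, theta)).dose_rate
                hi = s.dose_rate(measured, 1.0, s.DosePoint(r + 1e-9, theta)).dose_rate
                assert at == pytest.approx(lo, rel=1e-6)
                assert at == pytest.approx(hi, rel=1e-6)


class TestInverseOperations:
    def test_inverse_square_profile_gives_unit_g(self):
        profile = {r: 5.0 / r ** 2 for r in np.arange(0.5, 10.5, 0.5)}
        table = s.derive_g_from_transverse_profile(profile, POINT)
        np.testing.assert_allclose(table.g, 1.0, atol=1e-12)

    def test_exponential_profile_closed_form(self):
        mu = 0.03
        radii = np.arange(0.5, 10.5, 0.5)
        profile = {r: math.exp(-mu * (r - 1)) / r ** 2 for r in radii}
        table = s.derive_g_from_transverse_profile(profile, POINT)
        np.testing.assert_allclose(
            table.g, np.exp(-mu * (radii - 1)), rtol=1e-12
        )

    @pytest.mark.parametrize("model", [POINT, LINE])
    def test_forward_inverse_roundtrip_g(self, bare, model):
        radii = bare.radial.r_cm[~np.isnan(bare.radial.g)]
        profile = {
            float(r): s.dose_rate(bare, 1.0, s.DosePoint(float(r), 90), model).dose_rate
            for r in radii
        }
        table = s.derive_g_from_transverse_profile(profile, model)
        np.testing.assert_allclose(
            table.g, bare.radial.g[~np.isnan(bare.radial.g)], rtol=1e-12
        )

    def test_forward_inverse_roundtrip_F(self, measured):
        grid = measured.anisotropy
        model = POINT
        doses = {}
        for i, th in enumerate(grid.theta_deg):
            for j, r in enumerate(grid.r_cm):
                if not math.isnan(grid.F[i, j]):
                    doses[(float(r), float(th))] = s.dose_rate(
                        measured, 1.0, s.DosePoint(float(r), float(th)), model
                    ).dose_rate
        rec = s.derive_F_from_grid(doses, model)
        for i, th in enumerate(grid.theta_deg):
            for j, r in enumerate(grid.r_cm):
                if math.isnan(grid.F[i, j]):
                    continue
                got = rec.value_at_node(float(r), float(th))
                assert got == pytest.approx(grid.F[i, j], rel=1e-12)

    def test_isotropic_grid_gives_unit_F(self):
        doses = {
            (r, t): 3.0 / r ** 2
            for r in (1.0, 2.0, 5.0)
            for t in (0.0, 30.0, 90.0, 120.0, 180.0)
        }
        grid = s.derive_F_from_grid(doses, POINT)
        np.testing.assert_allclose(grid.F, 1.0, atol=1e-12)

    def test_halved_cone_recovered(self):
        def rate(r, t):
            return (0.5 if t < 30 else 1.0) / r ** 2

        doses = {
            (r, t): rate(r, t)
            for r in (1.0, 3.0)
            for t in (10.0, 20.0, 45.0, 90.0, 150.0)
        }
        grid = s.derive_F_from_grid(doses, POINT)
        for i, t in enumerate(grid.theta_deg):
            expected = 0.5 if t < 30 else 1.0
            np.testing.assert_allclose(grid.F[i], expected, rtol=1e-12)

    def test_missing_reference_samples_are_errors(self):
        with pytest.raises(s.NormalizationError, match="reference"):
            s.derive_g_from_transverse_profile({2.0: 1.0, 3.0: 0.5}, POINT)
        with pytest.raises(s.NormalizationError, match="r = 2.0"):
            s.derive_F_from_grid({(2.0, 45.0): 1.0}, POINT)
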