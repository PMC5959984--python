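import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srs_idp.geometry import SphericalTarget
from srs_idp.plan_model import (
    CalibrationError,
    PlanQuality,
    calibrate_radial_model,
    plan_quality_for,
    render_grid,
)


def quality(ci=1.0, gi=2.6, dmax=112.0):
    return PlanQuality(dmax_pct=dmax, dmean_pct=100.0, rtog_ci=ci, paddick_gi=gi)


class TestCalibration:
    def test_falloff_exponent_from_gradient_index(self):
        m = calibrate_radial_model(SphericalTarget(4.0), quality(gi=2.6), 15.0)
        assert m.k == pytest.approx(3 * math.log(2) / math.log(2.6), rel=1e-12)
        assert m.k == pytest.approx(2.176, abs=5e-4)

    def test_gi_of_8_gives_inverse_linear_falloff(self):
        m = calibrate_radial_model(SphericalTarget(2.0), quality(gi=8.0), 18.0)
        assert m.k == pytest.approx(1.0)

    def test_unit_ci_puts_prescription_isodose_on_ptv_surface(self):
        m = calibrate_radial_model(SphericalTarget(4.0, 0.0), quality(ci=1.0), 15.0)
        assert m.r_rx_cm == pytest.approx(2.0)

    def test_rejects_degenerate_indices(self):
        with pytest.raises(CalibrationError):
            PlanQuality(dmax_pct=110, dmean_pct=100, rtog_ci=1.0, paddick_gi=1.0)
        with pytest.raises(CalibrationError):
            PlanQuality(dmax_pct=110, dmean_pct=100, rtog_ci=-1.0, paddick_gi=2.0)


class TestDoseProfile:
    def test_boundary_continuity_and_half_dose_radius(self):
        m = calibrate_radial_model(SphericalTarget(3.0), quality(gi=3.0), 18.0)
        assert m.dose_at_radius(m.r_rx_cm) == pytest.approx(m.rx_dose_gy)
        # by definition of the gradient index under this calibration
        r_half = m.r_rx_cm * 3.0 ** (1 / 3)
        assert m.dose_at_radius(r_half) == pytest.approx(9.0, rel=1e-12)

    def test_printed_configuration_hits_12gy_at_2_216_cm(self, plan_table):
        q = plan_quality_for(plan_table, 4.0, 0, "noncoplanar")
        m = calibrate_radial_model(SphericalTarget(4.0, 0), q, 15.0)
        assert m.dose_at_radius(2.216) == pytest.approx(12.0, abs=5e-3)

    def test_profile_non_increasing(self):
        m = calibrate_radial_model(SphericalTarget(2.0, 1.0), quality(gi=3.5, dmax=130), 18.0)
        r = np.linspace(0.0, 8.0, 500)
        d = m.dose_at_radius(r)
        assert np.all(np.diff(d) <= 1e-9)


class TestHealthyBrainVolume:
    def test_printed_v12_values(self, plan_table):
        """Closed-form V12 for the two printed 4 cm configurations."""
        m1 = calibrate_radial_model(
            SphericalTarget(4.0, 0), plan_quality_for(plan_table, 4.0, 0, "noncoplanar"), 15.0
        )
        assert m1.healthy_brain_volume_at_dose(12.0) == pytest.approx(12.07, abs=0.01)
        m2 = calibrate_radial_model(
            SphericalTarget(4.0, 2), plan_quality_for(plan_table, 4.0, 2, "coplanar"), 15.0
        )
        assert m2.healthy_brain_volume_at_dose(12.0) == pytest.approx(30.69, abs=0.01)

    def test_at_prescription_level_with_unit_ci(self):
        target = SphericalTarget(3.0, 2.0)
        m = calibrate_radial_model(target, quality(ci=1.0), 15.0)
        assert m.healthy_brain_volume_at_dose(15.0) == pytest.approx(
            target.ptv_volume_cm3 - target.gtv_volume_cm3
        )

    def test_monotone_in_level_and_geometry(self):
        q = quality(gi=3.0)
        m = calibrate_radial_model(SphericalTarget(2.5, 1.0), q, 18.0)
        levels = np.linspace(2.0, 18.0, 30)
        vols = [m.healthy_brain_volume_at_dose(l) for l in levels]
        assert all(a >= b for a, b in zip(vols, vols[1:]))
        # fixed quality: larger target, margin, or GI -> more irradiated brain
        v_base = m.healthy_brain_volume_at_dose(12.0)
        bigger = calibrate_radial_model(SphericalTarget(3.0, 1.0), q, 18.0)
        wider = calibrate_radial_model(SphericalTarget(2.5, 2.0), q, 18.0)
        shallower = calibrate_radial_model(SphericalTarget(2.5, 1.0), quality(gi=3.5), 18.0)
        for other in (bigger, wider, shallower):
            assert other.healthy_brain_volume_at_dose(12.0) > v_base

    def test_rescaling_linearity(self):
        m = calibrate_radial_model(SphericalTarget(2.0, 1.0), quality(gi=3.3), 18.0)
        f = 1.37
        scaled = m.rescaled(f)
        for level in (6.0, 12.0, 17.0):
            assert scaled.healthy_brain_volume_at_dose(level) == pytest.approx(
                m.healthy_brain_volume_at_dose(level / f), rel=1e-12
            )

    def test_rejects_nonpositive_level(self):
        m = calibrate_radial_model(SphericalTarget(2.0), quality(), 18.0)
        with pytest.raises(ValueError):
            m.healthy_brain_volume_at_dose(0.0)


class TestGrid:
    def test_gtv_mask_volume_close_to_analytic(self, plan_table):
        q = plan_quality_for(plan_table, 4.0, 0, "noncoplanar")
        m = calibrate_radial_model(SphericalTarget(4.0, 0), q, 15.0)
        g = render_grid(m, spacing_mm=1.0)
        assert g.mask_volume_cm3("gtv") == pytest.approx(33.510, rel=0.01)

    def test_grid_v12_matches_closed_form(self, plan_table):
        q = plan_quality_for(plan_table, 4.0, 0, "noncoplanar")
        m = calibrate_radial_model(SphericalTarget(4.0, 0), q, 15.0)
        g = render_grid(m, spacing_mm=1.0)
        assert g.volume_at_dose(12.0, "healthy") == pytest.approx(
            m.healthy_brain_volume_at_dose(12.0), rel=0.02
        )

    def test_truncation_flag(self):
        m = calibrate_radial_model(SphericalTarget(2.0), quality(), 18.0)
        with pytest.warns(UserWarning, match="truncates"):
            g = render_grid(m, spacing_mm=1.0, extent_cm=1.5)
        assert g.truncated
        g_ok = render_grid(m, spacing_mm=2.0)
        assert not g_ok.truncated

    def test_voxel_dose_equals_profile_at_centres(self):
        m = calibrate_radial_model(SphericalTarget(2.0), quality(dmax=125), 18.0)
        g = render_grid(m, spacing_mm=2.0, supersample=1)
        assert float(g.dose_gy.max()) <= m.dmax_gy + 1e-9
        # centre voxels sit half a diagonal from the origin
        r_min = math.sqrt(3) * 0.1
        assert float(g.dose_gy.max()) == pytest.approx(m.dose_at_radius(r_min), rel=1e-6)
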