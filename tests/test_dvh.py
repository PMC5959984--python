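import numpy as np
import pytest

from srs_idp.dvh import (
    CumulativeDVH,
    d_at_volume,
    dvh_from_grid,
    dvh_from_model,
    paddick_gi,
    rescale,
    rtog_ci,
    v_at_dose,
)
from srs_idp.geometry import SphericalTarget
from srs_idp.plan_model import (
    DoseGrid,
    PlanQuality,
    calibrate_radial_model,
    plan_quality_for,
    render_grid,
)


def toy_grid(dose_value=10.0, n=6, spacing=0.1):
    dose = np.full((n, n, n), dose_value)
    mask = np.zeros((n, n, n), dtype=bool)
    mask[:3] = True
    return DoseGrid(dose_gy=dose, spacing_cm=spacing, masks={"s": mask})


@pytest.fixture(scope="module")
def model_4cm(plan_table):
    q = plan_quality_for(plan_table, 4.0, 0, "noncoplanar")
    return calibrate_radial_model(SphericalTarget(4.0, 0), q, 15.0)


class TestConstruction:
    def test_constant_dose_grid(self):
        g = toy_grid(dose_value=10.0)
        dvh = dvh_from_grid(g, "s", bin_width_gy=1.0)
        total = g.mask_volume_cm3("s")
        # every bin at or below the constant dose holds the full volume, none above
        np.testing.assert_allclose(dvh.volume_cm3[dvh.dose_gy <= 10.0], total)
        np.testing.assert_allclose(dvh.volume_cm3[dvh.dose_gy > 10.0], 0.0)
        assert v_at_dose(dvh, 0.0) == pytest.approx(total)
        assert v_at_dose(dvh, 10.0) == pytest.approx(total)
        assert v_at_dose(dvh, 11.0) == 0.0

    def test_union_additivity(self):
        g = toy_grid()
        g.dose_gy[3:] = 4.0
        m1 = np.zeros_like(g.masks["s"])
        m2 = np.zeros_like(m1)
        m1[:2], m2[4:] = True, True
        d1 = dvh_from_grid(g, m1, 1.0)
        d2 = dvh_from_grid(g, m2, 1.0)
        du = dvh_from_grid(g, m1 | m2, 1.0)
        n = min(len(d1.dose_gy), len(d2.dose_gy))
        np.testing.assert_allclose(
            du.volume_cm3[:n], d1.volume_cm3[:n] + d2.volume_cm3[:n]
        )

    def test_empty_mask_rejected(self):
        g = toy_grid()
        with pytest.raises(ValueError, match="empty structure"):
            dvh_from_grid(g, np.zeros_like(g.masks["s"]), 1.0)

    def test_monotone_invariant_enforced(self):
        with pytest.raises(ValueError):
            CumulativeDVH(np.array([0.0, 1.0, 2.0]), np.array([1.0, 2.0, 0.5]))


class TestQueries:
    def test_grid_v12_matches_closed_form_within_2pct(self, model_4cm):
        g = render_grid(model_4cm, spacing_mm=1.0)
        dvh = dvh_from_grid(g, "healthy")
        assert v_at_dose(dvh, 12.0) == pytest.approx(
            model_4cm.healthy_brain_volume_at_dose(12.0), rel=0.02
        )

    def test_inverse_pair(self, model_4cm):
        dvh = dvh_from_model(model_4cm, "healthy")
        for v in (2.0, 10.0, 25.0):
            assert v_at_dose(dvh, d_at_volume(dvh, v)) == pytest.approx(v, rel=1e-9)

    def test_flat_segment_ties_break_toward_higher_dose(self):
        # volume stays at 4.0 across doses 1..3: report the highest dose
        dvh = CumulativeDVH(
            np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
            np.array([10.0, 4.0, 4.0, 4.0, 0.0]),
        )
        assert d_at_volume(dvh, 4.0) == 3.0

    def test_volume_above_total_rejected(self):
        dvh = CumulativeDVH(np.array([0.0, 1.0]), np.array([5.0, 1.0]))
        with pytest.raises(ValueError):
            d_at_volume(dvh, 6.0)


class TestRescale:
    def test_identity_and_round_trip(self, model_4cm):
        dvh = dvh_from_model(model_4cm, "healthy")
        np.testing.assert_allclose(rescale(dvh, 1.0).volume_cm3, dvh.volume_cm3)
        rt = rescale(rescale(dvh, 2.0), 0.5)
        np.testing.assert_allclose(rt.dose_gy, dvh.dose_gy)
        np.testing.assert_allclose(rt.volume_cm3, dvh.volume_cm3)

    def test_query_transformation_exact(self, model_4cm):
        dvh = dvh_from_model(model_4cm, "healthy")
        f = 1.3
        scaled = rescale(dvh, f)
        for level in (6.0, 12.0, 15.0):
            assert v_at_dose(scaled, level) == pytest.approx(
                v_at_dose(dvh, level / f), rel=1e-9
            )

    def test_rescale_to_constraint_level(self, model_4cm):
        dvh = dvh_from_model(model_4cm, "healthy")
        f = 12.0 / d_at_volume(dvh, 10.0)
        assert v_at_dose(rescale(dvh, f), 12.0) == pytest.approx(10.0, rel=1e-6)

    def test_nonpositive_factor_rejected(self, model_4cm):
        dvh = dvh_from_model(model_4cm, "healthy")
        with pytest.raises(ValueError):
            rescale(dvh, 0.0)


class TestPlanQualityIndices:
    def test_analytic_round_trip_exact(self, plan_table):
        q = plan_quality_for(plan_table, 4.0, 0, "noncoplanar")
        m = calibrate_radial_model(SphericalTarget(4.0, 0), q, 15.0)
        assert rtog_ci(m, 15.0) == pytest.approx(1.0, rel=1e-12)
        assert paddick_gi(m, 15.0) == pytest.approx(2.6, rel=1e-12)

    def test_grid_round_trip_within_1pct(self, plan_table):
        q = plan_quality_for(plan_table, 2.0, 1, "coplanar")
        m = calibrate_radial_model(SphericalTarget(2.0, 1), q, 18.0)
        g = render_grid(m, spacing_mm=1.0, extent_cm=m.radius_at_dose(8.0) + 0.2)
        assert rtog_ci(g, 18.0) == pytest.approx(q.rtog_ci, rel=0.01)
        assert paddick_gi(g, 18.0) == pytest.approx(q.paddick_gi, rel=0.01)

    def test_grid_convergence(self, plan_table):
        """Plain-counting V12 error shrinks as the grid is refined."""
        q = plan_quality_for(plan_table, 2.5, 1, "noncoplanar")
        m = calibrate_radial_model(SphericalTarget(2.5, 1), q, 18.0)
        truth = m.healthy_brain_volume_at_dose(12.0)
        errs = []
        for sp in (2.0, 1.0, 0.5):
            g = render_grid(m, spacing_mm=sp, supersample=1)
            errs.append(abs(g.volume_at_dose(12.0, "healthy") - truth) / truth)
        assert errs[0] > errs[1] > errs[2]

    def test_csv_round_trip(self, model_4cm, tmp_path):
        dvh = dvh_from_model(model_4cm, "healthy")
        path = tmp_path / "dvh.csv"
        dvh.to_csv(path)
        back = CumulativeDVH.from_csv(path)
        np.testing.assert_allclose(back.dose_gy, dvh.dose_gy)
        np.testing.assert_allclose(back.volume_cm3, dvh.volume_cm3)
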