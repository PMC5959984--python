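"""Isotoxic dose prescription: renormalize a plan to a normal-tissue constraint.

The isotoxic prescription dose is the prescription at which the plan,
scaled globally (altering the monitor units, no re-optimization), meets a
healthy-brain dose-volume constraint exactly - e.g. V12Gy = 10 cm^3 of
brain-minus-GTV for single-fraction treatments. Because the nominal plans
prescribe to the 99% PTV coverage isodose and scaling preserves relative
coverage, the renormalized prescription retains that normalization.
No clinical dose cap is applied: small targets can receive isotoxic doses
above the nominal protocol and are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dvh import CumulativeDVH, d_at_volume, rescale, v_at_dose
from .geometry import SphericalTarget, sphere_radius
from .plan_model import PlanQuality, RadialPlanModel, calibrate_radial_model
from .radiobiology import Constraint, FractionationScheme

__all__ = ["IDPResult", "idp_dose_analytic", "renormalize_dvh_to_constraint"]


@dataclass(frozen=True)
class IDPResult:
    """Outcome of an isotoxic renormalization.

    idp_dose_gy is the total prescription meeting the constraint;
    scale_factor the ratio against the nominal prescription;
    achieved_volume_cm3 the healthy-brain volume at the constraint level
    after renormalization (equal to the constraint volume up to solver
    tolerance); ``constraint_isodose_inside_ptv`` flags the degenerate but
    legal case where the constraint isodose sphere lies inside the
    prescription isodose.
    """

    idp_dose_gy: float
    scale_factor: float
    achieved_volume_cm3: float
    scheme: FractionationScheme
    constraint: Constraint
    constraint_isodose_inside_ptv: bool = False


def idp_dose_analytic(
    target: SphericalTarget,
    quality: PlanQuality,
    constraint: Constraint,
    nominal_rx_gy: float | None = None,
) -> IDPResult:
    """Closed-form isotoxic prescription for a calibrated radial plan model.

    The constraint isodose must enclose ``constraint.volume_cm3`` of healthy
    brain beyond the GTV, i.e. sit at radius
    r_c = (3 (V_c + V_GTV) / 4pi)^(1/3); under the power-law falloff the
    prescription achieving this is D = level * (r_c / r_rx)^k. If r_c falls
    inside the prescription isodose (possible for large PTVs with small
    constraint volumes) the constraint level lies on the inner ramp instead
    and the scaling is solved there; the result is flagged.

    ``nominal_rx_gy`` only sets the reported scale factor (default: the
    constraint level itself is used as reference, giving the raw plan
    scaling). The post-condition - achieved volume equals the constraint
    volume - is re-evaluated through the model and asserted.
    """
    model = calibrate_radial_model(target, quality, rx_dose_gy=constraint.dose_gy)
    r_c = sphere_radius(constraint.volume_cm3 + target.gtv_volume_cm3)
    if r_c >= model.r_rx_cm:
        idp_dose = constraint.dose_gy * (r_c / model.r_rx_cm) ** model.k
    else:
        # relative dose on the inner ramp at r_c (>= 1); scale so it equals the level
        alpha = quality.dmax_pct / 100.0
        ratio = alpha + (1.0 - alpha) * r_c / model.r_rx_cm
        idp_dose = constraint.dose_gy / ratio
    reference = nominal_rx_gy if nominal_rx_gy is not None else constraint.dose_gy
    scaled = calibrate_radial_model(target, quality, rx_dose_gy=idp_dose)
    achieved = scaled.healthy_brain_volume_at_dose(constraint.dose_gy)
    assert abs(achieved - constraint.volume_cm3) <= 1e-6 * max(constraint.volume_cm3, 1.0)
    return IDPResult(
        idp_dose_gy=idp_dose,
        scale_factor=idp_dose / reference,
        achieved_volume_cm3=achieved,
        scheme=FractionationScheme.from_total(constraint.n_fractions, idp_dose),
        constraint=constraint,
        constraint_isodose_inside_ptv=r_c < model.r_rx_cm,
    )


def renormalize_dvh_to_constraint(
    dvh: CumulativeDVH,
    nominal_rx_gy: float,
    constraint: Constraint,
) -> IDPResult:
    """Isotoxic renormalization of a healthy-brain-minus-GTV DVH.

    Scales the DVH dose axis by f = level / D(V_c) so that exactly
    ``constraint.volume_cm3`` receives the constraint level; the isotoxic
    prescription is f times the nominal prescription.
    """
    if constraint.volume_cm3 > dvh.total_volume_cm3:
        raise ValueError(
            f"constraint volume {constraint.volume_cm3} cm^3 exceeds structure "
            f"volume {dvh.total_volume_cm3} cm^3"
        )
    d_v = d_at_volume(dvh, constraint.volume_cm3)
    if d_v <= 0:
        raise ValueError("constraint volume is attained only at zero dose")
    f = constraint.dose_gy / d_v
    achieved = v_at_dose(rescale(dvh, f), constraint.dose_gy)
    bin_width = float(dvh.dose_gy[1] - dvh.dose_gy[0])
    # post-condition: achieved volume within one (rescaled) bin of the request
    assert abs(achieved - constraint.volume_cm3) <= max(
        1e-9, _volume_slack(dvh, constraint.volume_cm3, bin_width)
    )
    return IDPResult(
        idp_dose_gy=f * nominal_rx_gy,
        scale_factor=f,
        achieved_volume_cm3=achieved,
        scheme=FractionationScheme.from_total(constraint.n_fractions, f * nominal_rx_gy),
        constraint=constraint,
        constraint_isodose_inside_ptv=f * nominal_rx_gy < constraint.dose_gy,
    )


def _volume_slack(dvh: CumulativeDVH, volume_cm3: float, bin_width: float) -> float:
    """Largest volume change across one dose bin near the queried volume."""
    import numpy as np

    v = dvh.volume_cm3
    idx = int(np.argmin(np.abs(v - volume_cm3)))
    lo, hi = max(0, idx - 1), min(len(v) - 1, idx + 1)
    return float(v[lo] - v[hi]) + 1e-9
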