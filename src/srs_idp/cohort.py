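"""Synthetic cohort emulating clinically realistic (non-spherical) SRS plans.

The validation cohort this emulates consists of 46 consecutive single-BM
patients planned with coplanar VMAT and a 2 mm GTV-PTV margin. Within the
radial plan framework the isotoxic prescription depends on a plan only
through (V_PTV, CI, GI), so departures from sphericity and planner
variability are injected where they act: as a multiplicative log-normal
perturbation of the gradient index around the spherical-plan value
interpolated at the patient's PTV volume. PTV volumes are drawn
log-uniformly over the SRS eligibility range (no clinical volume histogram
is available). A fixed seed makes a cohort fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import (
    DUTCH_PROTOCOL,
    PrescriptionProtocol,
    SphericalTarget,
    sphere_volume,
)
from .idp import idp_dose_analytic
from .plan_model import PlanQuality, load_plan_quality_table
from .radiobiology import (
    ALPHA_BETA_BRAIN_GY,
    FIVE_FRACTION_V20,
    SINGLE_FRACTION_V12,
    convert_constraint,
)

__all__ = ["CohortSpec", "generate_cohort", "tune_noise"]

_GI_FLOOR = 1.05


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort draw."""

    n_patients: int = 46
    ptv_volume_range_cm3: tuple[float, float] = (0.5, 65.0)
    margin_mm: float = 2.0
    beams: str = "coplanar"
    gi_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ptv_volume_range_cm3
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0 < lo < hi):
            raise ValueError("ptv_volume_range_cm3 must be positive and increasing")
        if self.gi_noise_sd < 0:
            raise ValueError("gi_noise_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        import yaml
        from pathlib import Path

        raw = yaml.safe_load(Path(path).read_text())
        if "ptv_volume_range_cm3" in raw:
            raw["ptv_volume_range_cm3"] = tuple(raw["ptv_volume_range_cm3"])
        return cls(**raw)


def _interpolators(spec: CohortSpec):
    """CI and GI of the reference spherical plans vs log PTV volume."""
    table = load_plan_quality_table()
    rows = table[
        (table.beams == spec.beams) & np.isclose(table.margin_mm, spec.margin_mm)
    ].sort_values("gtv_diameter_cm")
    d_ptv = rows.gtv_diameter_cm.to_numpy() + 2.0 * spec.margin_mm / 10.0
    log_v = np.log(np.pi / 6.0 * d_ptv**3)
    ci = rows.rtog_ci.to_numpy(dtype=float)
    gi = rows.paddick_gi.to_numpy(dtype=float)

    def interp(y: np.ndarray):
        return lambda v: np.interp(np.log(v), log_v, y)  # clamped at the ends

    return interp(ci), interp(gi)


def generate_cohort(
    spec: CohortSpec, protocol: PrescriptionProtocol = DUTCH_PROTOCOL
) -> pd.DataFrame:
    """Draw a synthetic cohort and compute its isotoxic prescriptions.

    Per patient: draw a PTV volume (log-uniform), look up the spherical-plan
    CI/GI at that volume, perturb the GI log-normally (clipped at 1.05),
    and renormalize isotoxically for the single-, three- and five-fraction
    constraints. The unperturbed single-fraction prescription is reported
    alongside as ``idp_1fx_spherical_gy`` - the spherical-model curve value
    at the same volume.
    """
    rng = np.random.default_rng(spec.seed)
    ci_at, gi_at = _interpolators(spec)
    lo, hi = spec.ptv_volume_range_cm3
    volumes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_patients))
    gi_noise = np.exp(rng.normal(0.0, spec.gi_noise_sd, size=spec.n_patients))

    c3 = convert_constraint(SINGLE_FRACTION_V12, 3, ALPHA_BETA_BRAIN_GY)
    rows = []
    for v_ptv, eps in zip(volumes, gi_noise):
        d_ptv = (6.0 * v_ptv / np.pi) ** (1.0 / 3.0)
        target = SphericalTarget(
            gtv_diameter_cm=d_ptv - 2.0 * spec.margin_mm / 10.0,
            margin_mm=spec.margin_mm,
        )
        ci = float(ci_at(v_ptv))
        gi_sph = float(gi_at(v_ptv))
        gi = max(_GI_FLOOR, gi_sph * eps)
        nominal = protocol.dose_for_volume(v_ptv)

        def q(g: float) -> PlanQuality:
            return PlanQuality(dmax_pct=120.0, dmean_pct=104.0, rtog_ci=ci, paddick_gi=g)

        rows.append(
            {
                "ptv_volume_cm3": v_ptv,
                "gtv_diameter_cm": target.gtv_diameter_cm,
                "rtog_ci": ci,
                "paddick_gi": gi,
                "nominal_rx_gy": nominal,
                "idp_1fx_gy": idp_dose_analytic(
                    target, q(gi), SINGLE_FRACTION_V12, nominal
                ).idp_dose_gy,
                "idp_3fx_gy": idp_dose_analytic(target, q(gi), c3, nominal).idp_dose_gy,
                "idp_5fx_gy": idp_dose_analytic(
                    target, q(gi), FIVE_FRACTION_V20, nominal
                ).idp_dose_gy,
                "idp_1fx_spherical_gy": idp_dose_analytic(
                    target, q(gi_sph), SINGLE_FRACTION_V12, nominal
                ).idp_dose_gy,
            }
        )
    return pd.DataFrame(rows)


def _scatter_sd(spec: CohortSpec, n_replicates: int) -> float:
    """Mean over replicate cohorts of the SD of (cohort - spherical curve) 1-fx doses."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_replicates) % (2**31)
    sds = []
    for s in seeds:
        df = generate_cohort(replace(spec, seed=int(s)))
        sds.append(float(np.std(df.idp_1fx_gy - df.idp_1fx_spherical_gy, ddof=1)))
    return float(np.mean(sds))


def tune_noise(
    target_sd_gy: float,
    spec: CohortSpec,
    n_replicates: int = 30,
    rel_tol: float = 1e-3,
    max_iter: int = 60,
) -> float:
    """Find the GI noise level whose cohorts scatter with the target SD.

    Monotone bisection of the Monte-Carlo scatter estimate (a fixed seed
    block of ``n_replicates`` cohorts) against ``target_sd_gy``.
    """
    if target_sd_gy <= 0:
        raise ValueError("target_sd_gy must be > 0")
    lo, hi = 0.0, 0.05
    f_hi = _scatter_sd(replace(spec, gi_noise_sd=hi), n_replicates)
    grow = 0
    while f_hi < target_sd_gy:
        hi *= 2.0
        grow += 1
        if grow > 12:
            raise RuntimeError(f"target SD {target_sd_gy} Gy unattainable by GI noise")
        f_hi = _scatter_sd(replace(spec, gi_noise_sd=hi), n_replicates)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _scatter_sd(replace(spec, gi_noise_sd=mid), n_replicates)
        if abs(f_mid - target_sd_gy) <= rel_tol * target_sd_gy:
            return mid
        if f_mid < target_sd_gy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
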