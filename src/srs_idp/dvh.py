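"""Cumulative dose-volume histograms and plan-quality indices.

A cumulative DVH stores, for a uniform grid of dose bin edges, the
structure volume receiving at least that dose. Queries interpolate
linearly between edges; renormalizing a plan (monitor-unit scaling) maps
onto an exact rescaling of the dose axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .plan_model import DoseGrid, RadialPlanModel

__all__ = [
    "CumulativeDVH",
    "dvh_from_grid",
    "dvh_from_model",
    "v_at_dose",
    "d_at_volume",
    "rescale",
    "rtog_ci",
    "paddick_gi",
]


@dataclass(frozen=True)
class CumulativeDVH:
    """Cumulative DVH: ``volume_cm3[i]`` is the volume with dose >= ``dose_gy[i]``."""

    dose_gy: np.ndarray  # ascending, uniform spacing
    volume_cm3: np.ndarray  # non-increasing

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_gy, dtype=float)
        v = np.asarray(self.volume_cm3, dtype=float)
        if d.ndim != 1 or d.shape != v.shape or d.size < 2:
            raise ValueError("dose_gy and volume_cm3 must be 1-d arrays of equal length >= 2")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dose bins must be strictly ascending")
        if np.any(np.diff(v) > 1e-9 * max(v[0], 1.0)):
            raise ValueError("cumulative DVH must be non-increasing")
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "volume_cm3", v)

    @property
    def total_volume_cm3(self) -> float:
        return float(self.volume_cm3[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"dose_gy": self.dose_gy, "volume_cm3": self.volume_cm3}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "CumulativeDVH":
        df = pd.read_csv(path)
        return cls(df["dose_gy"].to_numpy(), df["volume_cm3"].to_numpy())


def dvh_from_grid(grid: DoseGrid, mask: str | np.ndarray, bin_width_gy: float = 0.1) -> CumulativeDVH:
    """Cumulative DVH of the masked voxels of a dose grid.

    Bin ``i`` holds the volume of masked voxels with dose at or above the
    left edge of bin ``i``; edges run from 0 to just past the masked
    maximum dose in steps of ``bin_width_gy``.
    """
    if bin_width_gy <= 0:
        raise ValueError(f"bin_width_gy must be > 0, got {bin_width_gy}")
    if isinstance(mask, str):
        dose, m, voxel_volume = grid._arrays(mask)
    else:
        m = np.asarray(mask, dtype=bool)
        if grid.fine_dose_gy is not None and m.shape == grid.fine_dose_gy.shape:
            dose, voxel_volume = grid.fine_dose_gy, grid.fine_spacing_cm**3
        else:
            dose, voxel_volume = grid.dose_gy, grid.voxel_volume_cm3
    doses = dose[m]
    if doses.size == 0:
        raise ValueError("empty structure")
    n_bins = int(np.ceil(doses.max() / bin_width_gy)) + 2
    edges = np.arange(n_bins) * bin_width_gy
    # volume at-or-above each left edge
    counts, _ = np.histogram(doses, bins=np.append(edges, np.inf))
    vols = counts[::-1].cumsum()[::-1].astype(float) * voxel_volume
    return CumulativeDVH(edges, vols)


def dvh_from_model(
    model: RadialPlanModel,
    structure: str = "healthy",
    bin_width_gy: float = 0.1,
    min_dose_gy: float = 0.5,
) -> CumulativeDVH:
    """Analytic cumulative DVH of a radial plan model, down to ``min_dose_gy``.

    ``structure`` is ``healthy`` (everything outside the GTV, truncated at
    the ``min_dose_gy`` isodose), ``gtv`` or ``ptv``.
    """
    edges = np.arange(min_dose_gy, model.dmax_gy + 2 * bin_width_gy, bin_width_gy)
    vols = np.array([model.volume_at_dose(float(e)) for e in edges])
    if structure == "healthy":
        vols = np.maximum(0.0, vols - model.v_gtv_cm3)
    elif structure in ("gtv", "ptv"):
        cap = model.v_gtv_cm3 if structure == "gtv" else model.v_ptv_cm3
        vols = np.minimum(vols, cap)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return CumulativeDVH(edges, vols)


def v_at_dose(dvh: CumulativeDVH, level_gy: float) -> float:
    """Volume (cm^3) receiving at least ``level_gy``, by linear interpolation."""
    d, v = dvh.dose_gy, dvh.volume_cm3
    if level_gy <= d[0]:
        return float(v[0])
    if level_gy >= d[-1]:
        return float(v[-1]) if level_gy == d[-1] else 0.0
    return float(np.interp(level_gy, d, v))


def d_at_volume(dvh: CumulativeDVH, volume_cm3: float) -> float:
    """Highest dose (Gy) received by at least ``volume_cm3`` of the structure.

    Generalized inverse of :func:`v_at_dose`; on flat DVH segments ties are
    broken toward the higher dose so that isotoxic renormalization against
    a constraint is conservative.
    """
    d, v = dvh.dose_gy, dvh.volume_cm3
    if volume_cm3 > dvh.total_volume_cm3:
        raise ValueError(
            f"requested volume {volume_cm3} cm^3 exceeds structure volume "
            f"{dvh.total_volume_cm3} cm^3"
        )
    at_least = np.nonzero(v >= volume_cm3)[0]
    j = int(at_least[-1])  # last edge still attaining the volume
    if j == len(d) - 1 or v[j] == volume_cm3:
        return float(d[j])
    # interpolate within (d[j], d[j+1]) where v drops below the request
    frac = (v[j] - volume_cm3) / (v[j] - v[j + 1])
    return float(d[j] + frac * (d[j + 1] - d[j]))


def rescale(dvh: CumulativeDVH, factor: float) -> CumulativeDVH:
    """Multiply the dose axis by ``factor`` (volumes unchanged).

    Exact: V_x(rescaled) = V_{x/factor}(original). Models renormalizing a
    plan by altering the monitor units.
    """
    if factor <= 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    return CumulativeDVH(dvh.dose_gy * factor, dvh.volume_cm3.copy())


def _isodose_volume(obj: RadialPlanModel | DoseGrid, level_gy: float) -> float:
    if isinstance(obj, RadialPlanModel):
        return obj.volume_at_dose(level_gy)
    return obj.volume_at_dose(level_gy)


def rtog_ci(obj: RadialPlanModel | DoseGrid, rx_dose_gy: float, v_ptv_cm3: float | None = None) -> float:
    """RTOG conformity index: prescription isodose volume over PTV volume."""
    if rx_dose_gy <= 0:
        raise ValueError("rx_dose_gy must be > 0")
    v_rx = _isodose_volume(obj, rx_dose_gy)
    if v_rx == 0:
        raise ValueError("prescription isodose volume is zero")
    if v_ptv_cm3 is None:
        v_ptv_cm3 = (
            obj.v_ptv_cm3 if isinstance(obj, RadialPlanModel) else obj.mask_volume_cm3("ptv")
        )
    return v_rx / v_ptv_cm3


def paddick_gi(obj: RadialPlanModel | DoseGrid, rx_dose_gy: float) -> float:
    """Paddick gradient index: half-prescription isodose volume over prescription isodose volume."""
    if rx_dose_gy <= 0:
        raise ValueError("rx_dose_gy must be > 0")
    v_rx = _isodose_volume(obj, rx_dose_gy)
    if v_rx == 0:
        raise ValueError("prescription isodose volume is zero")
    return _isodose_volume(obj, rx_dose_gy / 2.0) / v_rx
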