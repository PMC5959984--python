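"""Spherical target geometry and the PTV-size-based prescription protocol.

Units are fixed throughout the package: target diameters in cm, setup
margins in mm, volumes in cm^3, doses in Gy. All conversions live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "SphericalTarget",
    "PrescriptionProtocol",
    "DUTCH_PROTOCOL",
    "IneligibleForSRSError",
    "sphere_volume",
    "sphere_radius",
    "expand_margin",
    "prescribe_by_ptv_size",
]

MM_PER_CM = 10.0


class IneligibleForSRSError(ValueError):
    """PTV volume exceeds the largest volume the protocol covers."""


def sphere_volume(diameter_cm: float) -> float:
    """Volume (cm^3) of a sphere of the given diameter (cm)."""
    if diameter_cm < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter_cm}")
    return math.pi / 6.0 * diameter_cm**3


def sphere_radius(volume_cm3: float) -> float:
    """Radius (cm) of a sphere of the given volume (cm^3)."""
    if volume_cm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_cm3}")
    return (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class SphericalTarget:
    """A spherical gross tumor volume (GTV) with an isotropic setup margin.

    Parameters
    ----------
    gtv_diameter_cm:
        Diameter of the spherical GTV in cm (> 0).
    margin_mm:
        Isotropic GTV-to-PTV expansion margin in mm (>= 0).
    """

    gtv_diameter_cm: float
    margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.gtv_diameter_cm <= 0:
            raise ValueError(f"gtv_diameter_cm must be > 0, got {self.gtv_diameter_cm}")
        if self.margin_mm < 0:
            raise ValueError(f"margin_mm must be >= 0, got {self.margin_mm}")

    @property
    def gtv_radius_cm(self) -> float:
        return self.gtv_diameter_cm / 2.0

    @property
    def ptv_diameter_cm(self) -> float:
        return self.gtv_diameter_cm + 2.0 * self.margin_mm / MM_PER_CM

    @property
    def ptv_radius_cm(self) -> float:
        return self.ptv_diameter_cm / 2.0

    @property
    def gtv_volume_cm3(self) -> float:
        return sphere_volume(self.gtv_diameter_cm)

    @property
    def ptv_volume_cm3(self) -> float:
        return sphere_volume(self.ptv_diameter_cm)


def expand_margin(target: SphericalTarget) -> float:
    """PTV diameter (cm) after isotropic margin expansion of the GTV."""
    return target.ptv_diameter_cm


@dataclass(frozen=True)
class PrescriptionProtocol:
    """Risk-adapted single-fraction prescription as a step function of PTV volume.

    ``bins`` is an ordered sequence of ``(lower_cm3, upper_cm3, dose_gy)``
    with half-open intervals ``[lower, upper)``; the final bin is closed at
    its upper edge, which doubles as the SRS eligibility ceiling. The
    default is the Dutch consensus protocol: 24 Gy below 1 cm^3, stepping
    down to 21, 18 and 15 Gy, with a 65 cm^3 ceiling.
    """

    bins: tuple[tuple[float, float, float], ...] = (
        (0.0, 1.0, 24.0),
        (1.0, 10.0, 21.0),
        (10.0, 20.0, 18.0),
        (20.0, 65.0, 15.0),
    )

    def __post_init__(self) -> None:
        prev_upper = None
        prev_dose = math.inf
        for lower, upper, dose in self.bins:
            if upper <= lower:
                raise ValueError(f"empty bin [{lower}, {upper})")
            if prev_upper is not None and lower != prev_upper:
                raise ValueError("protocol bins must be contiguous")
            if dose > prev_dose:
                raise ValueError("prescription must be non-increasing with volume")
            prev_upper, prev_dose = upper, dose

    @property
    def max_volume_cm3(self) -> float:
        return self.bins[-1][1]

    def dose_for_volume(self, ptv_volume_cm3: float) -> float:
        if ptv_volume_cm3 <= 0:
            raise ValueError(f"ptv_volume_cm3 must be > 0, got {ptv_volume_cm3}")
        for lower, upper, dose in self.bins:
            if lower <= ptv_volume_cm3 < upper:
                return dose
        if ptv_volume_cm3 == self.max_volume_cm3:  # closed top edge
            return self.bins[-1][2]
        raise IneligibleForSRSError(
            f"PTV volume {ptv_volume_cm3:.2f} cm^3 exceeds the "
            f"{self.max_volume_cm3:g} cm^3 SRS eligibility limit"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PrescriptionProtocol":
        """Load a protocol from a YAML file.

        Expected layout::

            bins:
              - {lower_cm3: 0, upper_cm3: 1, dose_gy: 24}
              - {lower_cm3: 1, upper_cm3: 10, dose_gy: 21}
        """
        raw = yaml.safe_load(Path(path).read_text())
        bins = tuple(
            (float(b["lower_cm3"]), float(b["upper_cm3"]), float(b["dose_gy"]))
            for b in raw["bins"]
        )
        return cls(bins=bins)


DUTCH_PROTOCOL = PrescriptionProtocol()


def prescribe_by_ptv_size(
    ptv_volume_cm3: float,
    protocol: PrescriptionProtocol = DUTCH_PROTOCOL,
) -> float:
    """Prescribed single-fraction dose (Gy) for a PTV of the given volume."""
    return protocol.dose_for_volume(ptv_volume_cm3)
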