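"""Linear-quadratic fractionation conversions and the logistic TCP model.

The linear-quadratic (LQ) model expresses the biologically effective dose
of n fractions of d Gy as BED = n*d*(1 + d/(alpha/beta)). Normal-brain
constraints use alpha/beta = 3 Gy (late toxicity); the tumor-control
covariate uses alpha/beta = 12 Gy, the convention for brain-metastasis
dose-response data. Tumor control probability (TCP) is a logistic function
of BED12:

    TCP = 1 / (1 + exp(-(beta0 + beta1 * BED12)))

The default model is calibrated to two printed single-fraction anchors
(42% at 1 x 15 Gy, 86% at 1 x 24 Gy); the parameters of the originally
fitted dose-response curve were not published, so the model is pluggable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FractionationScheme",
    "Constraint",
    "TCPModel",
    "ALPHA_BETA_BRAIN_GY",
    "ALPHA_BETA_TUMOR_GY",
    "SINGLE_FRACTION_V12",
    "THREE_FRACTION_V19_2",
    "FIVE_FRACTION_V20",
    "DEFAULT_TCP_MODEL",
    "bed",
    "isoeffective_total_dose",
    "convert_constraint",
    "calibrate_tcp",
    "tcp",
]

ALPHA_BETA_BRAIN_GY = 3.0
ALPHA_BETA_TUMOR_GY = 12.0


@dataclass(frozen=True)
class FractionationScheme:
    """``n_fractions`` fractions of ``dose_per_fraction_gy`` Gy each."""

    n_fractions: int
    dose_per_fraction_gy: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n_fractions, (int, np.integer)) and self.n_fractions >= 1):
            raise ValueError(f"n_fractions must be an integer >= 1, got {self.n_fractions}")
        if self.dose_per_fraction_gy <= 0:
            raise ValueError(
                f"dose_per_fraction_gy must be > 0, got {self.dose_per_fraction_gy}"
            )

    @property
    def total_dose_gy(self) -> float:
        return self.n_fractions * self.dose_per_fraction_gy

    @classmethod
    def from_total(cls, n_fractions: int, total_dose_gy: float) -> "FractionationScheme":
        return cls(n_fractions, total_dose_gy / n_fractions)


@dataclass(frozen=True)
class Constraint:
    """Normal-tissue dose-volume constraint: at most ``volume_cm3`` may receive
    >= ``dose_gy`` (total over ``n_fractions`` fractions). Zero volume means
    the constraint isodose may not extend beyond the structure of interest."""

    dose_gy: float
    volume_cm3: float
    n_fractions: int = 1

    def __post_init__(self) -> None:
        if self.dose_gy <= 0 or self.volume_cm3 < 0 or self.n_fractions < 1:
            raise ValueError(f"invalid constraint {self}")


#: Radionecrosis-risk constraints on healthy brain minus GTV.
SINGLE_FRACTION_V12 = Constraint(dose_gy=12.0, volume_cm3=10.0, n_fractions=1)
THREE_FRACTION_V19_2 = Constraint(dose_gy=19.2, volume_cm3=10.0, n_fractions=3)
FIVE_FRACTION_V20 = Constraint(dose_gy=20.0, volume_cm3=20.0, n_fractions=5)


def bed(scheme: FractionationScheme, alpha_beta_gy: float) -> float:
    """Biologically effective dose n*d*(1 + d/(alpha/beta)) in Gy."""
    if alpha_beta_gy <= 0:
        raise ValueError(f"alpha_beta_gy must be > 0, got {alpha_beta_gy}")
    d = scheme.dose_per_fraction_gy
    return scheme.n_fractions * d * (1.0 + d / alpha_beta_gy)


def isoeffective_total_dose(bed_gy: float, n_fractions: int, alpha_beta_gy: float) -> float:
    """Total dose in ``n_fractions`` fractions with the given BED.

    Positive root of T^2/(n*ab) + T - BED = 0; exact inverse of
    :func:`bed` for any valid scheme.
    """
    if bed_gy <= 0:
        raise ValueError(f"bed_gy must be > 0, got {bed_gy}")
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    nab = n_fractions * alpha_beta_gy
    return nab / 2.0 * (math.sqrt(1.0 + 4.0 * bed_gy / nab) - 1.0)


def convert_constraint(
    c: Constraint, to_n_fractions: int, alpha_beta_gy: float = ALPHA_BETA_BRAIN_GY
) -> Constraint:
    """Recalculate a dose-volume constraint for a different fraction number.

    The dose level is mapped through the LQ model at the same BED; the
    volume is unchanged. E.g. V12Gy = 10 cm^3 in one fraction becomes
    V19.2Gy = 10 cm^3 in three fractions at alpha/beta = 3 Gy.
    """
    b = bed(FractionationScheme.from_total(c.n_fractions, c.dose_gy), alpha_beta_gy)
    level = isoeffective_total_dose(b, to_n_fractions, alpha_beta_gy)
    return Constraint(dose_gy=level, volume_cm3=c.volume_cm3, n_fractions=to_n_fractions)


@dataclass(frozen=True)
class TCPModel:
    """Logistic tumor-control model: logit(TCP) = beta0 + beta1 * BED12."""

    beta0: float
    beta1: float
    alpha_beta_tumor_gy: float = ALPHA_BETA_TUMOR_GY

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ValueError(f"beta1 must be > 0 (increasing dose-response), got {self.beta1}")

    def tcp(self, scheme: FractionationScheme) -> float:
        lin = self.beta0 + self.beta1 * bed(scheme, self.alpha_beta_tumor_gy)
        return 1.0 / (1.0 + math.exp(-lin))

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "TCPModel":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


def calibrate_tcp(
    anchors: Iterable[tuple[FractionationScheme, float]],
    alpha_beta_tumor_gy: float = ALPHA_BETA_TUMOR_GY,
) -> TCPModel:
    """Fit the logistic TCP model to (scheme, probability) anchor points.

    Solves logit(p_i) = beta0 + beta1 * BED12_i exactly for two anchors and
    by least squares for more. Anchors with coincident BEDs (or a
    non-increasing response) are rejected.
    """
    pts = list(anchors)
    if len(pts) < 2:
        raise ValueError("need at least two anchors")
    beds = np.array([bed(s, alpha_beta_tumor_gy) for s, _ in pts])
    probs = np.array([p for _, p in pts])
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("anchor probabilities must lie in (0, 1)")
    if np.ptp(beds) < 1e-12:
        raise ValueError("anchor BEDs are identical; system is singular")
    logits = np.log(probs / (1.0 - probs))
    A = np.column_stack([np.ones_like(beds), beds])
    (beta0, beta1), *_ = np.linalg.lstsq(A, logits, rcond=None)
    return TCPModel(beta0=float(beta0), beta1=float(beta1), alpha_beta_tumor_gy=alpha_beta_tumor_gy)


#: Default model: logit-linear in BED12 through the printed single-fraction
#: anchors (15 Gy -> 42%, 24 Gy -> 86%).
DEFAULT_TCP_MODEL = calibrate_tcp(
    [
        (FractionationScheme(1, 15.0), 0.42),
        (FractionationScheme(1, 24.0), 0.86),
    ]
)


def tcp(model: TCPModel, scheme: FractionationScheme) -> float:
    """Predicted tumor control probability for a fractionation scheme."""
    return model.tcp(scheme)
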