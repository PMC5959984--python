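"""The factorial planning study: sweep, curve fits, fit comparison, export.

Runs the full 8 diameters x 3 margins x 2 beam-arrangement sweep of the
reference plans: nominal PTV-size-based prescription and healthy-brain
V12, then isotoxic prescriptions and predicted TCP for the single-,
three- and five-fraction constraints. The empirical size-dose relationship
is summarized by an exponential decay fit dose(V) = d_inf + d0*exp(-V/v0),
and spherical-model and cohort fits are compared with a Pearson
chi-squared statistic plus a seeded bootstrap test on the coefficients.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geometry import DUTCH_PROTOCOL, IneligibleForSRSError, PrescriptionProtocol, SphericalTarget
from .idp import idp_dose_analytic
from .plan_model import calibrate_radial_model, load_plan_quality_table, plan_quality_for
from .radiobiology import (
    ALPHA_BETA_BRAIN_GY,
    DEFAULT_TCP_MODEL,
    FIVE_FRACTION_V20,
    SINGLE_FRACTION_V12,
    FractionationScheme,
    TCPModel,
    convert_constraint,
)

__all__ = [
    "ExpDecayFit",
    "FitComparison",
    "run_sweep",
    "fit_exp_decay",
    "compare_fits",
    "export_results",
    "DIAMETERS_CM",
    "MARGINS_MM",
    "BEAMS",
]

logger = logging.getLogger(__name__)

DIAMETERS_CM = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
MARGINS_MM = (0.0, 1.0, 2.0)
BEAMS = ("coplanar", "noncoplanar")

_SWEEP_COLUMNS = [
    "gtv_diameter_cm",
    "margin_mm",
    "beams",
    "ptv_volume_cm3",
    "nominal_rx_gy",
    "nominal_v12_cm3",
    "idp_1fx_gy",
    "tcp_1fx",
    "idp_3fx_gy",
    "tcp_3fx",
    "idp_5fx_gy",
    "tcp_5fx",
]


def run_sweep(
    protocol: PrescriptionProtocol = DUTCH_PROTOCOL,
    table: pd.DataFrame | None = None,
    tcp_model: TCPModel = DEFAULT_TCP_MODEL,
) -> pd.DataFrame:
    """One row per plan configuration (48 for the default factorial design).

    The three-fraction constraint level is the exact LQ conversion of
    V12Gy = 10 cm^3 at alpha/beta = 3 Gy (19.17 Gy); the five-fraction
    constraint is V20Gy = 20 cm^3. Missing plan-quality rows are skipped
    with a warning.
    """
    if table is None:
        table = load_plan_quality_table()
    c1 = SINGLE_FRACTION_V12
    c3 = convert_constraint(c1, 3, ALPHA_BETA_BRAIN_GY)
    c5 = FIVE_FRACTION_V20
    rows = []
    for d in DIAMETERS_CM:
        for m in MARGINS_MM:
            for beams in BEAMS:
                try:
                    quality = plan_quality_for(table, d, m, beams)
                except KeyError:
                    logger.warning("no plan-quality data for %s/%s mm %s; skipped", d, m, beams)
                    continue
                target = SphericalTarget(gtv_diameter_cm=d, margin_mm=m)
                nominal = protocol.dose_for_volume(target.ptv_volume_cm3)
                nominal_model = calibrate_radial_model(target, quality, nominal)
                row = {
                    "gtv_diameter_cm": d,
                    "margin_mm": m,
                    "beams": beams,
                    "ptv_volume_cm3": target.ptv_volume_cm3,
                    "nominal_rx_gy": nominal,
                    "nominal_v12_cm3": nominal_model.healthy_brain_volume_at_dose(12.0),
                }
                for label, constraint in (("1fx", c1), ("3fx", c3), ("5fx", c5)):
                    res = idp_dose_analytic(target, quality, constraint, nominal)
                    row[f"idp_{label}_gy"] = res.idp_dose_gy
                    row[f"tcp_{label}"] = tcp_model.tcp(res.scheme)
                rows.append(row)
    return pd.DataFrame(rows, columns=_SWEEP_COLUMNS)


@dataclass(frozen=True)
class ExpDecayFit:
    """dose(V) = d_inf + d0 * exp(-V / v0), fitted by least squares."""

    d_inf_gy: float
    d0_gy: float
    v0_cm3: float
    residual_sd_gy: float
    n_points: int

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.d_inf_gy, self.d0_gy, self.v0_cm3])

    def predict(self, volume_cm3: float | np.ndarray) -> np.ndarray:
        v = np.asarray(volume_cm3, dtype=float)
        return self.d_inf_gy + self.d0_gy * np.exp(-v / self.v0_cm3)


def _exp_decay(v, d_inf, d0, v0):
    return d_inf + d0 * np.exp(-v / v0)


def fit_exp_decay(
    volumes_cm3: Sequence[float],
    doses_gy: Sequence[float],
    starts: Sequence[tuple[float, float, float]] | None = None,
) -> ExpDecayFit:
    """Least-squares exponential decay fit with deterministic multi-start.

    Three fixed starting points (fast/medium/slow decay) are tried and the
    best-residual solution kept; v0 is constrained positive.
    """
    v = np.asarray(volumes_cm3, dtype=float)
    y = np.asarray(doses_gy, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 points for a 3-parameter fit")
    if starts is None:
        spread = float(y.max() - y.min())
        base = float(y.min())
        starts = [(base, max(spread, 1.0), s) for s in (2.0, 10.0, 30.0)]
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _exp_decay,
                    v,
                    y,
                    p0=p0,
                    bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _exp_decay(v, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise RuntimeError("exponential decay fit failed from all starts")
    popt, ssr = best
    dof = max(1, v.size - 3)
    return ExpDecayFit(
        d_inf_gy=float(popt[0]),
        d0_gy=float(popt[1]),
        v0_cm3=float(popt[2]),
        residual_sd_gy=float(np.sqrt(ssr / dof)),
        n_points=int(v.size),
    )


@dataclass(frozen=True)
class FitComparison:
    """Agreement between a reference curve and a second dataset/fit.

    ``chi2_stat``/``chi2_p``: Pearson chi-squared of dataset B against the
    curve fitted to dataset A (dof = n_B - 3). The bootstrap block tests
    whether the coefficient difference between the two fits is zero
    (two-sided percentile intervals; ``bootstrap_p`` is the smallest
    per-coefficient p-value).
    """

    chi2_stat: float
    chi2_dof: int
    chi2_p: float
    coefficient_difference: tuple[float, float, float]
    bootstrap_p: float | None = None
    bootstrap_p_by_coefficient: tuple[float, float, float] | None = None
    n_bootstrap: int = 0


def compare_fits(
    fit_a: ExpDecayFit,
    fit_b: ExpDecayFit,
    data_a: tuple[np.ndarray, np.ndarray],
    data_b: tuple[np.ndarray, np.ndarray],
    n_bootstrap: int = 0,
    seed: int = 0,
) -> FitComparison:
    """Compare two exponential-decay fits.

    The Pearson chi-squared statistic sums (observed_B - predicted_A)^2 /
    predicted_A over dataset B. With ``n_bootstrap`` > 0, case-resampled
    refits of both datasets give percentile p-values for each coefficient
    difference being zero.
    """
    vb, yb = (np.asarray(a, dtype=float) for a in data_b)
    pred = fit_a.predict(vb)
    if np.any(pred <= 0):
        raise ValueError("predicted doses must be positive for the chi-squared statistic")
    chi2_stat = float(np.sum((yb - pred) ** 2 / pred))
    dof = max(1, vb.size - 3)
    chi2_p = float(stats.chi2.sf(chi2_stat, dof))
    diff = tuple(fit_a.coefficients - fit_b.coefficients)

    boot_p = boot_p_by = None
    if n_bootstrap > 0:
        va, ya = (np.asarray(a, dtype=float) for a in data_a)
        rng = np.random.default_rng(seed)
        diffs = []
        start_a = (fit_a.d_inf_gy, fit_a.d0_gy, fit_a.v0_cm3)
        start_b = (fit_b.d_inf_gy, fit_b.d0_gy, fit_b.v0_cm3)
        for _ in range(n_bootstrap):
            ia = rng.integers(0, va.size, va.size)
            ib = rng.integers(0, vb.size, vb.size)
            try:
                fa = fit_exp_decay(va[ia], ya[ia], starts=[start_a])
                fb = fit_exp_decay(vb[ib], yb[ib], starts=[start_b])
            except RuntimeError:
                continue
            diffs.append(fa.coefficients - fb.coefficients)
        diffs = np.array(diffs)
        p_by = []
        for j in range(3):
            frac_le = np.mean(diffs[:, j] <= 0)
            frac_ge = np.mean(diffs[:, j] >= 0)
            p_by.append(float(min(1.0, 2.0 * min(frac_le, frac_ge))))
        boot_p_by = tuple(p_by)
        boot_p = min(p_by)
    return FitComparison(
        chi2_stat=chi2_stat,
        chi2_dof=dof,
        chi2_p=chi2_p,
        coefficient_difference=diff,
        bootstrap_p=boot_p,
        bootstrap_p_by_coefficient=boot_p_by,
        n_bootstrap=n_bootstrap if boot_p is not None else 0,
    )


def export_results(
    table: pd.DataFrame,
    fits: dict[str, ExpDecayFit] | None,
    outdir: str | Path,
    figures: bool = False,
) -> dict[str, Path]:
    """Write the sweep table (CSV), fits (JSON) and optional figures.

    Output is deterministic: fixed column order, fixed float format, keys
    sorted in the JSON. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    csv_path = outdir / "idp_sweep.csv"
    table.to_csv(csv_path, index=False, float_format="%.6g")
    written["sweep_csv"] = csv_path

    if fits:
        fits_path = outdir / "exp_decay_fits.json"
        fits_path.write_text(
            json.dumps({k: asdict(f) for k, f in sorted(fits.items())}, indent=2, sort_keys=True)
            + "\n"
        )
        written["fits_json"] = fits_path

    if figures:
        written.update(_figures(table, outdir))
    return written


def _figures(table: pd.DataFrame, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}

    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, m in zip(axes, MARGINS_MM):
        for beams, style in (("coplanar", "o-"), ("noncoplanar", "s--")):
            sub = table[(table.margin_mm == m) & (table.beams == beams)]
            ax.plot(sub.gtv_diameter_cm, sub.nominal_v12_cm3, style, label=beams)
        ax.axhline(10.0, color="k", lw=0.8, ls=":")
        ax.set_title(f"margin {m:g} mm")
        ax.set_xlabel("GTV diameter (cm)")
    axes[0].set_ylabel("healthy-brain V12 (cm$^3$)")
    axes[0].legend()
    p = outdir / "nominal_v12.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["fig_nominal_v12"] = p

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for beams, style in (("coplanar", "o-"), ("noncoplanar", "s--")):
        sub = table[(table.margin_mm == 0.0) & (table.beams == beams)]
        ax1.plot(sub.gtv_diameter_cm, sub.idp_1fx_gy, style, label=beams)
        ax2.plot(sub.gtv_diameter_cm, sub.tcp_1fx, style, label=beams)
    ax1.set_xlabel("GTV diameter (cm)")
    ax1.set_ylabel("single-fraction isotoxic dose (Gy)")
    ax2.set_xlabel("GTV diameter (cm)")
    ax2.set_ylabel("predicted TCP")
    ax1.legend()
    p = outdir / "idp_dose_tcp.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["fig_idp_dose_tcp"] = p

    fig, ax = plt.subplots(figsize=(6, 4))
    sub = table[(table.margin_mm == 1.0) & (table.beams == "noncoplanar")]
    for label, col in (("1 fraction", "tcp_1fx"), ("3 fractions", "tcp_3fx"), ("5 fractions", "tcp_5fx")):
        ax.plot(sub.gtv_diameter_cm, sub[col], "o-", label=label)
    ax.set_xlabel("GTV diameter (cm)")
    ax.set_ylabel("predicted TCP")
    ax.legend()
    p = outdir / "tcp_by_scheme.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written["fig_tcp_by_scheme"] = p
    return written
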