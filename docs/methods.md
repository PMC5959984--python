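# Methods

## The radial plan surrogate

The package replaces full VMAT treatment planning with a radially
symmetric dose model per plan. A plan is characterized by four
plan-quality indices (maximum and mean PTV dose in % of prescription,
RTOG conformity index, Paddick gradient index), shipped as a packaged CSV
of 48 reference plans (8 spherical GTV diameters 0.5–4.0 cm × margins
0/1/2 mm × coplanar/non-coplanar VMAT). For a radial distribution the CI
and GI pin down a unique two-parameter falloff

    D(r) = D_rx (r_rx/r)^k  for r ≥ r_rx,
    r_rx = (3·CI·V_PTV/4π)^(1/3),  k = 3 ln2 / ln GI,

so the calibrated model reproduces both indices identically. Inside the
prescription isodose the dose ramps linearly from the tabulated maximum at
the centre to D_rx at r_rx; this inner ramp never affects healthy-brain
dose–volume metrics except in one regime (below). Assumptions:

- **Infinite homogeneous medium.** No skull or brain-contour truncation;
  the reference plans placed targets away from critical structures, and
  the dose at clinically relevant isodoses (≥12 Gy) is well inside any
  realistic brain contour for the target sizes considered.
- **Pure radial symmetry.** Real VMAT distributions are mildly
  anisotropic; the model underestimates the printed healthy-brain V12 of
  the two 4 cm reference values by ~7% (12.07 vs 13 cm³ and 30.69 vs
  33 cm³), which we attribute to this.
- **Prescription-isodose sphericity.** CI and GI are volume ratios; mapping
  them onto concentric spheres is exact for spherical targets by
  construction.

## Dose–volume machinery

Healthy brain is defined as everything outside the GTV ("brain minus
GTV"). Closed forms give V(level) = (4π/3)·r(level)³ − V_GTV. The voxel
route renders the model on an isotropic grid (default 1 mm, the reference
plans' calculation grid), with the sphere centre on a voxel corner.
Because V12 is a small difference of two large sphere volumes, plain
centre-in-voxel counting at 1 mm carries several percent error for
sub-centimetre targets; `render_grid` therefore evaluates volumes and DVHs
on a sub-voxel lattice (default 4³ subsamples per voxel, float32,
slab-wise), the standard small-structure practice in DVH engines. With
`supersample=1` the renderer reverts to plain counting, which the test
suite uses to demonstrate grid convergence (2 mm → 1 mm → 0.5 mm).

Cumulative DVHs store volume-at-or-above on uniform dose bins (default
0.1 Gy); queries interpolate linearly, and the inverse query breaks ties
on flat segments toward the higher dose so isotoxic renormalization is
conservative. Plan renormalization ("altering the monitor units") is an
exact rescaling of the dose axis — no re-binning, no re-optimization.

## Isotoxic prescription

Constraints are (dose level, volume, fractions) triples: V12Gy = 10 cm³
at 1 fraction, its linear-quadratic equivalent at 3 fractions, and
V20Gy = 20 cm³ at 5 fractions. The closed-form prescription is
D_IDP = D_c·(r_c/r_rx)^k with r_c = (3(V_c + V_GTV)/4π)^(1/3). When r_c
falls inside the prescription isodose (4 cm GTV with 2 mm margin: the
PTV–GTV shell alone exceeds 10 cm³) the constraint level lies on the
inner ramp; the scaling is then solved through the ramp so the achieved
volume still equals the constraint volume exactly, and the result is
flagged. Every renormalization (analytic or DVH-based) asserts its
post-condition. No clinical cap is applied to isotoxic doses above the
nominal protocol; capping is the caller's decision.

The three-fraction constraint level is used at its exact LQ-converted
value, 19.1696 Gy (the commonly quoted 19.2 Gy is its one-decimal
rounding); the conversion itself is the positive root of
T²/(n·α/β) + T − BED = 0 and round-trips to 1e-9.

## Radiobiology

BED = n·d·(1 + d/(α/β)) with α/β = 3 Gy for late brain toxicity and
12 Gy for brain-metastasis tumor response. TCP is logistic in BED₁₂.
The originally fitted dose–response parameters are not published, so the
default model solves the two-anchor system through the printed
single-fraction operating points (15 Gy → 42%, 24 Gy → 86%), giving
β₀ = −2.2093, β₁ = 0.05590 per Gy BED₁₂. Consequences: absolute TCP
values for fractionated schemes are model-dependent and differ from the
original study's (e.g. we predict 37% at 1×14 Gy where it reported 32%);
the qualitative result — fractionated isotoxic prescription dominates
single-fraction for GTV ≥ 2.5 cm — is parameter-robust and is what the
tests assert. The model is pluggable (`calibrate_tcp` accepts any anchor
set and falls back to least squares for >2 anchors).

## Synthetic cohort

The validation cohort emulates 46 consecutive single-metastasis patients
(coplanar VMAT, 2 mm margin, prescriptions 15–24 Gy). Within the radial
framework a plan enters the isotoxic calculation only through
(V_PTV, CI, GI), so departure from sphericity and planner variability are
injected where they act: GI is perturbed multiplicatively by
exp(N(0, σ)) (clipped at GI = 1.05), around the spherical-plan value
interpolated in log-volume from the packaged table. PTV volumes are drawn
log-uniformly over 0.5–65 cm³ — no clinical volume histogram was
available, and log-uniform spreads patients evenly across the protocol's
size bins. σ is tuned by bisection of a fixed-seed Monte-Carlo estimate so
the cohort's single-fraction isotoxic doses scatter around the spherical
curve with SD = 1.70 Gy, the clinically observed value; the tuned
σ_lnGI ≈ 0.17 then reproduces that scatter on held-out seeds within 10%.

What the generator does *not* emulate: real GTV shape statistics, the
clinical volume distribution, multi-fraction clinical prescriptions, or
CI variability (CI is interpolated deterministically). Passing tests
therefore show the *pipeline* is faithful and the spherical curve is
robust to GI-level shape noise — not that it is validated on real
patients. The scatter distribution is also heavier-tailed than clinical
(small targets amplify GI noise strongly), so individual cohorts can show
larger extremes than the clinical ±4 Gy range.

## Study pipeline and statistics

The factorial sweep evaluates all 48 configurations: nominal prescription
(half-open protocol bins [0,1,10,20,65) cm³ with a closed 65 cm³
eligibility ceiling → 24/21/18/15 Gy), nominal V12, isotoxic dose and TCP
per scheme. The empirical size–dose relationship is fitted with
dose(V) = d_inf + d0·exp(−V/v0) by least squares from three fixed starts
(v0 = 2, 10, 30 cm³), best residual kept. Fit agreement is assessed two
ways: the Pearson chi-squared of the cohort doses against the spherical
curve (dof = n − 3) — reported because it is the field's customary
statement — and a seeded case-resampling bootstrap (default 2000
resamples) giving two-sided percentile p-values for each coefficient
difference being zero. The bootstrap is the more powerful test: a +5 Gy
curve shift at n = 46 yields chi-squared p ≈ 0.02–0.03 but bootstrap
p < 0.01. No multiple-testing correction is applied (single comparison).

Numerical choices: DVH bin width 0.1 Gy; grid extent chosen so the
boundary dose is below 1 Gy (a warning and a `truncated` flag otherwise);
solver tolerances 1e-6 relative (analytic renormalization) and one bin
width (DVH route); all randomness flows through named integer seeds
(numpy PCG64), with replicate seeds derived via `SeedSequence`.

## Limitations

- The falloff exponent is a surrogate, not a planned dose distribution;
  absolute V12 values carry ~10% model uncertainty.
- TCP predictions inherit the two-anchor calibration; they should be read
  as a consistent ranking device, not as absolute outcome probabilities.
- Single-metastasis, single-constraint geometry only; no brainstem/optic
  constraints, no multi-target plans, no NTCP model beyond the threshold
  constraints.
- The 5-fraction constraint (V20 = 20 cm³) is an independent clinical
  limit, not an LQ conversion of the single-fraction one.
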