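# Methods

## The disposition model

A zebrafish eleuthero-embryo exposed to a compound by bath immersion
and/or microinjection is modelled as a single well-mixed compartment of
intrabody amount `A` (ng).  Exchange with the bath is a passive
bidirectional clearance `Q` (L/h) acting on the bath concentration `M`
(ng/L); all loss processes — back-exchange through `Q` plus any one-way
active clearance — are lumped into a single total elimination rate
constant `k` (h⁻¹):

    dA/dt = −k·A + Q·M,        A(0) = Dose

with the closed form

    A(t) = Dose·e^(−k t) + (M·Q/k)·(1 − e^(−k t)).

Assumptions, and why they are reasonable for this system:

- **One compartment, no absorption lag.** Injected tracer disperses from
  the pericardial/intraperitoneal depot within minutes relative to the
  15 min–48 h sampling grid, so `A(0) = Dose` exactly.  Intra-yolk
  injection violates this (the compound stays trapped in the yolk) and is
  deliberately out of scope.
- **Constant bath.** The bath (~5 mL per well) is ≫ the embryo
  (~0.25 µL), so uptake never depletes `M` measurably; `M` is treated as
  constant over 48 h.
- **Lumped elimination.** The active clearance `CL` and the distribution
  volume `V` appear in the mechanistic balance only through
  `k = (Q + CL)/V`; they are not separately identifiable from whole-body
  amount data and are intentionally not represented as parameters.
- **Linear fluorescence.** Whole-body fluorescence is proportional to
  amount, `RFU = FLUOR·A`, with a compound- and instrument-specific
  yield `FLUOR` (RFU/ng).  Absolute RFU is therefore never comparable
  across compounds; every cross-compound metric in the package (RE, RC,
  k, t½, Q) is constructed to be `FLUOR`-free.

Internal units are fixed: ng, h, ng/L, L/h, RFU.  On these scales the
reference magnitudes are mutually consistent: a 2 mg/kg dose into a
0.25 mg embryo is 0.5 ng, and a passive exchange of a few nL/h against a
10 µM bath yields sub-nanogram steady states `M·Q/k`.

The ODE right-hand side is also integrated numerically (LSODA,
rtol 1e−12, atol 1e−18) as an independent oracle for the closed form.
The step tolerances are set two orders tighter than naive because a
per-step rtol of 1e−9 was measured to accumulate ~1e−6 global error over
48 h, the very bound the oracle is meant to certify; at 1e−12 the
worst-case deviation over the tested parameter box is below 1e−8.

## Exposure metrics

All AUCs are closed-form integrals of the fitted model ("fitted
functions"), not trapezoids on raw data; a trapezoid helper exists for
diagnostics only.  Relative Exposure RE(t₁) = AUC_imm/AUC_inj compares
10 µM immersion against the 0.5 ng injection over the same window; the
injection limb uses a single (pericardial) parameterization since the
two injection routes are kinetically equivalent in this model.  The
Relative Contribution of a route to a combined treatment uses the
model's linearity: AUC_combination = AUC_imm + AUC_inj exactly, so
RC_imm + RC_inj = 100 by construction — asserted, not assumed, in the
tests.

## Fitting

One parameter triple (FLUOR, k, Q) per compound is estimated by
unweighted nonlinear least squares over the pooled non-censored
observations of all routes.  The joint fit is what makes the triple
identifiable: the injection decay pins `FLUOR·Dose` and `k`, the
immersion uptake then pins `Q`.  Single-route data trigger an
identifiability warning instead of silently returning a confounded
estimate.

Numerical choices:

- Parameters are optimized as logarithms (positivity by construction,
  uniform scaling across the ~12 orders of magnitude separating `Q` from
  `FLUOR`); the optimizer is Levenberg–Marquardt, i.e. damped
  Gauss–Newton.
- Starting values are moment-based: `k₀` from the log-linear slope of
  the late (≥ 1 h) injection means, `FLUOR₀` from the extrapolated
  intercept over the dose, `Q₀` from the initial immersion uptake slope
  via A(t) ≈ M·Q·t; all clipped positive, with a floor-and-warn path for
  uninformative immersion signals.
- Standard errors are asymptotic (Jacobian-based) on the log scale,
  mapped to the natural scale by the delta method; the residual standard
  error is √(SSE/(n−3)).

**Censoring.** Freshly injected depots self-quench (the compound is
locally concentrated enough to absorb its own emission), so the earliest
injection observations sit systematically below the model.  Two
strategies are provided.  The default automates the visual
residual-plot procedure: fit, flag observations with standardized
residual beyond 2.5, refit, for at most 3 rounds; the censored set can
only grow, and censoring more than 50% of a compound's data raises
rather than silently hollowing out the fit.  The alternative `window`
mode drops injection-route observations before a fixed cutoff (1 h by
default, 3 h for severely quenched compounds), mirroring the
fit-from-1 h-or-3 h convention.  Note the residual rule's detection
power depends on how much of the data carries the artifact: with the
artifact confined to one route it flags essentially all affected points,
whereas an artifact present on every injection route simultaneously
drags the fit toward itself and partially escapes a 2.5σ rule — in that
regime the window mode is the right tool.

## Synthetic data

The generator reproduces the reference study design: seven compounds
spanning LogD −1.96 to 1.73, four exposure conditions (10 µM immersion,
2 mg/kg PC and IP injections, and the combination), sampling at 0.25,
1, 3, 6, 24, 48 h, 10 replicates per cell.  Signals are
`FLUOR·A(t)` times a multiplicative lognormal error parameterized to
have **mean one** (CV 20% by default; the mean-one convention is
recorded in the dataset provenance), optionally plus a small additive
Gaussian background, clipped at zero.  The default truth parameters are
the reference (k, Q) values per compound; the `FLUOR` truths are
arbitrary fixed constants in the 10³–10⁴ RFU/ng range, since
fluorescence yields are instrument-specific and never enter any
cross-compound conclusion.  The injection-quench artifact is modelled as
a fixed 50% attenuation of injection-route signals before 1 h,
configurable per spec.

Randomness is structured as one substream per (compound, route) keyed on
the global seed, so adding a compound to a simulation never perturbs
another compound's draws.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: per-embryo random effects (each observation is
an independent draw, whereas real designs image the same ten larvae
repeatedly), spatial heterogeneity of the signal within the body,
yolk entrapment after intra-yolk injection, photobleaching, and any
dependence of uptake on immersion concentration beyond linearity.

## QSPkR

With n = 7 compounds, the regression analysis is deliberately austere.
Descriptors are first screened into groups with pairwise |Pearson r|
below 0.7 (greedy first-fit in column order; constant columns are
excluded with a warning).  The core model is the centered quadratic in
lipophilicity, y ~ 1 + LogD + (LogD − x̄)², where x̄ is recomputed as the
sample mean of LogD (−0.177 on the reference panel), never hard-coded;
centering decorrelates the square from the linear term, and predictions
are invariant to the centering constant (tested).  Model search is
bidirectional stepwise on the Gaussian AIC, n·log(SSE/n) + 2k, starting
from the intercept-only model, with candidate models capped at three
estimated coefficients so at least three residual degrees of freedom
remain; a model is reported only if its overall F-test clears p < 0.05.
On pure-noise responses this procedure returns "no model" in ~90% of
seeds, and on the reference panel it returns no model for k and t½ —
matching the published null result — while selecting the LogD quadratic
for Q and RE.

Reported statistics follow the standard identities: R²adj =
1 − (1 − R²)(n−1)/(n−p−1), RMSE = √(SSE/(n−p−1)), with an explicit
normal-equations oracle in the test suite guarding the OLS solve to
1e−10.

## LogD assay layer

Calibration lines are fitted by unweighted OLS on per-level replicate
means (five standard levels, 10 → 0.63 µM); replicate %RSD is retained
per level as QC metadata.  The QC gates fire at R² < 0.998 and
%RSD ≥ 10%, the assay's stated acceptance limits.  LogD is
log₁₀(C_octanol/C_Danieau), computed as a difference of logarithms so
that swapping the phases negates the result exactly in floating point.
The logarithm is part of the definition even where a source formula
prints a bare ratio: measured values down to −1.96 are only expressible
on the log scale.

## Imaging

The whole-body readout is the raw sum of pixel intensities inside a
manually delineated contour — no background subtraction by default,
matching the upstream acquisition workflow; a mean-background
subtraction exists for synthetic fixtures only.  Rasterization uses the
even-odd (crossing-number) rule on pixel centers at (col + 0.5,
row + 0.5) in 0-based row-major coordinates; it is implemented directly
(a dozen lines of vectorized scanline code) rather than through a
plotting library's point-in-path test, whose sampling conventions
differ from this contract.  Exposure-time correction is linear
(RFU × t_ref/t), and 16-bit file I/O flags saturation at the dtype
maximum.  The synthetic renderer places an ellipse-plus-tail embryo
whose interior sum equals `FLUOR × amount` exactly before Poisson
background, which makes the amount → pixels → RFU chain testable end to
end.

## Problem sizes in the test suite

Monte-Carlo checks use the study's own design (10 replicates × 6 times ×
3 routes) across 50 seeds for parameter recovery and quench detection,
100 random draws for the closed-form/ODE equivalence and the stepwise
null behaviour, and 20–50 draws for the smaller property checks; the
whole suite runs in well under a minute.

## Known limitations

- The residual-censoring rule standardizes by a single residual standard
  error although the noise is proportional; heteroscedasticity means
  low-signal outliers are under-weighted.  The window mode sidesteps
  this.
- Asymptotic standard errors at n ≈ 180 observations per compound are
  adequate but not exact; no bootstrap is wired in.
- Published summary values are printed to 2–4 significant figures;
  quantities recomputed from those rounded inputs (e.g. R²adj of the RE
  regressions, the t½ column) can differ from their published
  counterparts by a few percent, which is an irreducible property of the
  inputs, not of the implementation.
- Between-embryo variance components are not modelled (no mixed-effects
  layer), matching the estimation approach this package reimplements.
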