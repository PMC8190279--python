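# zfpk

Pharmacokinetics of fluorescent compounds in zebrafish eleuthero-embryos.

Zebrafish eleuthero-embryos (3–5 dpf) are a workhorse for pharmacology and
toxicity screening, but how much of a compound actually gets *into* the
animal depends strongly on the administration route: bath immersion, the
standard screening route, can severely under-expose the body for
hydrophilic compounds, while microinjection (pericardial or
intraperitoneal) delivers a known dose instantly. `zfpk` implements the
quantitative machinery for comparing these routes from whole-body
fluorescence imaging of fluorescent tracer compounds:

- a **one-compartment amount/fluorescence model** with passive bath
  exchange,

  dA/dt = −k·A + Q·M,  A(0) = Dose, so
  A(t) = Dose·e^(−k·t) + (M·Q/k)·(1 − e^(−k·t)),
  RFU = FLUOR·A

  with k the total elimination rate constant (h⁻¹), Q the passive
  bidirectional exchange with the medium (L/h), M the bath concentration
  (ng/L) and FLUOR the compound-specific fluorescence yield (RFU/ng);
- **joint nonlinear least-squares fitting** of (FLUOR, k, Q) per compound
  across routes, with iterative residual-based censoring of
  quenching-distorted early injection points, asymptotic standard errors
  and t½ = ln 2 / k;
- **exposure metrics** from closed-form AUCs: Relative Exposure
  RE(t₁) = AUC_imm(0,t₁)/AUC_inj(0,t₁) and the Relative Contribution
  split RC_route = AUC_route/AUC_combination × 100 of a combined
  treatment;
- **QSPkR regression**: descriptor collinearity screening, the centered
  quadratic lipophilicity model y ~ 1 + LogD + (LogD − x̄)², and
  bidirectional stepwise AIC selection with a significance gate;
- a **shake-flask LogD** calculation layer (calibration lines, %RSD and
  R² QC gates, log₁₀ phase ratio);
- **image quantification**: even-odd polygon rasterization of whole-body
  contours, integrated pixel-intensity RFU, exposure-time correction,
  plus a synthetic embryo renderer for end-to-end testing;
- a seeded **synthetic-data generator** reproducing the reference study
  design (7 compounds × 4 routes × 6 sampling times × 10 replicates,
  mean-one lognormal noise, optional injection-quench artifact).

## Worked example

Exposure metrics for the built-in seven-compound reference panel
(10 µM immersion vs 2 mg/kg ≈ 0.5 ng injection):

```sh
$ zfpk metrics --window 3 --window 48 --outdir out
$ column -s, -t out/exposure_metrics.csv   # abridged
compound  window_h    re     rc_imm_pct  rc_inj_pct
S-CY3A         3     0.005       0.478      99.522
S-CY3A        48     0.084       7.722      92.278
S-CY5.5A      48     0.203      16.881      83.119
R6GA          48     0.780      43.821      56.179
CY3A           3     0.136      12.001      87.999
CY3A          48     2.897      74.338      25.662
```

Reading: after 3 h of immersion even the most lipophilic compound (CY3A,
LogD 1.73) has accumulated only 14% of the exposure a 0.5 ng injection
provides (RE = 0.136), and immersion contributes 12% of a combined
treatment; over 48 h CY3A's bath uptake overtakes the injected dose
(RE = 2.9, 74% of the combined exposure), while the most hydrophilic
compound (S-CY3A, LogD −1.96) still sits at RE = 0.08.

The QSPkR stage regresses the PK quantities on the molecular descriptors:

```sh
$ zfpk qspkr --outdir out
$ column -s, -t out/qspkr_models.csv
response  model                                              r2_adj    rmse       p_value
Q         1.357e-09 + 1.699e-09*LogD + 8.428e-10*(LogD-c)^2  0.817828  1.198e-09  0.01475
ke        none significant
t_half    none significant
RE_3h     0.01953 + 0.02554*LogD + 0.01466*(LogD-c)^2        0.741245  2.291e-02  0.02976
RE_48h    0.3239 + 0.5353*LogD + 0.3302*(LogD-c)^2           0.729826  5.031e-01  0.03244
```

Uptake (Q) and relative exposure depend parabolically on lipophilicity —
LogD is the only descriptor the stepwise search retains — while the
elimination-side quantities k and t½ show no significant structure at
n = 7.

A full synthetic round trip (simulate → fit with censoring → metrics →
QSPkR) is one command:

```sh
zfpk run --seed 1 --outdir out
```

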