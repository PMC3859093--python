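# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices behind `powdercal`.

## Problem setting

Reflectance spectra of powder mixtures are acquired on three instrument
bands — VIS 360–700 nm (328 channels), SNIR 700–1040 nm (378 channels,
same instrument as VIS), LNIR 937–2500 nm (241 channels, second
instrument) — and paired with the reference notoginseng (NP) mass
percentage. Designs A and B adulterate NP with a single component (SFP or
CF respectively) at 0/5/10/15/20 %; Design C uses both adulterants over a
3×3 grid of {5, 10, 15} % each. Every treatment has 20 samples (100, 100
and 180 samples per design); 15 samples per treatment calibrate, 5 are
held out for prediction. No spectral preprocessing (SNV, MSC, derivatives)
is applied anywhere: the calibration methods operate on raw reflectance,
which is why models built on a handful of selected wavelengths remain
applicable to wavelength-dispersive hardware.

## PLS regression

PLS1 by NIPALS on mean-centered X and y (no unit-variance scaling;
reflectance magnitudes are information). Each latent variable (LV) a
extracts a weight vector w_a ∝ X_aᵀy_a, scores t_a = X_a w_a, loadings
p_a = X_aᵀt_a/t_aᵀt_a and y-loading q_a, followed by deflation of both
blocks. The coefficient vector on the original variables is
b_k = W_k (P_kᵀW_k)^(−1) q_k, using the leading k×k block so the k-LV
sub-models are nested; predictions are b0 + X·b with
b0 = ȳ − x̄ᵀb, and agree with the score-path prediction to 1e-8.

- LV count is chosen by k-fold cross-validation (default 5 folds,
  contiguous after a seeded shuffle), minimizing RMSECV with ties broken
  toward fewer LVs; the cap is 10 LVs. Thanks to nesting, each fold is
  fitted once at the deepest LV count and evaluated at every depth.
- Requests beyond the numerical rank truncate at the LV whose score norm
  falls below 1e-12 of the first score norm, with a warning
  (`RankDeficiencyWarning`), never silently.
- With the full LV complement on full-rank tall data, PLS fitted values
  equal ordinary least squares; this and NIPALS score orthogonality are
  enforced in tests (plus an independent cross-check against
  scikit-learn's PLS implementation, which is test-only — the package
  itself has no scikit-learn dependency).

## LS-SVM regression

Least-squares SVM regression with the RBF kernel
K(u, v) = exp(−‖u−v‖²/σ²). Training solves the (n+1)×(n+1) KKT system

    [0  1ᵀ      ] [b]   [0]
    [1  Ω + I/γ ] [α] = [y]

whose structure implies Σα_i = 0 and training residuals e_i = α_i/γ; both
are asserted in tests. Spectra enter unscaled.

- Hyperparameters (γ, σ²) come from a grid search minimizing leave-one-out
  RMSECV: both axes log-spaced over 10⁻¹…10⁶ (8 points), then one
  refinement pass at 3× finer log-spacing around the coarse optimum. Ties
  break toward smaller γ, then smaller σ².
- LOO residuals use the closed-form identity e_i = α_i/(A⁻¹)_{ii} (one
  factorization instead of n refits). The naive n-refit loop is the
  normative definition; the shortcut is tested against it to 1e-8 on
  20-sample problems.
- A numerically singular system raises with advice to decrease γ; no
  jitter is added silently. Grid points whose system is singular are
  skipped during search.

## CARS wavelength selection

Each of N = 50 sampling runs: (1) draw ⌈0.8·n⌉ calibration samples without
replacement and fit a PLS model on the currently retained variables, its
LV count chosen by inner 5-fold CV; (2) convert coefficients to weights
w_j = |b_j|/Σ|b_j|; (3) enforced reduction — keep the top ⌈r_i·p⌉
variables by weight, where r_i = a·e^(−k·i) with a = (p/2)^(1/(N−1)) and
k = ln(p/2)/(N−1), so r_1 = 1 and r_N = 2/p; (4) adaptive reweighted
sampling — ⌈r_i·p⌉ draws with replacement, probability proportional to
weight; variables drawn at least once survive ("survival of the fittest");
(5) record the 5-fold RMSECV of a PLS model on the surviving subset over
the whole calibration set. The subset with minimal RMSECV wins; exact ties
go to the later (smaller) subset. The prediction set never enters
selection.

Numerical choices that mattered:

- The ARS draw count follows the EDF schedule in the *original* variable
  count p even when fewer variables survive. Capping draws at the current
  retained size compounds the ~37 % per-run loss of sampling-with-
  replacement and collapses the retained-count trace to 2 variables within
  a dozen runs; with the absolute schedule the trace follows the intended
  exponential decay.
- One fold assignment (derived from the CARS seed) is shared by all runs,
  so per-run RMSECV values are comparable; independently drawn folds per
  run make the best-run choice partly fold luck.
- If ARS ever leaves fewer than 2 variables, the best 2 by weight are
  retained and the event is logged.
- Coefficient paths record, per run, the full-calibration refit
  coefficients of surviving variables and exact zeros for eliminated ones;
  an eliminated variable never returns.

## Evaluation statistics

r is the Pearson correlation; R² = 1 − SS_res/SS_tot on the respective
sample set (calibration or prediction) — note R² can be negative for a
badly biased model and equals 1 exactly iff the RMSE is 0. RPD uses the
sample (n−1) standard deviation of the prediction set's reference values
divided by RMSEP, the dominant chemometrics convention, with the usual
reading: ≥ 3 usable for most applications, ≥ 2.5 usable for screening.
Robustness is |RMSECV − RMSEP|; gaps above ~2 % by mass flag overfitting.

## Synthetic-data generator

The generator emulates the statistical structure this analysis faces, not
any specific instrument. Pure-component spectra are flat backgrounds
(reflectance 0.65) minus Gaussian absorption dips at the classical
overtone/combination positions: 450 nm (colour), 840 and 980 nm (O–H
second overtone region), 1225 (C–H second overtone), 1450 (O–H first
overtone), 1940 (water combination, identical depth in all three
components), 2140 (C–H/C=C combination), 2380 and 2488 nm (starch-region
combinations). A sample of a treatment with mass fractions f is

    R(λ) = m · Σ_c f_c R_c(λ) + β0 + β1 (λ − λ̄) + ε(λ),

with per-sample scatter m ~ N(1, 0.01), baseline offset
β0 ~ N(0, 0.002), baseline slope β1 ~ N(0, 1e-5 /nm) and i.i.d. channel
noise ε ~ N(0, 0.005), clipped to [0, 1]. All noise scales are fabricated
stand-ins (no repeatability figures exist for the real measurements, which
averaged 10 scans); they are exposed on `NoiseModel` and documented here
as tunable.

Component band depths were constructed, before freezing, to encode the
qualitative physics the study reports and to land full-spectrum PLS on
Design A in the realistic r_P ≈ 0.9–0.97 regime rather than being
trivially perfect:

- The three pure spectra share all band centers and differ only in depths,
  giving pairwise correlations > 0.95 on the LNIR grid ("similar chemical
  bonds, similar profiles").
- Below 1040 nm the two adulterant contrast spectra are **anti-parallel
  with equal magnitude** (NP−CF = −(NP−SFP)). Each single-adulterant
  design is then well determined on VIS/SNIR, but in Design C the only
  adulterant-related spectral degree of freedom is proportional to
  (SFP% − CF%), which is uncorrelated with NP% over the 3×3 design — so
  two-adulterant quantification *fails* on VIS and SNIR, as it should.
- In the long-wave region the two contrasts are genuinely independent
  directions (CF's LNIR contrast is ~0.85× the SFP contrast at ~60°), so
  Design C is identifiable there but noisier than A or B — LNIR succeeds
  where VIS/SNIR fail, and A/B beat C in every band.

What the generator does **not** emulate: nonlinear scattering
(Kubelka–Munk), particle-size effects, wavelength-dependent noise,
instrument drift, or real component spectra. Passing tests therefore
demonstrate that the algorithms recover planted structure under the stated
noise model at the study's sample sizes — not that any specific real
powder system behaves this way.

### Planted-signal recovery

The CARS recovery check uses a variant generator in which NP and SFP
differ only at three narrow bands (width 3 nm, depths 0.30/0.25/0.20 at
1200/1700/2200 nm) and noise is zero. Off-band channels are then exactly
constant across samples, receive exactly zero sampling weight, and CARS
isolates the planted channels (within ±10 nm) for every seed. With
appreciable i.i.d. noise this sharpness is lost by construction, not by
defect: removing a pure-noise channel neither helps nor hurts a PLS model
measurably, so the RMSECV-over-runs valley is flat and the argmin run is
decided by cross-validation noise. The noisy regime is exercised
separately by the paper-scale recovery tests, which assert performance
and orderings rather than exact support recovery.

## Experiment orchestration

`run_experiment` derives per-stage seeds from one global seed by hashing
"stage:design:band" (CRC-32) into [0, 2³¹−1), so every cell is
independently reproducible and reruns are bit-identical. Method II runs
CARS once per (design, band) on the calibration set and reuses the
selection for both calibrators. A failing cell is logged and skipped
without aborting the matrix. The default 36-cell matrix takes a few
seconds on one CPU at the study's sample sizes (n ≤ 180, p ≤ 378).

## Known limitations

- CARS selected-variable counts on the default synthetic data (tens of
  channels) are larger than typical real-data selections (3–11), because
  every channel of a broad Gaussian band carries signal and channel noise
  is i.i.d.; subset size, not subset location, is the weakly determined
  quantity.
- On this generator Method II (selected wavelengths) performs at or
  slightly below Method I (full spectrum): with strictly linear mixing and
  i.i.d. noise the full spectrum can always average noise down and cancel
  multiplicative scatter, so selection cannot improve prediction, only
  parsimony. The real-data advantage of selection comes from
  noise-dominated and redundant spectral regions the generator does not
  emulate.
- The LS-SVM closed-form LOO inverts the KKT matrix once per grid point;
  for n beyond a few thousand samples a factorization-based update would
  be preferable.
- The published calibration equations are fixtures for a specific
  instrument and sample set; applying them to other spectra, synthetic or
  real, is not meaningful beyond worked-example arithmetic. The Design C
  equation cites 2496 and 2502 nm although the stated LNIR range ends at
  2500 nm; both are encoded verbatim.
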