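# Methods

This note documents the models and numerical choices behind `nirscal`:
what each stage assumes, which parameters matter, what the synthetic data
do and do not emulate, and where genuinely open design questions were
settled.

## Spectra model and preprocessing

Spectra are apparent absorbance log(1/R) on an even wavelength grid,
by default 1100–2500 nm at 2 nm (701 points). All preprocessing operates
per spectrum except MSC:

- **SNV** standardises each spectrum to mean 0, sample SD 1 (n−1
  denominator). It is affine-invariant and idempotent.
- **Detrend** removes a least-squares polynomial baseline in wavelength.
  The degree is 2, the standard SNV-detrend formulation; the wavelength
  axis is centred and scaled before the fit purely for conditioning.
- **SNV+DT** applies SNV first, then detrend, following the originating
  convention for that combination.
- **MSC** regresses each spectrum on a reference spectrum over
  wavelengths and inverts the fitted affine map. The reference is the
  mean calibration-set spectrum. It is fitted once on calibration data,
  stored in the model, and reused verbatim for validation and prediction
  sets — scatter parameters are never refitted from new data. Slopes
  below 1e-8 in magnitude are reported as a scatter-correction failure.
- **Gap–segment derivatives** use the WinISI-style notation
  `(d, g, s1, s2)`: boxcar smooth over `s1` points, then over `s2`
  points (`s2 = 1` meaning no second smoothing), then `d` applications of
  the gap difference `D[i] = s[i + g/2] − s[i − g/2]`; odd gaps use
  symmetric half-point interpolation. Units are data points (2 nm each).
  Edges are truncated, never padded — padding invents data — and the
  trimmed wavelength axis is carried with the output, so a fitted model
  knows exactly which axis its coefficients live on.

The candidate treatment grid is the 4 × 2 product
{SNV, DT, SNV+DT, MSC} × {(1,4,4,1), (2,4,4,1)} — eight pipelines.

## Modified PLS

Calibration is PLS1 via NIPALS. With `modified=True` (the default), after
each factor is extracted the columns of the X-residual matrix are divided
by their sample standard deviation (n−1; columns with SD < 1e-12 keep
scale 1 so dead channels are not amplified) before the next factor is
computed — the Shenk–Westerhaus "modified" variant that equalises
residual variance across wavelengths. The per-factor scalings are folded
into a single coefficient vector by propagating the deflation operators,
so prediction is one centring and one dot product; an equivalence test
guarantees the folded vector reproduces the sequential recursion. At full
rank the predictions coincide with ordinary least squares, which is used
as an oracle in the tests; the unmodified path is additionally
cross-checked against scikit-learn's PLS regression. No autoscaling of X
is applied before the first factor (absorbance-space convention);
`x_scale` exists in the model for completeness and is 1.

**Factor selection.** Grouped cross-validation: samples are randomly
assigned to `n_groups = 5` groups (seeded); each group is predicted by a
model refitted — including the MSC reference — without it. SECV(f) pools
held-out squared errors (denominator n) at every candidate factor count
up to `max_factors = min(16, n/3)`. The chosen count is the smallest f
with SECV(f) ≤ 1.02 × min SECV, a parsimony guard against flat
overfitting plateaus; pure argmin is available. The 2% window and the
group count are conventional values fixed a priori.

**Outlier elimination.** Per pass: cross-validate, form
T_i = |ŷ_i − y_i| / SECV from held-out predictions, drop samples with
T > 2.5, refit. At most 2 passes; the process aborts if more than 25% of
the original samples would be discarded. The threshold and pass count
follow common chemometric practice; they matter little on clean data and
mainly protect against reference-value blunders.

## Validation statistics

SEP is bias-corrected by default, sqrt(Σ(e−ē)²/(n−1)); the RMSEP
(sqrt(Σe²/n)) variant is behind a flag since reported tables rarely state
which is used. SEC uses n − f − 1 degrees of freedom with f latent
factors. Bias is mean(predicted − reference). The slope is from the
regression of *reference on predicted* (the reporting convention in which
the laboratory value is the response), and r² is the squared Pearson
correlation in both calibration and validation roles (a 1 − SSE/SST
variant is available). RPD = SD(reference)/SEP and RER = range/SEP;
RPD ≥ 3.0 and/or RER > 10 flag a calibration as usable for quantitative
analysis. Report tables round RPD/RER to one decimal, half away from
zero; raw values are retained. By construction every emitted report
satisfies rpd·se = sd_ref and rer·se = range_ref exactly.

## Model comparison

Three nested OLS structures relate laboratory FN to NIRS-predicted FN:
common line; species intercepts (common slope); species intercepts and
slopes. Species are treatment-coded; the log-likelihood is Gaussian at
the MLE (variance SSE/n). K counts the intercept, all coefficients, and
the residual variance, so with 5 species K = 3, 7, 11. AICc =
−2 logL + 2K + 2K(K+1)/(n−K−1); Δi and Akaike weights follow. The n
entering the correction defaults to the number of paired observations
(80 in the default study) and is user-settable, since with external
pairs the effective sample size is a judgement call. Exact-AICc ties are
broken toward smaller K. Residual diagnostics (Shapiro–Wilk,
Breusch–Pagan) are advisory only.

## Bland–Altman agreement

Differences d_i = a_i − b_i (fixed direction: monospecies minus
multispecies prediction) give mean d, SD (n−1), and limits d ± 1.96·sd.
CIs use the classical small-sample approximations — half-width
t·sd/√n for d and t·sd·√(3/n) for each limit — with t quantiles by
default and z behind a flag, since published analyses rarely say which
they used. Under normal differences the expected fraction of points
outside the limits is 5%, which the tests verify at n = 10⁴.

## Synthetic data generator

The generator encodes the data-generating process the analysis assumes,
with defaults fixed to the study conditions: five calibration species
with their FN means, SDs and truncation ranges (e.g. rabbit 1.288 ±
0.569 in 0.75–2.74 % DM), calibration/validation counts of
60+14 / 60+10 / 68+17 / 77+19 / 80+20 (345 + 80), five hold-out species
(71 samples), two scans per sample.

Each clean spectrum is a sloping baseline (species-specific offset and
tilt) plus six Gaussian bands: water (1450, 1930 nm), fat (1730 nm) and
the protein/starch combination region (2106, 2312, 2350 nm). The FN link
is affine — Beer–Lambert at low concentration — and confined to the
2100–2350 nm region, positive at 2106 and negative at 2312/2350 nm
(higher nitrogen reduces absorption there). FN-independent band
amplitudes carry per-sample relative jitter (8%) and per-species scale
factors, giving species their own spectral signatures. Each replicate
scan observes b·clean + a + ε with b ~ LogNormal(0, 0.05) and
a ~ N(0, 0.02) (particle-size scatter) and white noise ε with SD 5e-4
absorbance. Truncated-normal FN uses rejection sampling, which is
adequate for bounds within ~3 SD of the mean.

The key error parameter is `spectral_fn_noise_sd = 0.03 % FN`: a
per-sample perturbation of the FN value that drives the spectrum,
decoupling spectrum from reference value. It is the irreducible error
floor of any calibration on these data (SECV cannot fall below it) and
stands in for combined laboratory and matrix error. The value keeps the
default SECV on the same few-hundredths-of-%DM scale seen in real faecal
FN calibrations while leaving enough headroom that narrow-FN-range
hold-out species (goat SD 0.234, cattle SD 0.267, n = 12) can still show
r² well above 0.86: with floor σ and reference SD s, the expected
validation ρ² is ≈ 1 − (σ/s)², which at σ ≈ 0.1 would drop to ~0.82 for
goat — structurally below that bar — whereas σ = 0.03 puts all species
near 0.99 in expectation, where small-sample fluctuation at n = 12 is
tolerable.

What the generator does *not* emulate: real covariance structure between
constituents (fibre, fat and protein co-vary with diet), wavelength-
dependent scatter, instrument drift, peak shifts (the real nitrogen
effect includes a shift at 2312/2350 nm, modelled here only as an
amplitude change), or reference-method bias. Passing the end-to-end
tests therefore shows the pipeline is correct and well-calibrated under
its own assumptions, not that any particular accuracy will be attained
on real faeces.

The companion generator `simulate_lab_nirs_pairs` produces
(lab FN, NIRS FN, species) tuples with species intercepts of SD 0.15 %
DM, common slope 1, residual SD 0.10 % DM and per-species predictor
spread 0.45 % DM — the structure under which the additive model is true.
The additive model's Akaike weight exceeds 0.5 in ~93% of replicates at
n = 80; the shortfall from 100% is the pivotal likelihood-ratio tail of
spurious interaction fits (≈ P(F₄,₇₁ > 2.4)) and does not depend on the
chosen effect sizes.

## Problem sizes and determinism

The default study (345/80/71 samples, 701 wavelengths, 8 treatments,
5-group CV, ≤ 16 factors, ≤ 2 outlier passes) runs end-to-end in well
under a minute on one core; the model-selection experiment uses 200
replicates of n = 80 and the limits-of-agreement calibration 10⁴ pairs.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; reruns with the same seed are bit-identical.

## Known limitations

- The "modified" PLS variant follows the published Shenk–Westerhaus
  description; the proprietary WinISI implementation may differ in edge
  conventions (its derivative edge handling is likewise unpublished —
  truncation is assumed here).
- Outlier elimination operates on the pooled calibration set; per-species
  elimination within a pooled calibration is not implemented.
- No Mahalanobis (GH) spectral outlier screening; only the T residual
  criterion.
- PLS2, wavelength selection, repeatability-file corrections and
  regression-based Bland–Altman variants are out of scope.
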