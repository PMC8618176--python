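# Methods

## The monitoring problem

Chloraminated drinking-water systems lose their monochloramine (NH2Cl)
residual to decay; the released free ammonia can then be oxidised by
nitrifying bacteria to nitrite and nitrate (together: NOx⁻, reported as
mg-N/L). Rising NOx⁻ is an early warning of nitrification. All four major
UV absorbers in such water overlap in the 200–245 nm window: NH2Cl peaks at
245 nm, nitrite at 210 nm, nitrate near 205 nm, and natural organic matter
(NOM) contributes a featureless continuum. A plain difference between a
later spectrum S_t and the baseline S_0 therefore mixes the NOx⁻ gain with
the NH2Cl loss. The method implemented here separates them optically, with
no reagents.

## Chloramine-decay compensation (the Δ245 anchor)

Nitrate and nitrite are effectively transparent at 245 nm, while NH2Cl
absorbs maximally there, so the baseline-minus-sample offset at 245 nm,
Δ245 = S_0(245) − S_t(245), measures decay alone. On pure-NH2Cl dilution
series the offset at any wavelength i in 200–244.5 nm is a linear function
of the offset at 245 nm. `ChloramineCompensation` fits one ordinary
least-squares line per modelled wavelength (90 wavelengths, 0.5 nm steps)

    Δ_i = slope_i · Δ245 + intercept_i

to all C(n,2) ordered concentration pairs of the calibration series
(pairs oriented higher-minus-lower so anchors are nonnegative; a
`pair_mode="baseline"` switch restricts to pairs against the top
concentration). Under Beer–Lambert behaviour the slopes equal the
absorptivity ratio ε(λ_i)/ε(245) and the intercepts vanish; intercepts are
fitted anyway so real-data deviations surface in the per-wavelength R² and
RMSE diagnostics rather than being hidden. Applying the model to a
monitoring sample gives the estimated decay-only spectrum
Ŝ_NOM+NH2Cl(λ_i) = S_0(λ_i) − Δ̂_i, and the isolated NOx⁻ spectrum is
S_t − Ŝ_NOM+NH2Cl.

Numerical choices:

* A negative sample anchor (absorbance *rose* at 245 nm) cannot be decay;
  it triggers a warning and zero compensation, which reduces the isolation
  to the plain difference S_t − S_0.
* Beyond the anchor (245.5–300 nm) the decay offset uses the band's
  symmetry: the offset at 245 + d equals the modelled offset at 245 − d,
  and past the mirror range the fall-off follows a log-quadratic
  extrapolation of the fitted slopes (exact for a Gaussian band).
  Quantification uses only 200–245 nm, so this choice cannot affect
  reported concentrations.
* Wavelength comparisons use a 1e-6 nm tolerance; grids are uniform with
  0.5 nm default step. Spectra store (but never silently rescale) the
  optical pathlength; all operations require equal pathlengths, since a
  different cell implies a different calibration, not a rescale.
* R² here and throughout is the squared Pearson correlation. Note this
  form is invariant under affine transforms of the predictions (perfect
  anticorrelation also scores 1) and is *not* 1 − SS_res/SS_tot; model
  selection therefore never uses it (see below).

## NOx⁻ quantification (support-vector regression)

`NOxRegressor` maps the 91 absorbances at 200–245 nm (0.5 nm steps) of an
isolated NOx⁻ spectrum to the combined NOx-N concentration. Features and
labels are min-max scaled to [−1, +1] (constant features map to 0; values
outside the training range extend beyond ±1 unclipped, keeping
extrapolation visible). The regression is epsilon-insensitive SVR with an
RBF kernel by default; linear, polynomial and sigmoid kernels are
available. Defaults:

| parameter | default | meaning |
|---|---|---|
| C | grid-searched over {0.1, 1, 10, 100, 1000} | penalty beyond the ε tube |
| γ | grid-searched over {0.001, 0.01, 0.1, 1} | RBF kernel width |
| ε | 0.001 (scaled label units) | insensitivity margin |
| folds | 10 | cross-validation folds (seeded shuffle, no stratification) |

Hyperparameters are selected by pooled 10-fold cross-validation RMSE in
mg-N/L, with ties broken toward smaller C, then smaller γ; RMSE is used
rather than R² precisely because of the affine blind spot noted above. The
selected model is refit on all data. Predictions are inverse-scaled,
clipped at zero, and flagged as extrapolations above the training ceiling
(2.4 mg-N/L for the default standards design: nitrite and nitrate each up
to 1.2 mg-N/L). Trained models persist as JSON (support vectors, dual
coefficients, intercept, scalers); prediction evaluates the kernel
expansion directly from the stored arrays, and a test cross-checks that
expansion against libsvm's own predictions.

A `LocalCalibration` estimator fits the site-specific line
lab = a·predicted + b for stations where laboratory NOx-N values exist; the
monitoring pipeline applies it, when supplied, before the alert check.

## Monitoring and alerting

`run_monitoring` (CLI: `noxmon monitor`) takes a time-ordered series whose
first spectrum is the baseline, and per timestamp computes Δ245 → predicted
Δ̂_i → decay estimate → isolated NOx⁻ spectrum → NOx-N estimate →
threshold check. Reported concentrations are relative to the baseline
(whose NOx⁻ content is defined as zero); a known baseline concentration can
be added back via configuration. The default alert threshold of
0.05 mg-N/L follows common utility guidance for a nitrite increase and is
applied here to the combined NOx-N change; it is configurable. Re-baselining
is done by starting a new series (or passing a different leading spectrum),
matching how an operator would reset after a water-quality change.

## The synthetic-spectra generator

No instrument data ship with the package; `noxmonitor.synth` generates
every input with known ground truth.

**Component bands.** Each species' extinction curve is parametric:
NH2Cl is a single Gaussian at 245 nm (σ = 22 nm, ε₂₄₅ = 0.0086 AU cm⁻¹ per
mg/L — near the literature molar absorptivity, and broad enough to retain
realistic absorbance down to 200 nm). Nitrite has its primary band at
210 nm and a weak secondary at 355 nm; nitrate a primary at 205 nm, a weak
long-wavelength shoulder at 220 nm, and a weak secondary at 302 nm; at
equal mg-N/L nitrate absorbs more strongly than nitrite at their peaks.
The nitrogen-species bands are *truncated* Gaussians that reach exactly
zero ~30 nm from their centres: real nitrate/nitrite absorptivity between
the primary and secondary bands is below 0.1% of peak, and that
transparency at the 245 nm anchor is the premise that lets the anchor
offset be read as decay-only. NOM is an exponential continuum
0.055·exp(−0.015(λ−200)) AU cm⁻¹ per mg-C/L, which puts its 254 nm
specific absorbance in the typical range for treated waters. Absolute
amplitudes are free parameters of the generator — chosen once for realism —
while every peak position, ordering and crossing is structural.

**Apparent nitrate peak shift.** Strict Beer–Lambert additivity cannot move
an argmax with concentration. The observed rightward drift of the nitrate
peak at high concentration is reproduced through an optional hard detector
ceiling (`saturation_AU`): clipping the asymmetric band (primary +
long-wavelength shoulder) produces a flat-topped apex whose conventional
peak reading — the plateau midpoint, `apparent_peak_nm` — lies above
205 nm.

**Decay/nitrification scenarios.** `DecayScenario` evolves a mixture as:
first-order NH2Cl decay (rate `k_decay`); each mg of NH2Cl lost releases
`ammonia_yield` mg-N of free ammonia (default 0.25 mg-N/mg, a configurable
bookkeeping constant, not a mechanistic value); the ammonia pool converts
to NOx-N along a logistic curve (onset day, rate per day) normalised so
conversion is exactly zero at t = 0, split between nitrite and nitrate by
`nitrite_fraction` (default 0.5); DOC may drift linearly by at most
0.2 mg-C/L over the horizon (NOM is assumed stable relative to
chloramine). Nitrogen is conserved to 1e-9 at every timestamp, and equal
seeds give bit-identical series. Free ammonia and free chlorine are
spectrally inert; dichloramine is excluded (high-pH chloramination keeps it
below 0.1 mg/L). Six preset scenarios emulate a bench design of
unprocessed / filtered (microbes removed, no conversion) / enhanced
(+0.8 mg-N/L ammonia, faster conversion) waters at 4.3 and 1.3 mg/L
initial NH2Cl.

**Standards.** `standard_solution_mass` converts a requested mg-N/L target
to grams of KNO3 or NaNO2 using standard atomic masses; it is always on the
nitrogen basis (100 mg-N/L from KNO3 in 1 L requires 0.7218 g; the same
target from NaNO2 requires 0.4926 g — a mass of 0.15 g would correspond to
100 mg/L *as nitrite ion*, about 30.4 mg-N/L, a units distinction worth
keeping explicit). The default training design is the Cartesian product of
15 per-species levels spanning 0–1.2 mg-N/L (225 mixtures, combined labels
up to 2.4 mg-N/L) with 0.001 AU Gaussian instrument noise.

**What the generator does not emulate.** Particle/turbidity absorbance
(samples are assumed filtered), dichloramine, pH effects (none were
significant in the 7–9 range for this chemistry), chemical interactions
between species, instrument drift and stray-light nonlinearity (other than
the idealised hard ceiling), and NOM composition changes beyond a linear
DOC drift. Passing tests on synthetic data therefore demonstrate the
pipeline's correctness under Beer–Lambert additivity with Gaussian noise —
not robustness to matrix effects in real distribution-system water, which
is what local calibration against laboratory data is for.

## Problem sizes and determinism

The shipped tests and the acceptance script use: a 10-level NH2Cl dilution
series (0.2–5 mg/L, 45 pairs), the 225-mixture standards design, a 5 × 4
hyperparameter grid with 10-fold cross-validation, and weekly
eight-week monitoring series (9 spectra of 201 points). These sizes keep
any single run in seconds while exercising every code path at the same
resolution a bench spectrophotometer produces. Every random draw flows
from an explicit seed (`numpy.random.default_rng`); CLI outputs embed the
seed and a configuration hash, and rerunning any command with the same
inputs is byte-identical.

## Known limitations

* Relative quantification only: a series whose baseline already contains
  NOx⁻ reports changes, not totals, unless a baseline concentration is
  supplied.
* The compensation assumes the 245 nm offset is pure decay; slow NOM loss
  over long windows biases it (use short windows or re-baseline).
* The alert threshold comparison is pointwise per timestamp; values within
  the method's ±0.01 mg-N/L precision of the threshold can flip either
  way.
* The SVR is only trusted inside its training hull; predictions above
  2.4 mg-N/L are flagged, and high-concentration work calls for a shorter
  pathlength cell and a new calibration.
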