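# Methods

## Scope and data model

`padquant` quantifies colorimetric µPAD assays from the mean R, G, B
intensities of circular detection zones. The atomic datum is a
`ZoneMeasurement` (zone id, concentration, replicate, per-channel means
on the 0–255 scale, pixel count); a `BlankReference` aggregates the
zero-concentration zones (per-channel mean and replicate SD). Everything
downstream — the nineteen signal transforms, calibration, figures of
merit, discrimination scoring — operates on these two objects, so image
files and tabular exports are interchangeable entry points.

## ROI extraction

A pixel belongs to a zone when its centre lies within `radius`
(inclusive) of the zone centre; coordinates are 0-based, x = column,
y = row, origin top-left. This membership rule is simple, exactly
reproducible by per-pixel enumeration (the test oracle), and matches how
ImageJ-style ROI means are taken over whole circles. Channel means are
never rounded. Images load as float64 on the 0–255 scale: 16-bit sources
are rescaled by 255/65535, greyscale replicated to three channels, alpha
discarded; CMYK is rejected rather than guessed at. No colour management
is attempted — scans are assumed sRGB-like, and JPEG chroma artefacts are
accepted as-is.

Grid auto-detection thresholds the luminance with Otsu's method, labels
dark connected components (the wax barrier rings), takes each component's
centroid as the zone centre and the minimum centroid-to-ring distance as
the interior radius, then shrinks radii by `margin_frac` to stay clear of
barrier ink. It assumes non-overlapping rings on a light background and
reports a detection error whenever the component count disagrees with the
requested grid.

## Signal transforms

Method numbering (1–19) is frozen so reports are comparable across
assays; the table is in the README. Conventions:

* **Δ sign**: Δc = blank − reacted zone, so darkening reactions give
  positive differences.
* **Log base**: 10, by analogy with attenuance −log(I/I₀); configurable
  (`log_base`), since only the slope scale — not usability, R² or the
  Δsignal ratio — depends on it.
* **γ** in the log-product method defaults to 1 (a correction factor
  that may be used, not required).
* **Guards**: ratio methods raise on a zero denominator channel and log
  methods on non-positive intensities, because silent clamping biases
  calibrations; an explicit `clamp=True` replaces offending values by 1.
  In the batch table these failures become NaN with a logged reason, so
  one bad zone never aborts a study.
* The multi-zone Euclidean distance (squared deltas summed across several
  zone/blank pairs before the root) is exposed separately
  (`multi_zone_ed`); the single-pair form is method 18.
* HSV conversion is the standard hexcone transform (hue in degrees,
  saturation/value in percent, hue ≡ 0 on the grey axis), provided for
  completeness; the comparison study itself stays in RGB.

Algebraic structure used as test invariants: method 4 is the mean of
1–3; method 11 is the sum of 8–10; method 19 with γ = 1 equals the sum
of 5–7; method 18² equals the sum of squares of 8–10.

## Calibration and figures of merit

Unweighted OLS on replicate-level points (not replicate means) — the
replicate scatter is exactly what the confidence limits must reflect. At
least 3 points with non-identical concentrations are required. The fit
itself is delegated to statsmodels OLS; tests verify it against the
closed-form normal equations independently.

* **Sensitivity error** = 100·SE(slope)/|slope| (%).
* **Usability**: two-sided t-test of slope = 0 at α = 0.05. An unusable
  method stays in every report (rendered as dash cells) but is excluded
  from ranking and has no defined LOD.
* **LOD** = k·σ/|slope| with k = 3.3 by default (k = 3 available).
  σ is the SD of the blank *signals* when at least 3 blank replicates
  exist, otherwise the residual SD s_yx; the source is recorded in the
  result. The formula choice is a documented convention of this package:
  detection limits are only comparable under an explicitly stated rule.
* **Confidence limit of Y**: the mean-response CI,
  t(0.975, n−2)·s_yx·√(1/n + (x₀−x̄)²/Sxx). A prediction interval would
  add 1 under the root and describe a single future zone; the Δsignal
  ratio compares *calibrated* signal levels, for which the mean response
  is the natural uncertainty. The choice is stamped in report headers.

## Δsignal ratio and ranking

ratio = |ŷ(c_high) − ŷ(c_low)| / ((u_low + u_high)/2) with u = 95 % CI
half-widths. It is invariant under affine rescaling of a method's signal
(both numerator and half-widths scale by |a|), so methods with wildly
different signal scales are directly comparable. Ratios are displayed at
2 decimal places; computations keep full precision. If both half-widths
are zero the ratio is reported as +inf with a warning.

The concentration pair is user-supplied — which concentrations must be
distinguished is an assay property, not something the data decide. The
default ranking (ratio descending, ties by lower LOD then lower
sensitivity error, stable order) is a labelled convenience: no single
rule fits all assays, and a weighted-score policy is available. A pair
outside the calibrated range attaches an extrapolation note to every row
rather than failing.

## Synthetic data

The generator emulates the measurement chain, not the chemistry:
per-channel means follow clip(blank_c + slope_c·conc + N(0, replicate_sd),
0, 255); rendered scans add N(0, pixel_sd) per interior pixel, a dark
barrier ring of given width, and a light background. Defaults are the
bromothymol-blue-like conditions: blank (230.0, 226.1, 226.9), channel
sensitivities (−0.594, −0.386, −0.212) per mg/L, six levels 0–100 mg/L,
three replicate zones per level, replicate_sd 1.5 and pixel_sd 2.0
intensity units (chosen to give confidence half-widths of the order seen
in practice for n = 18 calibrations). A Zn-like variant with a single
responding channel, (0, −78.65, 0) per mmol/L over 0–0.4 mmol/L,
reproduces the selectivity situation where single-colour red/blue
calibrations are pointless. Geometry: 30 px interior radius, 3 px border,
a scaled stand-in for 10 mm circles with 1 mm barriers (dpi is cosmetic
in simulation). If more than 20 % of zone means hit the 8-bit clip
bounds a saturation warning is raised instead of silently truncating.

What the generator does **not** model: scanner optics and colour
restoration, JPEG quantisation, paper texture, chromatographic spreading,
heteroscedastic or nonlinear responses. Passing tests therefore
demonstrate correctness of the computational pipeline under an idealised
linear-Gaussian response — they do not validate any particular chemistry.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); there is no hidden global state.

## Problem sizes and statistical test design

The simulation-based checks use 18-zone calibrations (6 levels × 3
replicates), 100 rendered scans for slope-CI coverage (300 channel fits,
asserted ≥ 90 % at a nominal 95 %), 200 fits for the LOD recovery check
(±15 % of 3.3σ/|b|), and 500 fits for slope-CI coverage at the unit
level. The single-responding-channel selectivity pattern is asserted as a
frequency over 50 seeded datasets (flat channels non-significant ≥ 80 %
of runs, the responding channel significant ≥ 95 %): with a 5 % test
size, a truly flat channel is *expected* to look significant in ~5 % of
datasets, so a frequency assertion is the statistically honest form of
the qualitative claim.

## Known limitations

* No weighted or nonlinear (e.g. 4PL) calibration and no outlier
  rejection; assays far from linearity need preprocessing elsewhere.
* Grid detection expects clean, non-touching rings; damaged barriers or
  skewed scans require an explicit layout CSV.
* The LOD depends on an explicit formula convention; values are not
  comparable to limits derived under other definitions.
* Replicate-level OLS assumes independent, homoscedastic errors across
  zones; strong zone-to-zone correlation (e.g. shared pipetting bias per
  level) would narrow the reported confidence limits artificially.
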