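# Methods

## Signal model

Each locus series is modelled as trend + periodicity + correlated noise:

```
y(t) = S(t) + Σ_{k=1,2} [a_k cos(2πkt/T) + b_k sin(2πkt/T)] + ε(t),
ε_t = φ ε_{t-1} + η_t
```

* `T` — cardiac period, taken from the pulse-oximeter beep intervals
  (mean of successive differences). It is a design constant of the fit,
  never re-estimated from the pixel signal: the acquisition is
  cardiac-gated by construction.
* `S(t)` — linear spline with interior knots at each cycle boundary
  (two knots for a three-cycle record). This absorbs slow drifts in
  illumination and accommodation without touching the cardiac bands.
* Two harmonics only: retinal pulse waveforms are well described by a
  fundamental plus one overtone at these frame rates; higher harmonics
  are indistinguishable from noise at ~25 samples per cycle.
* AR(1) errors: consecutive video frames share slowly varying optical
  and physiological noise; a first-order autoregression is the smallest
  model that captures it.

Estimation is iterated Cochrane–Orcutt: ordinary least squares, lag-1
autocorrelation of the residuals as the new `φ` (clamped to ±0.99),
Prais–Winsten whitening (first observation scaled by √(1−φ²), later ones
quasi-differenced), refit, repeat to |Δφ| < 1e-6 or 50 iterations. With
the Prais–Winsten row the whitened OLS solution is algebraically the
exact GLS estimator for the current `φ`, which makes the procedure
directly testable against a dense-covariance oracle (it agrees to
machine precision). A numerically perfect fit (zero residual variance,
e.g. noiseless synthetic input) short-circuits `φ` to 0 rather than
dividing 0/0.

## Amplitude definition

The pulse amplitude is the **peak-to-trough range of the fitted
two-harmonic waveform** over one period, evaluated on a 4096-point grid
and polished by bounded scalar optimisation at both extremes (two-
harmonic ranges have no closed form). An alternative definition,
`2·√(a1² + b1²)` (first harmonic only), is available via
`amplitude_method="first_harmonic"`; peak-to-trough is the default
because it is what a heat map of "pulsation strength" should show when
the waveform is non-sinusoidal. Amplitudes are natural-log transformed
("log u"); values at or below a floor of 1e-3 arbitrary units (constant
series) are clamped and flagged rather than mapped to −∞. The log base
is configurable in the sense that any rescaling is linear; all shipped
numbers use natural log.

The optional 5-arbitrary-unit detection threshold (a sensitivity optimum
for visible pulsation) is exposed as a filter argument but off by
default: the group summaries here are amplitude averages, not detection
calls.

## Geometry

Pixel coordinates are (row, col), 0-based, origin top-left. The optic
disc centre is the polar origin; distance is in mm (pixels × µm/px /
1000, default 6 µm/px so a 5 × 5 cluster is 30 µm), angle counter-
clockwise from the horizontal axis in (−180°, 180°]. "Superior" means
smaller row indices (image top); this is the standard fundus-photo
orientation and is what the hemivessel split of HVO eyes relies on.
Analysis keeps loci with 0.25 mm ≤ d ≤ 1.0 mm — the inner zone is
excluded because pulsation is still in its rising phase near the vessel
origin — and the bounds are treated as closed, a convention this package
fixes explicitly. A locus is valid when ≥ 60% of its 25 pixels carry the
target vessel label; loci exactly on the horizontal axis inherit the
hemifield of their vessel's circular-mean angle.

A vessel's slope needs at least 5 annulus loci spanning ≥ 0.2 mm of
radial distance; below that the slope is reported missing rather than
estimated from a degenerate design.

## Synthetic data: what it emulates

The generator produces, per eye: a labelled segmentation (artery, vein,
disc, cup, background; one artery and one vein per hemifield by default,
drawn as wiggling radial paths 7 px wide from the cup margin to beyond
1 mm), a log-linear truth amplitude field, and rendered video per force
level. Rendering composes a label-dependent baseline, a global
sinusoidal drift (one cycle per record, default magnitude 3 intensity
units), the cardiac waveform scaled to each pixel's truth amplitude
(pulsation *darkens* the green channel; the analysis is polarity-free),
and stationary AR(1) pixel noise (marginal SD 2, φ = 0.4). The
second-harmonic energy fraction defaults to 0.2; frame rate 25 fps and
cardiac period 1.0 s give 25 samples/cycle and 75-frame records. These
acquisition constants are declared package defaults, not values inferred
from any particular camera.

Group presets carry the six study groups' venous/arterial mean log
amplitudes and amplitude slopes with between-eye SDs; per-eye effects
are drawn per vessel class (mean offset and slope offset), and the truth
field's intercept is calibrated so the annulus-pixel mean equals the
drawn target exactly. An HVO eye carries the affected preset on its
superior hemifield and the unaffected (N2) preset on the inferior one —
one physical eye, two hemifield presets; the affected side is fixed
superior by convention. Arterial slope centres for the two fellow-eye
groups and the HVO hemifields are package choices interpolated
monotonically between the normal and CRVO centres, as no measured values
exist for them; they are not used as recovery targets. Covariates: ages
Gaussian per group, sex Bernoulli(0.5), glaucoma prevalence per group.

What the generator does **not** emulate: eye movement and blink
artefacts, photoreceptor/choroidal background texture, vessel calibre
changes, optical blur, non-green channels, and any dependence of the
truth amplitude on induced IOP (force levels re-render noise, not
physiology). Passing recovery tests therefore demonstrates that the
estimator chain is unbiased under the model's own assumptions — not that
it is robust to real-video artefacts, which is what the alignment cap,
validity masks and label-fraction rules are for.

A second, summary-level generator (`sample_observation_table`) draws
vessel × force observations directly from the preset distributions,
skipping rendering. It exists for statistical calibration of the mixed-
model layer (type-I error over hundreds of replicates, coverage checks),
where the imaging chain would add hours of runtime and no information
about the statistics under test.

## Mixed model

`fit_lmm` regresses an observation-level summary (mean/max log
amplitude or slope) on study group (treatment-coded), age, sex, induced
IOP and POAG, with a participant random intercept plus an
eye-within-participant component; the eye intercept absorbs laterality
and the repeated force levels. Covariates that are constant in the
analysed subset are dropped automatically (a normals-only table has no
POAG variation). The eye-within-participant component is attempted only
when some participant contributes two eyes — otherwise it is
unidentifiable — and a singular or non-converging fit falls back to an
eye-only intercept, then to OLS, with a logged warning. P-values are
Wald z; with the small per-group eye counts typical here they are
mildly anticonservative, which the null-calibration test bounds
empirically. Distance from the disc centre is deliberately *not* a
fixed effect at this level: the slope response already integrates it,
and the mean/max responses average over the annulus, so including it
again would double-count the radial structure.

## Problem sizes and tolerances

Recovery runs use 20 eyes per group, 3 force levels, 384 px frames at
6 µm/px, 75 frames per record — about one minute per 20-eye cohort per
force level on one CPU. Recovery is judged against 2 **parametric**
simulation standard errors (known generator dispersion / √n); with 20
eyes the generator's own between-eye draw, not estimator error,
dominates the distance from the preset centres. The noiseless
end-to-end check (truth recovered to 1e-3 log u) switches drift off as
well as noise, because a smooth sinusoidal drift is not exactly
representable by the cycle-knot linear spline and leaks ~1e-2 log u into
amplitudes — visible as a small, documented positive bias under default
(noisy) conditions, largest at low amplitude where the fitted-waveform
range inflates under coefficient noise.

## Known limitations

* Alignment is integer-pixel rigid translation with a 20 px cap;
  sub-pixel or deformable registration is out of scope, preserving raw
  densitometry values.
* Beep timing is consumed as a CSV of seconds; decoding the oximeter
  audio track is out of scope.
* Heart rate is assumed constant within a record (single `T`).
* Phase information is discarded; only amplitudes are analysed.
* The per-eye truth is IOP-independent, so the induced-IOP fixed effect
  in synthetic fits estimates a true zero.
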