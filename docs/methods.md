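# Methods

## The stiffness surrogate

Transmission UST measures two co-registered scalar fields per coronal
slice: longitudinal sound speed `c` (m/s) and pulse attenuation `a`
(relative units).  Bulk-modulus reasoning says a hard lesion is dense
(high `c`) while a non-solid lesion barely attenuates; the fused stiffness
map must therefore be high only where *both* channels are high and must
vanish wherever attenuation vanishes.  We first rescale each channel per
breast,

    x̂ = clip((x − P_lo) / (P_hi − P_lo), 0, 1),

with `P_lo`, `P_hi` the 1st and 99th percentiles of the within-mask voxel
values (the published analysis is explicitly relative, scaled to the range
of stiffness found in that breast), and then combine

    S = sqrt(ĉ · â).

The geometric mean reproduces every qualitative contract stated for the
production fusion — `S = 0` when `â = 0` regardless of `ĉ` (cysts stay
soft), `S = 1` only where the tissue is both dense and attenuating, and
monotonicity in each channel — without claiming to reproduce its exact
(unpublished) form.  A `weighted_mean` rule is retained as a configuration
alternative for sensitivity analysis.  Percentiles are estimated on the
mask eroded by 2 in-plane voxels so a high-attenuation skin rim cannot
dominate the scale; the rim itself is still mapped (and clipped).  A
constant channel degrades to all-zeros with a warning rather than an
error.

Two consequences of this design are worth knowing.  Near `â = 0` the
square root amplifies noise (`E[sqrt(|ε|)] ≈ sqrt(σ)`), so cyst interiors
have a small positive stiffness floor on noisy data.  And any voxel whose
raw value exceeds the 99th percentile clips to 1, so the stiffest object
in a breast saturates; mass metrics are therefore computed on contours
traced at the apparent margin (see below) rather than on idealized
interiors only.

## Tissue classification

Within-mask voxel intensities (intensity only, no spatial features) are
clustered by 1-D K-means — Lloyd's algorithm, k-means++ initialization,
`n_init=10`, `tol=1e-6`, fixed seed — with cluster indices relabeled by
ascending centroid: sound speed with k=2 (fat low, fibroglandular high)
and stiffness with k=3 (soft / intermediate / hard, the handheld-US
elasticity descriptors).  Clustering is fitted per breast, matching the
per-breast stiffness scaling and keeping breasts independent experimental
units.  The six whole-breast components are the voxelwise intersection of
the two partitions; their voxel counts sum to the breast-mask volume by
construction, asserted on every run.  No morphological cleanup is applied:
boundary partial-volume voxels are misassigned exactly the way plain
intensity K-means misassigns them, a known behavior we reproduce rather
than fix (a 1-voxel boundary-erosion flag exists but is off by default).
A stack with fewer distinct values than classes falls back to the lowest
class with a warning.

Component volumes are voxel counts × voxel volume (1.40625 mm³ at the
default spacing).  Cohort tables average per-breast volumes and recompute
percentages from mean volumes — not mean percentages — because that is the
arithmetic that makes the published cohort table internally consistent
(82/737 = 11.1% against a printed 11.2%, a pre-rounding difference we
report rather than hide).

## High-pass spatial filtering

Masses are emphasized by suppressing spatial scales above 1.5 cm:
per-coronal-slice Gaussian subtraction `F = S − G_σ(S)` with
FWHM = cutoff = 15 mm (σ = 6.37 mm), chosen over a sharp Fourier cutoff to
avoid ringing (a Butterworth option is config-exposed).  Filtering is 2-D
per slice because review is slice-based and out-of-plane spacing (2.5 mm)
is coarse.  The filtered map is robustly re-stretched per breast to [0, 1]
(same percentile rule) so the three-class split and mass indices stay on
the unit scale; clipping negatives instead of re-stretching is available
as a flag since the production choice is unpublished.  The analytic
transfer of the subtraction filter on a sinusoid of wavelength λ is
`1 − exp(−2π²σ²/λ²)`, verified in tests against direct convolution.

## Mass metrics

Metrics are single-slice by design, mirroring the hand-traced single most
representative coronal contour of the clinical analysis, and are computed
strictly inside the polygon (peritumoral tissue excluded): pixels whose
centers fall inside the contour (even-odd rule; simple polygons enforced
via shapely).  The stiffness index is the mean pixel value (0–1); class
and six-component percentages come from intersecting the ROI with the
whole-breast masks; size class uses the equivalent circular diameter
`d = 2·sqrt(area/π)` with ties at exactly 1.5 cm counted small (the
source protocol writes both "≤1.5 cm" and "<1.5 cm"; we follow the ≤
form).  GLCM homogeneity uses 8 uniform bins on [0, 1], the four symmetric
unit offsets, co-occurrence restricted to pixel pairs both inside the ROI
(hand-rolled for that reason; cross-checked against scikit-image on
rectangular ROIs), averaged over offsets with at least one pair.

Simulated cohorts trace circular contours at 1.15× the true sphere
diameter — the apparent margin of a band-limited reconstruction — because
that is what hand tracing on the displayed image does, and because the
margin gradient carries most of the texture signal once the clipped core
saturates.

## Statistics

Welch's unequal-variance t-test (the published tables show clearly unequal
group spreads), Pearson chi-squared without continuity correction for
frequency contrasts, and 5th–95th percentile intervals of the per-mass
indices (the published "5–95% C.I." ranges are far too wide to be
confidence intervals of means; we interpret them as percentile ranges of
the per-mass values).  Raw p-values are always reported; 0.05 sets only a
significance flag; no multiple-testing correction, matching the published
reporting.

## The phantom generator

The generator emulates what the analysis needs from a reconstructed scan,
not acoustic propagation.  A cylindrical pendant-breast mask is filled
with a two-tissue mixture: a Gaussian-smoothed random field (correlation
length `fg_texture_scale`, default 20 mm — parenchymal groupings are
centimeter-scale, larger than the 1.5 cm mass-emphasis cutoff; that
relation is a premise of the filtering step) is thresholded at the
within-mask quantile realizing the requested fibroglandular fraction
exactly (default 0.291, the cohort-mean density mix).  Acoustic values
vary smoothly with tissue-field depth — fat 1412–1438 m/s and attenuation
0.10–0.30, fibroglandular 1490–1570 m/s and 0.30–0.80, continuous across
the fat/FG boundary — so both compartments contain soft, intermediate and
hard subregions (the cohort table shows ~31% of fibroglandular tissue hard
and most fat soft; a class-constant generator cannot produce that
structure) and neither channel saturates breast-wide.  Absolute values are
invented but only their ordering matters to the (relative) analysis; all
are configurable.

Masses are spheres in mm (center-of-voxel rasterization) overwriting the
tissue beneath, rejected if they leave the mask or overlap an existing
mass.  Type profiles: cyst 1520 m/s / att 0.02; fibroadenoma 1510 / 0.45,
nearly homogeneous; cancer 1570 / 0.60 with full-scale smoothed speckle
(3 mm correlation) and a centrally dominant radial attenuation gradient
(+50% core, −50% margin) — cancers image as stiff-centered, texturally
disordered masses whose attenuation sits at the top decile of, not above,
the parenchymal range, since published cancer indices spread well inside
(0, 1); fibrosis is a milder cancer-like profile.  After mass insertion
the noiseless maps receive an in-plane acquisition blur (sound speed
1.5 mm FWHM ≈ the λ/2 resolution; attenuation 4 mm, transmission
attenuation being reconstructed at coarser effective resolution), then
i.i.d. Gaussian noise inside the mask (5 m/s; 0.05 relative units,
clipped at zero attenuation).  An optional 2-voxel high-attenuation skin
rim emulates the skin's artifactual stiffness.  Outside-mask voxels are
exactly water (1500 m/s, zero attenuation).  Everything is deterministic
given the seed.

What the phantom does **not** emulate: refraction/diffraction artifacts,
reflection imaging, anisotropic real parenchymal architecture, irregular
or spiculated mass margins, and breast-shape taper.  Passing tests
therefore demonstrate that the pipeline's logic and statistics behave as
specified under the stated contrast structure, not that the method
performs clinically.

## Simulation experiments

*Filter directionality.*  The published mechanism — adjacent large stiff
parenchyma partially obscures a small cancer on the unfiltered map, and
filtering raises the mass's hard-component percentage — is reproduced with
a 10 mm cancer at the edge of a 26 mm very stiff parenchymal grouping
(attenuation 1.1) that anchors the per-breast scale and the hard cluster.
A concentric embedding cannot show the effect under Gaussian subtraction:
the mass's local baseline is then the parenchyma itself, so the filter
removes both together.  The assembly is placed at the most fat-dominant of
eight candidate sites of the pre-mass tissue field (a representative-site
choice, deterministic per seed), and the hard fraction is measured on the
apparent-margin contour.  The direction (filtered > unfiltered) holds in
essentially every seed, with a mean gain of a few percentage points —
directionally faithful, smaller in magnitude than the published
23-point gain for small cancers.

*Mass-type ordering.*  Twenty simulated small masses per class give mean
stiffness indices ordered cancer > fibroadenoma > cyst on both renderings,
and lower GLCM homogeneity for cancers than fibroadenomas on the
unfiltered (default) rendering.  On filtered maps the renormalization
amplifies background noise into mid-scale masses and the texture contrast
is not expressed; the published homogeneity statement is not tied to a
rendering, and we document ours.

*Null calibration.*  Type-I error of the record-and-compare pipeline is
estimated from 200 replicates, each a phantom with 20 identical
fibroadenomas (fatty background with fine 6 mm texture plus a fixed stiff
anchor region stabilizing the percentile scale) randomly relabeled into
two 10-mass pseudo-groups.  The Welch test on the stiffness indices
rejects at ≈5–6%, inside the 3–8% acceptance band.  With heterogeneous
per-mass surroundings or mass-dominated percentile anchors the index sets
are heavy-tailed and the test becomes conservative — a useful caution for
small clinical subgroups.

## Problem sizes and numerical choices

Tests and the acceptance script use 64–200 voxel grids (full-size
200×200×40 for the density-fraction contract), 10–12 seeds for sign-type
properties, 30 phantoms for density recovery, and 200 null replicates;
together they run in a few minutes on one CPU.  Percentiles use linear
interpolation (NumPy default); K-means ties are resolved by the fixed
seed; degenerate inputs (constant stacks, empty masks, sub-2-pixel
cutoffs, polygons with no area) raise or warn as documented in the API.
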