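# Methods

This note records the models, estimators and numerical choices behind
`actinquant`, and what the synthetic generator does and does not emulate.

## Synthetic image model

All images are rendered additively: object intensity profiles + a constant
background + i.i.d. Gaussian noise of a declared standard deviation,
clipped to the 16-bit range. All randomness in a call flows from a single
integer seed (`numpy.random.default_rng`), so identical specs give
bit-identical images.

**Fibres.** A fibre is a straight centreline segment with a Gaussian
cross-section whose full width at half maximum equals the declared width
(σ = width / 2.355). This makes "width" a physically meaningful, optically
plausible quantity that a detector can recover, and defines the fibre's
ground-truth mask as the half-max support. Orientations use the image
convention adopted throughout: origin top-left, x rightward, y downward,
angles in degrees in [−90, 90) from the x-axis with positive angles
pointing up on screen.

**Adhesions** are elliptical Gaussian spots whose half-max contour is the
declared ellipse (major/minor axes are FWHM extents). **Nuclei** are round
Gaussian blobs with a disc ground-truth mask; multinucleate fixtures place
disjoint discs. **NMIIA puncta** are Gaussian spots placed at the declared
period along a fibre's axis. **PLA foci** are isotropic Gaussian spots
placed by rejection sampling under a minimum-separation constraint
(required > 4σ so each focus is a resolvable connected component).

**Crossbow pattern.** Micropattern vendors do not publish their geometry,
so the generator's crossbow — a circular arc spanning 210° (the curved
leading edge) plus a straight stem from the centre of curvature to the
trailing edge, with radius 0.38 × image size — is the package's reference
geometry; it is a stand-in, and all edge-distance measurements are defined
against it. A faint outline of the pattern is rendered into the actin
channel (cells on micropatterns spread along the printed shape), which
also anchors template centring.

**Wounds.** A time-lapse frame is a vertical cell-free band in a textured
cell sheet: cell pixels carry Gaussian texture (default sd 12 on a mean of
120), wound pixels are near-background. The true band width at frame k is
max(0, W₀ − 2·v·k·dt) for per-front velocity v — the two-front linear
closure law — and clamps at zero. Defaults (512 px frames at 2 µm/px,
W₀ = 500 µm, hourly frames) mirror a culture-insert assay producing a
~500 µm uniform wound monitored by time-lapse.

**What is not emulated:** PSF/optics beyond the Gaussian cross-section,
3-D structure, photobleaching, uneven illumination, cell-to-cell intensity
variation, curved fibres, and touching/overlapping adhesions. Passing
tests therefore demonstrate correctness of the measurement chain, not
robustness to every real-microscopy artefact.

## Micropattern reference-cell pipeline

Preprocessing is Gaussian blur (σ configurable, 0 = no-op) with an
optional median pre-filter, then an automatic histogram threshold. Three
named criteria are provided: Huang's fuzzy-membership minimisation,
Kapur's maximum-entropy criterion, and the image median. Huang and Kapur
are implemented from their histogram definitions (256 fixed bins) because
scikit-image ships neither; "dark" means a dark background with bright
objects. A constant image has no defined threshold and yields an empty
mask with a warning.

Nucleus QC counts connected DAPI components above a minimum area
(default 40 px²): zero → off-pattern, two or more → multinucleate
(excluded), one → passed unless flagged mitotic. The mitotic flag —
condensed chromatin — is a single nucleus with area below 0.5× a
cohort-median reference area and solidity > 0.95; the criterion is
declared and configurable, and skipped when no reference area is known.

Centring maximises cross-correlation (via the phase-correlation peak)
between a channel (default: sum of channels) and the pattern template,
applies the integer-pixel translation to all channels, and records the
offset; centring twice moves at most 1 px more. Stack registration is
translation-only to the first image — rotation is not needed for centred
micropattern cells. Frequency maps are the pixel-wise mean (configurable
to max) over QC-passed centred cells, min–max rescaled to 0–255 integers;
the whole chain is deterministic.

## Filament morphometrics

Detection: binarise (Gaussian smooth + threshold; the default "half_max"
threshold sits halfway between the image median and maximum, appropriate
when structures share a peak brightness — Otsu, Huang or a fixed value are
alternatives), skeletonise, mark junction pixels (≥ 3 skeleton neighbours,
8-connectivity), remove them so crossing fibres split into separate
branches, and trace every branch at least `min_length` (default 10 px)
into a record.

*Length* is the geodesic length of the traced path with two corrections:
the path coordinates are smoothed with a 5-point moving average before
summing steps, because raw pixel-step sums overestimate oblique digital
lines by up to ~8% (staircase effect); and 1 px is added since N pixel
centres span N−1 steps. On 80 random fibres (20–200 px, all orientations)
the median absolute length error is ~0.8%.

*Width* is, by default, the median full width at half maximum of
perpendicular intensity profiles sampled (sub-pixel, bilinear) along the
trace, with the blur kernel's FWHM removed in quadrature when the image
was smoothed first. A distance-transform estimator (2 × mean EDT along the
trace) is kept as `width_method="edt"`, but on a pixel grid it quantises
to odd integer widths — a 2 px fibre reads 1 or 3 px — which is why the
FWHM estimator is the default: it recovers 2–8 px widths with ~1–2%
median error instead of up to 50% at the thin end.

*Orientation* is the principal axis of the traced coordinates (eigenvector
of the 2×2 scatter matrix), folded into [−90, 90).

Edge distance is the exact point-to-arc distance from a filament centre to
the crossbow's curved edge (closed form: radial distance within the arc's
angular span, else distance to the nearer arc endpoint). The thick-object
filter is strict (width > threshold, default 2 px). Skeleton statistics
count junctions as 8-connected clusters of junction pixels and branches as
the connected segments left after removing them, so a symmetric "X" gives
4 branches and 1 junction and a straight line 1 branch and 0 junctions.

Orientation distributions come from the smoothed structure tensor
(σ default 2 px): per-pixel orientation from the dominant eigenvector,
weighted by tensor energy (trace), accumulated over [−90, 90). The
circular mean and coherence are computed on doubled angles, as
orientations are axial; isotropic noise gives coherence ≈ 0.

## Adhesions and foci

Adhesions: threshold (default half-max, so the outline of a Gaussian-like
plaque is its FWHM contour and the fitted axes are FWHM extents — Otsu
optional), 8-connected labelling, components ≥ `min_area` (default 4 px²)
ellipse-fitted via second moments; length = major axis, width = minor
axis.

Foci: median filter (3 px) → Gaussian blur (σ = 2) → Kapur maximum-entropy
threshold → 8-connected particle count gated to [15, 10 000] px². The
lower gate reflects the blur: after σ = 2 smoothing any resolvable focus
covers ≳ 40 px above half-max, while correlated noise excursions at the
threshold form 4–16 px blobs, so 15 px² separates the two cleanly.
Counting is restricted to a supplied cell mask when available; otherwise
the whole image stands in for the cell (per-cell assignment is otherwise
undefined). The count is invariant to global intensity scaling because
the histogram bins are computed over the image's own range.

## Line profiles and peak frequency

Profiles are sampled by bilinear interpolation at unit steps along the
segment (round(length) + 1 samples); the reference protocol uses 150 px
scans. Peaks are prominence-filtered local maxima with default prominence
10% of the profile's dynamic range — plain local maxima count noise
ripple; the criterion used in the original R-based analyses is not
published, so this default is declared here. Peak frequency is
n_peaks / length × 100; spacing is the mean difference of peak positions.

## Wound healing

In bright-field/texture mode, the per-pixel local variance (uniform
window, default 15 px) is thresholded at the geometric mean of its 5th and
95th percentiles — the variance image is three-level (near-zero wound,
texture-level cell sheet, and a very high mean-contrast ridge along the
boundary), and this split ignores the ridge. Frames whose 95th/5th
variance ratio falls below 5 are reported closed (a confluent sheet has no
low-variance band). The variance window erodes the band by half a window
per side, so the retained largest component is dilated back by the same
amount before measuring. Fluorescence mode thresholds low SiR-actin
intensity (Otsu) instead. Width is measured per row (mean and sd of row
chords — for a straight vertical band this equals area / band height);
area is the pixel count × pixel size².

Closure % and migration rate follow the two formulas exactly; closure may
be negative if a wound grows, and if the wound closes before the series
ends, W_f = 0 is taken at the first closed frame with t running to that
frame, so the rate reflects time-to-closure. Whether t counts from
wounding or from imaging start is an assay-reporting ambiguity; the
segmentation API takes a `t0` offset so either convention can be used.
On noiseless synthetic series the measured widths track truth within
~0.7% and the measured rate equals 2v to three digits.

## Statistics

Observations are averaged within biological replicate before ranking
(raw-observation mode via a flag); the Kruskal–Wallis H uses pooled
mid-ranks with the tie correction 1 − Σ(t³−t)/(N³−N) and a χ²(k−1)
reference. Dunn's pairwise z uses mean-rank differences over the
tie-corrected pooled variance N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided,
with Holm step-down adjustment (statsmodels). All values identical yields
H = 0, p = 1 by convention. The empirical size of the test under the null
(3 groups × n = 20, 2 000 seeded simulations) is 0.04–0.06 at α = 0.05.

## Problem sizes

Detector scoring runs at the scale the estimators are specified for:
100 single-fibre images (256²), 10-seed foci fields (256²–420²), 12-cell
cohorts per phenotype (256²), 12–25-frame wound series (512²), and 2 000
null simulations for the test-size check; each stage completes in seconds
on one core.

## Known limitations

- Crossing fibres are split at junctions by design, so per-cell filament
  counts on crowded cells are counts of *branches*, not of generative
  fibres; exact count recovery holds for non-overlapping structures.
- The half-max binarisation assumes structures of comparable brightness;
  images with strongly varying fibre intensity need Huang/Otsu or a fixed
  threshold.
- The wound segmenter assumes a single dominant, roughly vertical band;
  ragged multi-region wounds are measured as their largest component.
- The crossbow geometry is the package's own reference, not a vendor's.
- Trend curves for wound kinetics (e.g. GAM smoothers) are deliberately
  out of scope; the kinetic read-outs are the two closed-form metrics.
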