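# Methods

## Coordinate conventions

A polar frame is a raster `[a_line, depth]`. A-line 0 points at 0°, angles
increase counter-clockwise with uniform spacing 360°/`n_alines`; depth
pixel *k* spans `[k, k+1) · axial_pitch` from the catheter center, so its
center radius is `(k + 0.5) · axial_pitch`. Angles are degrees in
[0, 360), lengths are millimetres, intensities are normalized to [0, 1].
Frame *i* of a pullback sits at `i · frame_spacing` mm.

Acquisition defaults emulate a contemporary frequency-domain intravascular
OCT console: 100 frames/s at 20 mm/s pullback → 0.2 mm frame spacing over
a 54 mm pullback, with ~20 µm axial resolution sampled at a 5 µm axial
pixel pitch. The per-frame A-line count (504) and the exact pixel pitch
are package conventions, not published console constants; both are
configurable in `AcquisitionMeta`.

## Phantom

The generator renders, per frame:

* a dark catheter core with a bright sheath ring just inside
  `catheter_radius` (default 0.4 mm);
* a lumen boundary `r(θ, z)`: an offset circle (center offset < radius)
  with linear taper along the pullback and a second-harmonic ovality term
  — the realistic envelope of eccentric, mildly elliptic coronary cross
  sections. Entry into the wall is a bright edge band (intensity 0.9 over
  20 µm) followed by tissue at 0.7 decaying with a 0.3 mm attenuation
  length, under multiplicative gamma speckle (shape 4);
* optional stent struts: bright Gaussian blobs (σ ≈ 1.2 A-lines × 2 depth
  px) seated `standoff` (30 µm) inside the wall, each multiplying all
  deeper pixels of its A-lines by 0.1 — the bright-reflection-with-dark-
  tail signature the detector targets. Struts whose angle falls inside the
  guidewire sector are physically occluded: they are neither rendered nor
  listed in ground truth;
* an optional guidewire: a superficial bright reflection with everything
  deeper multiplied by 0.05 over a configurable sector (default 30°);
* residual blood as **independent Bernoulli bright pixels** (value 0.85)
  at the requested density inside the effective lumen. The bookkeeping
  region excludes the guidewire sector and strut A-lines (±2), so the
  recorded bright-pixel count is an exact above-threshold census of the
  rendered frame — every downstream pixel statistic has a combinatorial
  oracle. Real residual blood forms correlated swirls; independence is a
  deliberate simplification that makes the oracle exact, and it means the
  phantom does not probe texture-level failure modes of the detector.
* two side-branch analogs: localized +30% radius bulges at configurable
  landmark frames, recorded as landmarks for matching.

Paired generation renders the same vessel twice. Member B's radial
structure is scaled by `index_b / index_a`: under a medium of lower
refractive index the optical path shortens, so a console calibrated for
medium A renders the anatomy smaller. The catheter radius is not scaled
(the console knows its own sheath). Both members share the noise seed, so
equal indices, densities and offset give bit-identical stacks; a frame
offset shifts member B longitudinally to exercise landmark matching.

## Segmentation

**Lumen contour.** Per A-line, the axial Gaussian-derivative gradient
(σ = 3 px) is scanned beyond the catheter; threshold crossings
(gradient > 0.04) are snapped to the local gradient peak and accepted if
(a) the forward mean over 40 px reaches 0.2 (sustained tissue) and
(b) the 6 px immediately following the peak have mean ≥ 0.3 **and**
median ≥ 0.25. The median condition is what rejects isolated or paired
blood specks, which are bright but sparse; the wall fills the window.
A-lines without an accepted boundary (guidewire shadow, strut shadow) are
filled from a least-squares Fourier fit (orders 0–4) of the found radii —
the right interpolant for a smooth periodic contour and insensitive to
noise at shadow-gap edges — then a circular-median filter (window 7)
replaces outliers deviating > 0.3 mm. Confidence is the gradient at the
boundary normalized to the frame maximum; filled/replaced A-lines are
flagged and get confidence 0.

**Guidewire.** The contiguous circular run (≥ 10°) of A-lines whose deep
band (0.05–0.25 mm beyond the contour) is near-dark (< 0.08) while a
bright superficial reflection (> 0.5) is present. An all-dark frame is
degenerate and raises.

**Struts.** Local axial maxima above 0.6 within [−0.15, +0.05] mm of the
contour whose tail window (0.05–0.20 mm deeper) averages below 0.12. The
narrow inward band matters: a blood speck further than ~0.15 mm from the
wall has only dark lumen behind it and would pass the tail test. A
pluggable classifier then scores candidates on (peak intensity, tail
contrast, distance-to-contour, axial width); the default is a logistic
regression trained once per process on phantom-labeled candidates from
the tight detector (fixed seed), with a rule-based soft-threshold
fallback. Non-maximum suppression keeps one detection per 4° window.
This learned stage is a stand-in with a pluggable interface, not a
reproduction of any particular production model.

**Stent contour.** A periodic cubic smoothing spline (`splrep`, `per=1`)
through the abluminal strut radii (peak depth + half strut thickness,
default 0), evaluated at every A-line; smoothing 0 interpolates to
numerical precision. Duplicate angles collapse to their mean first;
fewer than 3 distinct angles raises.

**Scan conversion.** Polar frames resample onto a square Cartesian grid
(default 10 µm pixels) by nearest-neighbor lookup. Nearest (not bilinear)
is the default because bilinear interpolation spreads isolated bright
pixels across neighbors and biases pixel-count fractions (~0.002 on the
flushing statistic at density 0.05); nearest preserves per-pixel
statistics. The Cartesian masks classify each pixel by the *same*
quantized polar pixel it samples, so mask counts and image counts agree
down to boundary pixels. Bilinear remains available for display.

## Quality

The flushing capability of a frame is computed on the Cartesian raster
(equal-area pixels make the denominator a true area):
`1 − bright / effective`, bright = normalized intensity > 0.35. The 0.35
default is a package convention — the underlying background threshold of
any given console is device-specific — and is configurable. An r-weighted
polar mode agrees within the resampling error (≪ 1%).

Per-A-line clarity: arterial structure is *visible* if a bright
reflection (wall or strut) sits within 0.15 mm of the contour or the
boundary was confidently detected; the A-line is *clear* if additionally
its in-lumen bright fraction is ≤ 0.20. Strut A-lines therefore count as
clear (the strut visualizes the wall); guidewire A-lines do not (nothing
behind the wire is seen). The visible arc is the longest *circular* run
of clear A-lines; frame clear ⇔ arc > 270° (strict); CIS ⇔ clear
fraction ≥ 50% (inclusive) over a 1-mm segment
(`round(segment_length / frame_spacing)` frames, trailing partial segment
dropped); clear run ⇔ CIS fraction ≥ 90% (inclusive). Whether the
original per-frame judgment was algorithmic or human is unknowable from
outside a core lab; the per-A-line rule here is a stated convention.
The per-pullback flushing summary is the median (IQR) across frames; a
mean mode is available.

## Morphometry

Areas use the polar quadrature `½ Σ rᵢ² Δθ` (agrees with the Cartesian
shoelace to < 0.5% at 300+ A-lines). Segment volumes use the rectangle
rule (area × spacing) so segment volumes tile the pullback exactly;
SLV additivity is exact by construction. MLA/MSA are minima over a
caller-chosen frame range (first index on ties); an all-absent stent
range yields *absent*, never 0.

Refractive correction: the radial coordinate *is* axial optical depth, so
distances scale by `n_reference / n_actual` and areas/volumes by its
square/cube. With pentastarch (1.3433) against a contrast-calibrated
console (1.4421) the factor is ≈ 1.0735 linear, increasing the
measurement — correcting the underestimation a lower-index medium causes.

## Paired statistics

Landmark matching: offset = median of landmark index differences; any
landmark deviating > tolerance (2 frames) is a mismatch. Paired t and
Wilcoxon signed-rank (zero-excluding) are always both reported — no
automatic normality gate; an all-zero difference vector is flagged
degenerate with p = 1. ICC is fixed as ICC(2,1), two-way random effects,
absolute agreement, single measure — the standard choice for method
comparison, matching the Bland–Altman pairing — computed from the ANOVA
mean squares with the F-based confidence interval; the test suite checks
it against an independent from-scratch ANOVA and against `pingouin`.
Bland–Altman: bias ± 1.96 SD of differences. Sample size: smallest *n*
whose exact noncentral-t power (df = n−1, ncp = d√n) meets the target —
the exact computation, not the normal approximation, is what yields
n = 44 at (d = 0.50, α = 0.05, power 0.90) without off-by-one ambiguity
(n = 43 gives 0.893). The CIN classifier implements the strict-inequality
creatinine rule (> 0.5 mg/dL or > 25% within 72 h).

## Numerical and testing choices

Problem sizes in the suite are chosen for desk-scale runs: the flushing
oracle uses 100 frames of a 300 × 320 phantom, segmentation recovery uses
20 single-frame phantoms spanning radii 1–3 mm, and the end-to-end
refractive round trip uses a 25-frame pair; the full suite runs in ~15 s.
On those conditions the contour detector achieves ~1.4 px mean radius
error (≤ 2 px required) and strut recall/precision of 1.00 (≥ 0.95
required).

What passing tests show — and what they do not: the phantom validates the
*logic* of every stage against exact oracles (pixel censuses, analytic
areas, ANOVA mean squares, Monte-Carlo rejection rates). It does not
validate robustness to correlated blood swirls, NURD or sew-up artifacts,
tissue heterogeneity (lipid/calcium), malapposed or bioresorbable struts,
or operator-dependent flushing variability; clinical-grade claims require
clinical data.

## Known limitations

* The strut classifier is phantom-trained; on real pullbacks it should be
  retrained or replaced via the `StrutClassifier` protocol.
* The guidewire detector assumes a single contiguous sector.
* `detect_lumen_contour` assumes one dominant wall entry per A-line;
  dissections or deep side branches beyond the rendered bulges are out of
  scope.
* DICOM ingestion and 3-D rendering are out of scope; interchange is
  multi-page TIFF + JSON sidecar.
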