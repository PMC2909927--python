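# Methods

`irispipe` implements a complete iris-recognition pipeline — segmentation,
occlusion masking, rubber-sheet normalization, log-Gabor phase encoding and
masked Hamming-distance matching — together with a synthetic eye-image
generator that provides exact ground truth for every stage.  This note
records the models, the tunable parameters, the numerical choices, and what
the synthetic benchmarks do and do not demonstrate.

## The synthetic eye model

Real evaluation datasets for this problem (high-magnification slit-lamp
photographs) are rarely redistributable, so the package ships a generator
whose output has the statistical structure such photographs exhibit:

* a dark, near-circular pupil (mean intensity 0.1);
* a textured iris annulus (mean 0.5) whose pattern is the identity;
* a bright sclera (mean 0.9);
* non-concentric pupil and limbal circles (the pupil is rarely centred in
  the iris);
* eyelid arcs, specular highlights, and additive Gaussian noise
  (sd 0.02 by default, clipped to [0, 1]).

The iris texture is defined on the normalized polar grid (default 20 radial
x 240 angular samples) as Gaussian white noise blurred with sigma 1.5 px
(wrap-around in angle) and standardized to mean 0.5, sd 0.12 — band-limited,
identity-bearing, and deterministic in its seed.  An eye image is rendered
by *inverting* the rubber-sheet map: each annulus pixel looks up the texture
at its dimensionless polar coordinate.  Rendering the same texture at two
pupil radii therefore produces images that normalize to (nearly) the same
polar image; the round-trip error is pure resampling error, measured at
~0.01 mean absolute intensity and bounded in the tests at 0.05.

The non-concentric inverse map solves
`x = (1 - rho) * p(theta) + rho * l(theta)` per pixel by a fixed-point
iteration (direction update followed by a least-squares radial update,
30 iterations), which converges quickly because the center offset is small
relative to the radii.

Eyelids are horizontal parabolic arcs clipped to the top/bottom of the
limbal circle; the vertex depth is bisected so the occluded fraction of the
annulus matches the requested coverage (2/3 of the coverage on the upper
lid, 1/3 below).  Specular highlights are filled disks at intensity 1.0.
All occlusions are painted after noise and recorded exactly in the ground
truth.  Eyelid skin is painted at constant intensity 0.78 — smooth, like
real skin relative to iris texture, which is what the eyelid detector
exploits.

What the generator does *not* model: photorealistic iris structure (crypts,
nerve rings are optional extras, off by default), eye color, off-axis gaze,
and — deliberately — any dilation-dependent *deformation* of the iris
pattern.  Rendered dilation series are exactly rubber-sheet-consistent, so
passing the dilation benchmarks shows the pipeline's geometry is
self-consistent; it does not show how a real iris, whose tissue compresses
nonlinearly, would degrade matching.  See "Dilation sweep" below.

## Segmentation

All three methods share one primitive: the circular edge score at center
`c` and integer radius `r` is the forward difference `m(r+1) - m(r)` of the
contour mean (bilinear samples at equally spaced angles; samples outside
the image or in masked angular sectors are excluded), smoothed along the
radius axis with a 1-D Gaussian.  The detected circle is the global argmax
over candidate centers x radii, ties broken by smaller radius then
row-major center order — a deterministic rule that brute-force oracle tests
rely on.

* **Integrodifferential (exhaustive)** — limbal boundary first with every
  pixel as a candidate center (coarse smoothing, sigma 2 px; 256 angles;
  the sectors 45-135 and 225-315 degrees are skipped to avoid eyelids),
  then the pupil inside the detected disk with radii in [0.15, 0.80] of the
  limbal radius (fine smoothing, sigma 1 px; 128 angles).  Candidate
  circles must have their full contour inside the image (`min_coverage =
  1.0`); without this, circles clipped by the image border win on their
  unclipped arc.
* **Edge map + circular Hough** — Canny (sigma 2, hysteresis at 0.2/0.5 of
  the maximum gradient magnitude) followed by a circular Hough accumulator
  in which every edge pixel votes for all centers on the midpoint-rasterized
  circle of each radius (one vote per center; the rasterizer can repeat
  pixels at octant joins).  Limbal first over [0.25, 0.45] of the minimum
  image dimension, then a finer Canny (sigma 1) restricted to the limbal
  disk for the pupil.
* **Blob-seeded, pupil-first** — a 3-class multi-Otsu threshold (lowest
  cut) isolates the darkest intensity class; a plain Otsu cut would land
  between iris and sclera on three-mode images and swallow the whole limbal
  disk.  Morphological opening then closing (disk radius 3 px) removes
  eyelash strands and fills specular holes; the largest connected dark
  component whose centroid lies in the central 60% of the image is the
  pupil blob, giving center `c0` and equivalent radius `r0 = sqrt(area/pi)`.
  The integrodifferential operator then runs in reverse order: pupil first
  on a 10 x 10 grid of candidate centers around `c0` (offsets -5..+4) with
  radii in [0.8, 1.2] `r0`, then the limbal boundary on a second 10 x 10
  window around the found pupil center — at most 200 candidate centers in
  total, versus every pixel for the exhaustive method.

Two refinements make the pupil-first route robust on dilated pupils:

1. the limbal radius range is floored at 1.15 x the detected pupil radius,
   so the pupil/iris edge can never win the limbal search; and
2. the pupil search carries a darkness prior: candidate circles whose
   contour mean two radii inside the edge exceeds the blob threshold are
   disqualified.  The pupil/iris and iris/sclera steps have equal contrast
   (0.4) in the generator's intensity model, so without this prior a
   maximally dilated pupil's search window can reach, and lock onto, the
   limbus.

The coarse smoothing sigma is 2 px rather than a larger value because broad
radial smoothing favours *tangent circles* — circles touching the limbus
from inside at a displaced center spread their edge response over many
radii and, once smoothed, can outscore the sharp true-edge response.  This
failure mode was observed directly on benchmark eyes at sigma 3.

Degenerate searches (no score above `min_edge_score = 0.02`, e.g. a
constant image) raise a stage-tagged segmentation failure.  Results whose
pupil disk leaks more than 1 px outside the limbal disk are clipped, with a
warning recorded.

## Occlusion masking

Specular highlights are pixels at or above 0.97 (well above the sclera mean
of 0.9 plus noise), dilated by 2 px to cover halos.  Eyelash candidates
(pixels at or below 0.05) are masked only inside the iris annulus so the
pupil itself is never flagged.  Lowering the bright threshold can only grow
the mask (monotonicity is tested).

Eyelids are found from texture energy rather than edge magnitude: within
the limbal disk (pupil and a 3 px limbus rim excluded) the mean gradient
magnitude per row drops sharply under a lid, because eyelid skin is smooth
while the iris is strongly textured — on textured irides the lid-boundary
*edge* is indistinguishable in magnitude from texture edges, so a Canny
line fit latches onto texture.  Scanning from the top (bottom) of the disk,
the run of rows whose energy stays below 0.3 x the disk's median row energy
is lid; the horizontal boundary line is the run's last row and everything
above (below) it is masked.  Against generator truth this is exact for
lid-free eyes and conservative by about 0.03-0.06 of the annulus at
coverages 0.1-0.2 (the straight line cannot follow the parabolic wings).

## Normalization

The homogeneous rubber-sheet model maps the annulus to a fixed
`radial_res x angular_res` grid (20 x 240 by default, a common convention
for this code length): for angle `theta = 2*pi*j/angular_res` and
dimensionless radius `rho = (i + 0.5)/radial_res`, the sample point
linearly interpolates between the pupil- and limbal-boundary points at that
angle, each taken on its own (non-concentric) circle.  Angle zero lies on
the positive column axis, increasing counter-clockwise in image
coordinates.  Intensities are bilinear; the validity mask is cleared where
the interpolation neighborhood leaves the image or the nearest pixel is
occluded.

## Encoding

Each polar row is filtered along the angular direction with a single-scale
log-Gabor filter, `G(f) = exp(-(log(f/f0))^2 / (2 log(sigmaOnF)^2))` with
`f0 = 1/wavelength` (wavelength 18 px, sigmaOnF 0.5), applied in the
frequency domain on positive frequencies only — zero DC gain, circular
convolution (the ring is physically closed), complex analytic output.
Amplitude is discarded: each coefficient quantizes to the bit pair
`(Re >= 0, Im >= 0)`; exact zeros count as 1 for determinism.  The code is
`2 x 20 x 240 = 9600` bits.  A coefficient's mask bits are cleared if its
own polar sample, or either angular neighbor (wrap-around), was invalid — a
declared one-pixel approximation of the filter's support.

Circular filtering makes column rotation exactly equivariant (shift the
polar image by k columns, the code shifts by k bit-pairs), which is what
the rotational shift search in matching exploits; phase quantization makes
the code invariant to positive affine intensity rescaling.

## Matching

`HD = popcount((A xor B) and maskA and maskB) / popcount(maskA and maskB)`.
Identical irides give HD near 0; independent irides give HD near 0.5 with a
binomial-like spread.  `match` minimizes HD over circular shifts of the
second code within +-8 bit-pairs (+-12 degrees at 240 angular samples) and
applies the decision criterion inclusively: same iris iff `hd <= criterion`
(default 0.40).  Zero jointly-valid bits is an undefined comparison and
raises.  The decision is monotone in the criterion, which is what makes
sweep rows monotone by construction.

## Evaluation designs

Segmentation errors are classified by combined displacement — Euclidean
center offset plus absolute radius error, maximum over the two boundaries:
*success* at <= 2 px, *slight* at <= 5 px, *extreme* beyond; a failed
segmentation counts as extreme.  Success-rate tables count per-boundary
successes per method; percentages are printed to one decimal, rounded
half-up (the convention that reproduces published tables from their
counts).  HD distributions are summarized with 0.01-wide histograms, the
maximum intra-class HD, the minimum inter-class HD, and their separation
interval (empty when the classes overlap).  The dilation sweep compares a
non-dilated gallery against probes grouped by dilation level at each
decision criterion; a cell is the percentage of comparisons at or below the
criterion, and comparison counts per level are
`|gallery| x |probes at level|`.

## Benchmark conditions

All headline numbers come from three seeded benchmarks (sizes chosen so the
whole suite runs comfortably on one CPU):

* **Segmentation**: 50 eyes, 192 x 192 px, limbal radius 72 px (center
  jittered <= 3 px), pupil radii uniform in [20, 60] px, pupil center
  offset up to 10 px, noise sd 0.02, no occlusions.  The blob-seeded method
  locates the pupil within 2 px on >= 95% of eyes and the three methods
  rank proposed >= edge+Hough >= exhaustive in pupil success.  Limbal
  accuracy of the proposed method is limited by its 10 x 10 search window
  when the true limbal center sits near the offset limit — errors there are
  "slight", a few pixels.
* **Identity**: 20 identities x 3 images, 160 x 160 px, limbal radius
  60 px, pupil radii {26, 30, 34} px, eyelid coverage 0.15, one specular
  spot, noise sd 0.02; full pipeline per image (images failing segmentation
  are excluded from matching, as one would in practice).  Intra-class HDs
  run about 0.02-0.12 and inter-class about 0.43-0.52, a cleanly bimodal
  separation.
* **Dilation**: one identity; 68 gallery images at pupil diameters
  3.2-4.0 mm and 3 + 3 + 1 probes at 4.6 / 6.3 / 7.4 mm, at the declared
  analog scale of 10 px per mm (radius_px = diameter_mm x 5), giving
  204 / 204 / 68 comparisons per level; criteria 0.37-0.41.

Because the generator is rubber-sheet-consistent, dilated probes differ
from the gallery only by resampling and segmentation noise, and the sweep's
columns are non-increasing in dilation only weakly (cells sit at or near
100%).  A real iris deforms nonlinearly as the pupil dilates, which is
precisely what the rubber-sheet model does not capture — the synthetic
sweep validates the machinery (counts, monotone structure, criterion
handling), not the physiological effect size.

## Known limitations

* Boundaries are circles; elliptic or active-contour models are out of
  scope, as is off-axis gaze.
* The proposed method's limbal search window (10 x 10, centred on the pupil
  center) cannot recover limbal centers offset by more than ~7 px from the
  pupil center.
* The eyelid line is straight; parabolic lids are masked conservatively.
* Matching applies no quality weighting or low-valid-bit HD correction.
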