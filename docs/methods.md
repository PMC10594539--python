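# Methods

`phosmap` simulates the visual experience a cortical visual prosthesis can
deliver, starting from a retinotopically mapped cortical surface rather than
from an idealised phosphene grid. This note describes the models, the
defaults and their rationale, the numerical choices, and what the synthetic
data generator does and does not emulate.

## World model: the retinotopic surface

A surface is a cloud of *grayordinates* — cortical sample points ~2 mm
apart, each carrying a 3D position (mm), a population receptive field (pRF)
given as polar angle and eccentricity (deg) plus a pRF size (deg radius),
an ROI label (V1/V2/other), hemisphere and a gyrus/sulcus flag. Real maps of
this structure (e.g. from 7 T pRF mapping) can be supplied as a CSV/TSV
table with columns `id, x_mm, y_mm, z_mm, polar_angle_deg, eccentricity_deg,
prf_size_deg, roi, hemisphere, is_gyrus`.

The polar-angle convention is declared rather than inherited from any
dataset: 0° is the upper vertical meridian, angles grow clockwise, so the
right visual field has positive `x = ecc·sin(angle)`. Anatomically,
x is left–right (the coronal plane is x–z), y posterior–anterior,
z inferior–superior.

### Synthetic generator

The generator builds two mirror-symmetric hemispheres, each a folded sheet
with adjacent V1 and V2 bands:

* **Radial (eccentricity) coordinate** — the complex-log template
  `u = k·ln(ecc + a0)` with `a0 = 3.67°` (shared with the magnification
  model below) and `k` chosen so the sheet's extent at 2 mm sample spacing
  spans the requested eccentricity range. This reproduces cortical
  magnification: foveal degrees get far more cortex than peripheral ones.
* **Angular coordinate** — linear in the hemifield angle across the band
  (an anisotropic log-polar map; the conformal version would couple the
  angular extent to `k` and could not fill an arbitrary band).
* **V2** — a band adjacent to V1 with the angle mapping mirrored at the
  border, emulating the field-map reversal at the V1/V2 boundary.
* **Folding** — a single sinusoid along the eccentricity axis (default
  amplitude 2 mm, wavelength 12 mm, the scale of an occipital gyral fold)
  displacing the sheet laterally; `is_gyrus` is true where the displacement
  is outward. This is the simplest geometry that makes the gyri-only
  placement constraint non-trivial.
* **pRF size** — `size = 0.05·ecc + 0.5 deg` plus Gaussian noise
  (s.d. 0.1 deg), typical of early visual cortex; the slope/intercept/noise
  are parameters, and with zero noise an OLS fit recovers them to machine
  precision (a test).

What the generator does **not** emulate: real cortical curvature beyond one
sinusoid, subject-to-subject variability in map topology, pRF measurement
noise structure, the V3+ neighbourhood, or sulcal depth geometry. Tests
passing on synthetic surfaces therefore demonstrate correctness of the
machinery (projection, constraints, rendering, metrics), not fidelity to
any individual brain.

## Implant placement

The default array is 43 electrodes at 1 mm pitch: a 7×7 grid minus the four
corners and the two long-axis mid-edge sites, footprint 8 mm × 7 mm
(long × short). The true commercial tile geometry is not public; any layout
can be supplied.

Posing fits a tangent plane by least squares over the K = 20 nearest
grayordinates (they must lie within 20 mm, else the surface is declared
degenerate). The in-plane reference axis is the projection of the global
inferior–superior axis, so the rotation parameter measures the long axis'
angle from the coronal plane, which is how the ±45° hardware constraint is
stated. Constraint checks are inclusive at their boundaries (45°, 20 mm to
the coil centroid — by default the per-hemisphere centroid of implant
centres — and 3.6 mm separation, with a 1e-9 mm epsilon against float
noise). For high implant counts (more than 8) the separation rule may be
relaxed; violations then downgrade to warnings and the pairwise footprint
overlap is quantified instead: both rectangles are projected into the
mid-plane between the arrays and the overlap distance is the extent of
their intersection across the long edges (the larger of the two short-axis
extents). Identical poses give the short side; disjoint footprints give 0.

## From electrodes to phosphenes

Each electrode elicits one phosphene. Its visual-field position and raw pRF
size are inverse-distance-weighted averages (weights 1/d, 3D Euclidean
distance — geodesic distance is not computable from a point cloud and the
50-neighbour ball is locally flat at this scale) over the 50 nearest
grayordinates; an electrode within 1e-9 mm of a grayordinate takes that
grayordinate's values exactly.

Phosphene radius scales the pRF size through two factors:

1. **Subdural relation.** Activated cortical diameter is sigmoidal in
   current, `AC = MD/(1 + e^(−slope·(I − I50)))` with MD = 5.3 mm,
   I50 = 0.89 mA, slope = 5.85 mm/mA, and inverse magnification is
   `1/M = (ecc + e2)/A` with e2 = 3.67°, A = 29.8. At I = I50 the activated
   radius is MD/4 = 1.325 mm, giving the linear relation
   `radius = 0.044·ecc + 0.163` deg. A subject's own fitted pRF slope `a`
   is matched to this relation by the factor 0.044/a.
2. **Intracortical correction.** Intracortical stimulation (80 µA) activates
   a much smaller patch; its 0.34 mm radius is taken as a given constant
   (the sigmoid above, fit to subdural data, does not extrapolate to it),
   giving the ratio 0.34/1.325 ≈ 0.256.

The combined factor is ≈ 0.011/a. A printed alternative form of the scaled
relation with intercept `b/a × 0.007` is inconsistent with scaling the whole
relation by 0.044/a (which gives 0.044·b/a); this package applies the single
multiplicative factor 0.011/a to the raw pRF size, which reproduces all the
other constants of the chain.

The subject fit itself is OLS of pRF size on eccentricity over V1∪V2 with
outlier clamping: responses outside their 95% *prediction* interval (the
per-observation reading of "bounds for each response observation") are
replaced by the fitted value and the model is refit once; the count of
replaced points is reported for audit.

**Control maps** hold phosphene count fixed, draw positions uniformly over a
disc (default radius: the 95th-percentile eccentricity of the paired
retinotopic map — the control field extent is otherwise unspecified) and
assign radii from the averaged linear fit, preserving the magnification
trend while removing spatial clustering.

## Stimuli, selection and rendering

Optotypes use the standard 5×5 construction (height 5·MAR, stroke MAR,
MAR = 10^LogMAR arc-minutes). Gratings are square waves with bar width MAR,
50% duty cycle, phase anchored at the centre of a circular patch (patch size
and duty cycle are declared; the source acuity cards do not print them).
The rendering scale is 40 px/deg (consistent with a 200 px ≈ 5° clustering
epsilon) on a 1080×1080 canvas centred at fixation. Object stimuli are
parameterised 540×540 silhouettes of five clothing classes (top, trousers,
dress, sneaker, bag) — synthetic stand-ins for a clothing-image benchmark,
generated programmatically.

Selection: *skeleton sampling* thins the stroke to a 1 px medial axis and
activates the nearest phosphene of every skeleton pixel (Euclidean distance
in pixels, ties to the lowest index — deterministic); *direct masking*
activates every phosphene whose centre pixel exceeds an intensity threshold
(0.5; only meaningful for grayscale inputs). Centres off canvas are simply
inactive and are tallied.

Rendering draws each active phosphene as a 2D Gaussian, peak = intensity
(default 1), σ = radius/3 in pixels, summed and capped at 1. Windows of
±4σ bound the cost; the cap makes rendering order-independent.

Ladder scoring: tumbling-E levels (0.8–2.6 LogMAR, step 0.2) pass at ≥ 4/8
correct, grating levels (2.3–2.9) at ≥ 7/8; the score is the best passed
level, or 3.0 if nothing passes. The simulated-observer loop that would
produce trial outcomes is out of scope; `brvt_score` consumes outcomes from
any source. Validation blocks are 12 trials at VA−0.2, VA and VA+0.2
(levels below the 0.8 floor are returned but flagged).

## Relocation

DBSCAN on phosphene pixel positions (eps 200 px, minPts 100; closed
neighbourhood, self-counting — conventions differ between implementations,
so these are declared) separates the dominant cluster from outliers. The
stimulus centre is translated to the centroid (arithmetic mean) of the
largest cluster — ties go to the centroid nearest fixation — rounded to
whole pixels and clamped so the stimulus foreground stays on canvas
(clamping is flagged). If no cluster forms the stimulus is returned
unchanged with a warning flag.

## Map metrics

* **Complexity** adapts a contour shape-complexity measure to unordered
  point sets. The local angle at a point is subtended by its two nearest
  neighbours; per-point smoothness is `1 − θ/π` (0 for flat neighbourhoods,
  1 for spikes). The combined score is the unweighted mean of the distance
  entropy and angle entropy (each normalised by log₂ n_bins, default 16
  bins, base-2 logs) and the mean smoothness. Regular shapes score near 0,
  uniform scatters high; only this qualitative ordering is asserted, since
  the original method operates on ordered contours and its exact binning is
  unrecoverable. A caveat of the point-set adaptation: the tips of an open
  chain see both neighbours on one side (angle 0), so a finite collinear
  run reaches zero smoothness only as n grows.
* **Mutual information** between two images in [0,1]: centred zero-padding
  to a common size, joint PMF from the 2D histogram of co-located pixels
  (default 64 bins), cells below 1e-12 dropped (mass reported), result in
  bits. MI(X,X) = H(X) and symmetry hold exactly; the constant-image
  identity MI = 0 holds for equal-size inputs (padding makes a padded
  constant two-valued by construction).
* **Area** is the area of the tightest single-component alpha-shape
  containing all phosphene centres — the analogue of a maximally-shrunk
  compact boundary. Delaunay triangles are admitted in order of
  circumradius and the smallest threshold whose union is a single
  hole-free polygon covering every point is found by bisection (the
  predicate is monotone). Collinear input returns zero area with a
  degenerate flag; if no threshold qualifies the convex hull is the
  fallback.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng` seeds carried in
the configuration; two pipeline runs with the same config produce
byte-identical CSV/JSON artifacts (tested). Default test problem sizes —
2000 grayordinates per hemisphere, ≤ 516 phosphenes, ≤ 300-point clustering
fixtures, 1080² canvases — keep the full suite under ten seconds while
exercising every code path at the scale the method actually runs at.

## Known limitations

Phosphene brightness/temporal dynamics, multi-electrode interactions and
per-electrode thresholds are not modelled (one phosphene per electrode,
unit intensity unless specified). KNN uses Euclidean, not geodesic,
distance. The synthetic folding is a single sinusoid; sulcal banks face
each other unrealistically at large amplitudes. The human psychophysics
layer (eye tracking, display timing, observers) is explicitly out of scope.
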