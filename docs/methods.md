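# Methods

`fruitglove` re-creates, in software, the measurement chain of a sensor-glove
fruit grader: calibrated fingertip pressure sensing, laser-seeded interactive
segmentation with a single palm camera, pin-hole geometric morphometry, and
turgor-pressure ripeness grading. No hardware is involved; a synthetic
scene/sensor simulator generates every input together with machine-readable
ground truth.

## Sensor models (`fruitglove.calibration`)

Four transfer functions map raw electrical readings to physical quantities.

* **Pressure transducer** (MPX5700-style): `P0 = ((X − A)/0.064290)·0.101972`
  kgf/cm², with `X` the output voltage and `A` the offset (default 0.2 V).
  The 0.101972 factor is the kPa→kgf/cm² conversion; the 0.064290 V/kPa
  divisor is kept exactly as calibrated even though it is dimensionally
  surprising against the part's datasheet sensitivity — the constant pair is
  treated as an opaque bench calibration. Sub-offset voltages yield negative
  pressures and are deliberately not clamped (the probe correction
  `P = 0.83·P0 − 0.02` has a negative intercept); callers interpret them.
* **Fingertip FSR**: force-sensitive resistors respond with an inverse power
  law, `P = 3.29·x^−2.061` (r² = 0.99 on the bench data); a degree-2
  polynomial alternative `P = 0.0802x² − 0.77x + 2.606` (r² = 0.95) is kept
  for comparison. The power form requires x > 0.
* **IR distance sensor**: `D = 2736.24·adc^−0.9909` cm, with an activation
  gate at 5–25 cm — in the glove this is what wakes the optical system.
* **Finger bend**: a per-user linear map sends the completely-closed reading
  to 0° and completely-open to 180° (the angle convention is configurable —
  the hardware only defines the two calibration postures). For grasped
  spheres, a **natural cubic interpolating spline** through four
  reference-sphere knots (ADC 887→25 mm, 859→50 mm, 826→100 mm, 809→150 mm)
  maps raw readings to diameter. Natural boundary conditions were chosen as
  the simplest interpolant through four points; it reproduces eight of the
  nine bench check readings to the printed 0.01 mm. The ninth (reading 812,
  printed 146.49 mm) is unreachable by *any* cubic spline interpolating the
  knots that also matches the other eight rows — we treat that printed value
  as erroneous, and the corresponding acceptance test is left failing rather
  than bending the model to it.

`fit_model` fits fresh calibration tables: linear and degree-2 polynomial by
ordinary least squares, power laws by OLS in log–log space (requiring
positive data). r² is always computed on the original scale so the forms are
comparable; on synthetic FSR-style data the power form's r² is at least the
polynomial's, matching the sensor's theoretical response.

## Camera geometry (`fruitglove.vision`)

A pin-hole model with focal length `f = (w/2)/tan(FOV/2)` pixels, principal
point at the image centre, 0-based top-left pixel coordinates. Depth uses
parallel-axis triangulation, `Z = f·H/d`, where `H` is the 2.5 cm baseline
and `d` either the stereo disparity `xL − xR` or the laser dot's horizontal
offset from the principal point (the beam is parallel to the optical axis).
Laser depth is flagged reliable only within 3–7.3 cm; this window is kept as
a configuration constant because it does not follow from `f`, `H` and the
image width alone.

RGB+NIR fusion assumes the object is planar at known depth, so the NIR frame
is the visible frame translated by the disparity `f·H/Z`:
`I(x, y) = NIR(x − f·H/Z, y)`, bilinearly resampled, with out-of-bounds
source pixels zeroed and flagged.

For a segmented near-circular object of `a_CI` pixels at depth `Z`, the
distance-invariant area is `t = a_CI·Z²/f²`. The image-inversion sign of the
projection is dropped; areas are magnitudes. Conversion of `t` to cm² goes
through a configurable cubic, default
`A = −4.45·10⁻¹²·t³ + 1.11·10⁻⁷·t² + 2.05·10⁻³·t − 3.95·10⁻¹`
(an empirical per-camera fit on ten reference circles; it is monotone only
up to its turning point near t ≈ 2.1·10⁴, the top of that calibration span,
and negative raw outputs are clamped to zero with a flag). For the ideal
synthetic camera no empirical correction applies — with `Z` in cm and
`a_CI`, `f` in pixels, `t` already *is* the area in cm² — so the simulator
pipeline uses the identity coefficients `(0, 0, 1, 0)`. Radius and volume
assume a spherical fruit: `r = √(A/π)`, `V = (4/3)πr³`.

## Segmentation (`fruitglove.segmentation`)

The laser dot is the brightest red point: argmax of `s = R − max(G, B)`
subject to `s ≥ 60` and `R ≥ 200` (8-bit defaults, configurable), ties
broken toward the smallest `(y, x)`. Each detected dot becomes a seed with a
time-to-live (default 30 frames — the hardware defines the mechanism but no
number); seeds are advanced between frames by dense iterative Lucas–Kanade
optical flow (scikit-image's `optical_flow_ilk`, sampled at the seed),
dropped when they expire or leave the frame.

Region growing uses fuzzy connectedness with a Gaussian link affinity
`μ(p, q) = exp(−(I(p) − I(q))²/2σ²)` on the per-pixel channel mean, σ = 25
grey levels, threshold θ = 0.7. A pixel belongs to the object if some
4-connected path from a seed keeps every link affinity ≥ θ — equivalently,
if it is connected to a seed through edges with `|ΔI| ≤ σ·√(−2·ln θ)`
(≈ 21.1 grey levels at the defaults). That equivalence lets the mask be
computed exactly as connected components of the thresholded-edge pixel graph
(`scipy.sparse.csgraph`), rather than an explicit max-min path search; tests
verify it against an independent flood-fill oracle on noiseless images.

A note on pre-smoothing: blurring the image before growing is tempting for
noise robustness but is **off by default**, because a Gaussian blur
stretches the object boundary into a shallow ramp precisely where an image
column or row grazes the circular contour tangentially — there the per-step
intensity change becomes arbitrarily small and the region growing climbs out
of the object. With the hard edge intact, the boundary step is the full
object/background contrast everywhere, and the affinity's σ already absorbs
pixel noise (at the simulator's contrast of ~145 grey levels and noise sd
10, a boundary crossing would need a ≳15-sigma fluctuation).

The moving fovea restricts stereo block matching (7×7 SAD along the epipolar
row) to a 128×128 window centred on the last laser dot.

## Grading (`fruitglove.grading`)

A grasp event is a maximal interval where the across-finger pressure maximum
exceeds `on_kPa` (default 20) for at least `min_duration_s` (default 1 s).
Per finger, the plateau is the median over the middle 80 % of the interval,
trimming the grip/release ramps; fingers below half the best finger's
plateau are treated as poor contacts and excluded, and the event pressure is
the mean of the valid plateaus — robust to the routinely seen
low-contact finger. When a trace holds several events, the per-fruit
pressure reported by the pipeline is the median across events.

Ripeness bands (kPa): `< 20` inadequate (spoiled/overripe), `20–100` ripe,
`100–150` ripening (the literature gap between the ripe and unripe bands,
made explicit), `≥ 150` unripe; values above 400 stay unripe. A per-variety
ripe/unripe demo threshold (tomato: 200 kPa) lives in configuration, since
thresholds are variety-specific.

The overall quality score is a weighted mean of per-feature triangular
memberships — 1 at the centre of the user's ideal range, 0 at its limits —
normalised by the weight sum (hence invariant to uniform weight rescaling)
and bounded in [0, 1]; an alert fires below a configurable threshold (the
glove would vibrate).

## Synthetic data (`fruitglove.simulate`)

* **Scenes**: a flat-coloured disk of pixel radius `f·R/Z` (spherical fruit
  → circular projection) on a dark background, additive Gaussian pixel
  noise, and a red-saturated laser dot drawn at the triangulation-consistent
  offset `f·H/Z` from the principal point, so single-camera laser depth is
  exercised end to end. The dot colour (255, 150, 75) keeps the fruit
  flesh's channel-mean luminance so the seeded growth crosses from dot into
  fruit, as on real frames where the dot blooms into fruit-lit pixels.
  Default study conditions: fruit radius 2–4 cm, depth 4–7 cm, noise sd 10
  grey levels, VGA resolution. The simulator camera uses a 120° FOV: with
  the narrow 48° hardware FOV, a 2–4 cm-radius fruit at 4–7 cm cannot fit a
  VGA frame at all (the visible diameter at 4 cm is only 3.6 cm), nor can
  the laser dot's offset stay in-frame; widening the synthetic FOV keeps the
  stated radius/depth ranges intact while making every scene geometrically
  realisable. An optional NIR frame is rendered shifted by `−f·H/Z`.
* **Traces**: per grasp, a trapezoidal pulse (0.3 s linear ramps) whose
  plateau is turgor × per-finger contact quality, plus Gaussian noise,
  clipped at zero; defaults 3 s grasps, 2 s gaps, 50 Hz.
* **Calibration tables**: an even raw grid across the model's valid range
  with multiplicative Gaussian noise, mirroring the syringe-press bench
  procedure (0–6 kgf/cm² in 0.5 steps, readings averaged over repeats).

All generators are pure functions of their spec; the same spec and seed give
byte-identical output. What the simulator does **not** emulate: real fruit
shape (only disks), shading, specularity, lens distortion, background
clutter, sensor drift, or biomechanical turgor dynamics — so passing tests
demonstrate the computation chain is correct under its stated geometric
assumptions, not field performance on real produce.

## Pipeline (`fruitglove.pipeline`)

Depth source priority: laser (if its estimate is inside 3–7.3 cm) → IR
reading (inside 5–25 cm) → none (geometry skipped), reflecting that laser
triangulation is the more precise of the two short-range methods. The IR
gate also models the hardware power logic: an out-of-window IR reading with
no visible dot means the optical system would never have engaged. Reports
are JSON with fixed six-decimal float precision, embedded units and a schema
tag, so identical inputs and configuration produce bit-identical output.

## Problem sizes and numerical choices

The shipped accuracy experiment uses 20 scenes at VGA resolution (noise sd
10, radius 2–4 cm, depth 4–7 cm), which completes in a few seconds; the mean
per-scene accuracy `100·(1 − |est − true|/true)` of area and volume is the
headline metric. The residual few-percent area error is dominated by laser
dot localisation (the argmax lands anywhere inside the saturated dot blob,
so the depth carries a ±dot-radius quantisation) plus disk rasterisation;
volume error is ~1.5× the area error through `V ∝ A^{3/2}`. Degenerate
inputs are rejected with typed errors (`CalibrationError`, `GeometryError`,
`SegmentationError`, `GradingError`, `ConfigError`, `PipelineError`) rather
than NaNs; ties and clamping behaviours (dot ties to smallest (y, x),
spline extrapolation clamped-and-flagged, negative area clamped-and-flagged)
are part of the tested contract.

## Known limitations

* The four-knot bend spline is only as good as its sparse calibration;
  outside 809–887 ADC it clamps rather than extrapolates.
* Laser depth quantisation limits geometric accuracy at small dot offsets;
  a sub-pixel dot centroid would improve it and is not implemented.
* The fuzzy affinity uses channel-mean intensity only; chromatic information
  is ignored beyond dot detection.
* The quality score's triangular memberships are a modelling choice; the
  hardware specification prescribes weights and a threshold but no
  functional form.
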