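# Methods

This note records the model behind `epidiso`, the choices made where the
design was open, and what the synthetic validation does and does not show.

## Coordinate conventions

All geometry lives in the IEC 61217 machine frame: +lateral toward the
couch's left as viewed from the gantry, +longitudinal toward the gantry,
+vertical up.  The gantry rotates about the longitudinal axis; at gantry 0
the source is above the isocenter.  The EPID panel is modelled
perpendicular to the beam at the source-to-imager distance (SID); its
column axis maps to the room direction (cos g, 0, −sin g) and its row axis
to (0, 1, 0) for every gantry angle g.  The panel does not rotate with the
collimator — the jaw assembly rotates within the panel frame, with the X
jaws travelling along (cos c, sin c) and the Y jaws along (−sin c, cos c)
at collimator angle c.  X1/Y1 sit on the negative side of their travel
axis, X2/Y2 on the positive side.

Every distance the software reports is expressed in millimetres **at the
isocenter plane**: detector millimetres divided by the SID/SAD
magnification (1.46 for the default 1460/1000 mm geometry).  Couch shifts
are isocenter-plane quantities, so this scaling is physically forced even
though it is easy to omit.

## Measurement model

1. **Edge detection.**  A five-stage Canny detector is implemented
   stage-by-stage: separable Gaussian blur (kernel truncated at 4σ and
   renormalised, reflective boundaries), 3×3 Sobel gradients with the
   orientation quantised to four categories, non-maximum suppression with
   a deterministic tie-break (ties on a plateau keep the smaller index
   along the scan direction), double threshold, and edge tracing that
   keeps weak pixels only when 8-connected to a strong pixel.  Images are
   divided by their 99th-percentile intensity before detection so one
   threshold setting serves machines with different monitor-unit
   scalings.  Defaults (threshold_high 0.12, threshold_low = 0.4 ×
   threshold_high, σ = 2 px) were chosen from the gradient scales of the
   synthetic images: the field penumbra edge has a normalised Sobel
   response ≈ 0.5, the phantom face ≈ 0.2, and the 1 % noise floor
   ≈ 0.006, so the defaults sit an order of magnitude above noise and
   well below the weakest edge of interest.  AP (gantry 0/180) and
   lateral (gantry 90/270) views carry independent settings.  The config
   file also stores display window/level values for UI parity; they never
   affect detection.

2. **Subpixel localization.**  A Canny pixel only seeds the measurement.
   Per ray, the edge position is the linearly interpolated 50 %-intensity
   crossing of the blurred image, with the two side levels estimated in
   bands 2.0–4.2 mm on either side of the candidate.  Because an
   error-function penumbra is point-symmetric about its midpoint,
   symmetric level bands leave the 50 % crossing unbiased even when the
   bands clip the penumbra shoulders.  Eleven rays per edge, evenly
   spaced over the central 50 % of the edge's extent (an odd count keeps
   a center ray), are averaged; their standard deviation is reported as
   `ray_spread_mm`.  Candidates are filtered by gradient polarity — for a
   phantom face the intensity must rise moving out of the phantom — which
   also rejects the wall/interior contrast boundary a few millimetres
   inside each face.

3. **Phantom center.**  Per panel axis the center is the midpoint of the
   two opposing face edges.  The faces of a thick cuboid project with a
   geometric ramp (the silhouette of a 80 mm-deep box in a diverging
   beam spans ~3 mm), but the ramp is symmetric between opposing faces,
   so the midpoint stays unbiased to well below 0.05 mm for offsets up to
   a few millimetres.  When the central crosshair is modelled, its
   intensity dip (parabolic fit over rays placed 6–14 mm off-center)
   refines the estimate; the two estimates must agree within one pixel,
   otherwise the face midpoint wins and a warning is logged.

4. **Jaw policy.**  Siemens-style machines form the X field edge with an
   MLC whose adjacent leaves commonly step by ~1 mm; only the smooth Y2
   jaw is measured there, and a request to measure an X jaw is refused
   unless explicitly forced (used by the straightness diagnostics).
   Dual-jaw machines measure X2 and Y2 in every image.

## Solver

The pair shift s = (d₁ − d₂)/2 is evaluated with d₁ taken at the
collimator angle in [0, 180).  The mapping from (jaw, gantry, collimator
pair) to a signed room dimension is an explicit table, derived from the
IEC geometry above and validated in the tests against both the analytic
direction vectors and end-to-end renders of unit offsets: Y-jaw pairs at
collimator 90/270 measure lateral at gantry 0/180 and vertical at 90/270;
pairs at collimator 0/180 measure longitudinal at every gantry angle
(X jaws mirror this).  Averaging first groups pair shifts within a gantry
angle, then averages across gantry angles, so n in S̄_r = Σs/n counts
gantry angles as the model prescribes.  For the 16-image single-jaw plan
the collimator 0/180 pairs at gantry 90/270 are *included* in the
longitudinal average (n = 4); the alternative — discarding them — wastes
half the longitudinal information, and the closed-loop tests confirm the
included pairs are unbiased.  Sessions are strict by default (missing
views abort with the list of absent gantry/collimator combinations); a
permissive flag computes with the available pairs and the reduced n is
visible in the result.

The couch shift equals S̄ with a per-machine sign triple (default
identity: +lateral/+toward-gantry/+up).  Direction conventions differ
between couch vendors, so the signs are configuration, not physics.

## Synthetic data generator

The renderer is first-class, tested code: it is the ground-truth oracle
for every downstream module.  It emulates

* a square open field with error-function penumbra (default σ = 1.5 mm at
  the isocenter plane, a typical 6 MV EPID edge width), 2 % jaw
  transmission, and per-jaw calibration offsets (positive = field opens);
* an optional jagged MLC-formed X1 edge: 10 mm leaves with fixed per-leaf
  deviations uniform within ±1 mm, a property of the simulated machine
  (seed-dependent, view-independent);
* collimator walk-out as a field-center displacement of fixed amplitude
  in the collimator frame (≤ 1 mm, the mechanical tolerance);
* the phantom as a hollow 80 mm cube (6 mm solid walls, 25 % interior
  fill) with three thin denser central planes forming the crosshair,
  rendered by exact ray–box chord lengths from the true source position —
  divergence, magnification and the thick-edge silhouette ramp come out
  of the geometry rather than being painted on;
* single-energy exponential attenuation (μ ≈ 0.0047 mm⁻¹, solid ABS at
  megavoltage energy), a 0.7 mm focal-spot blur, additive Gaussian noise
  (default 1 % of the open-field plateau), and quantisation to integer
  detector units.

Defaults are the study conditions: 100 mm field, SAD 1000 mm, SID
1460 mm, detector pitches 0.4 and 0.78 mm, phantom offsets up to 2 mm in
closed-loop trials.  What the model deliberately omits: scatter and beam
hardening, EPID glare/ghosting, panel sag (irrelevant by construction —
the collimator is the frame of reference), couch-walk during acquisition,
and gantry sag beyond what the averaging is designed to absorb.  Passing
tests therefore demonstrate the *analysis* is correct and
self-consistent under realistic contrast, penumbra, magnification and
noise; they cannot certify behaviour under detector artefacts absent
from the model.

Star shots are rendered as strip films: every centerline passes through
the radiation isocenter, displaced from the film-center reference mark by
minus the phantom offset.  The axial film uses five gantry angles
(0°, 30°, 150°, 240°, 300°) for lateral/vertical; the coronal film uses
gantry 0/180 with the collimator rotated 10°, giving two strips at ±10°
whose intersection fixes longitudinal.  The coronal film is treated as at
isocenter height; the ≤ 0.2 % magnification error from a millimetre-scale
vertical offset is negligible at the reported precision.

## Star-shot analysis

The analyzer is image-driven and shares no code with the EPID
measurement.  A heavily blurred maximum locates the strip overlap; two
circular profiles (radii 20 and 32 mm) around that point yield the
angular centers of the above-half-maximum runs; opposing runs (≈ 180°
apart — near-diametral only because the profile circles are centred on
the rough intersection, which is why that recentering step exists) are
paired into strips; a total-least-squares line through the four
edge-midpoint crossings per strip gives its centerline; and the estimate
is the center of the exact minimum enclosing circle (brute force over
point pairs/triples) of all pairwise intersections — the conventional
"circle touching all lines" star-shot report.  By default at least three
strips are required and a two-strip image is rejected; the coronal
two-strip film is analysed by passing `min_strips=2` explicitly, since
its ±10° construction makes the single intersection well conditioned in
the longitudinal direction.  This analyzer is a reconstruction of
conventional film practice, not of any specific commercial tool.

Two instructive interactions surfaced in validation.  Collimator
walk-out, modelled as a displacement fixed in the collimator frame,
cancels *exactly* in the single-jaw 180° pairing (the displacement
projects identically onto the rotated jaw axis in both images) but
leverages into the near-parallel coronal strips as ≈ walkout/sin 10°;
the cross-validation records this disagreement rather than bounding it.
And penumbra plus detector blur average adjacent MLC leaves at rays that
straddle leaf boundaries, so the measured ray spread on a jagged edge
settles slightly below the raw ±1 mm leaf-jitter standard deviation
(≈ 0.48 vs 0.58 mm) while remaining two orders of magnitude above a
straight jaw's spread.

## Numerical and procedural choices

* Filename fallback: `G<ggg>_C<ccc>.dcm`, three digits each, matched
  strictly; used only when the DICOM angle tags are empty (an observed
  Elekta iView GT export quirk) and only when explicitly enabled, because
  a typo in a filename silently becomes a wrong couch shift.
* Synthetic Elekta sessions are written with empty angle tags so the
  fallback path is exercised on real files.
* Edge search windows: ±5 mm around the nominal half-field for jaws,
  ±6 mm around the nominal half-width for phantom faces — the "is the
  edge near its expected location" sanity check.
* A jaw or face measurement needs at least 3 successful rays of 11;
  fewer raises a named error rather than returning a degraded value.
* Determinism: identical inputs give bitwise-identical results end to
  end (no unseeded randomness anywhere in the analysis path); renders
  are bitwise-reproducible for a fixed truth seed.
* Problem sizes in the validation suite: closed-loop accuracy uses 20
  random offsets per detector pitch on full 8-image sessions;
  cross-validation uses 20 noisy truths; these sizes give stable worst-
  case statistics while keeping the whole suite around two minutes.

## Known limitations

* Measurement profiles are extracted along panel rows/columns, so
  analysis supports cardinal collimator angles (0/90/180/270) — all the
  acquisition plans use only these; the 10°-collimator geometry appears
  only in the star-shot module, which is angle-agnostic.
* The vendor jaw policy assumes X2/Y2 for dual-jaw machines; any jaw can
  be requested explicitly.
* No MLC leaf-position measurement, no couch-control integration, no
  per-gantry-angle wobble map (only the averaged best-compromise
  isocenter), no scatter/dosimetric realism in the renderer.
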