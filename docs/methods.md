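# Methods

## Measurement model

The measured quantity is the axial rotation α of a single vertebra, read
from two AP-film landmark groups: the projected body quadrilateral and the
inner-contour points of the two pedicle shadows. The geometric model is
that rotation about the cranio-caudal axis displaces the inter-pedicle
midpoint laterally by `d = x·tan α`, where `x` is the pedicle rotation
radius in the transverse plane (half lower-endplate depth plus half
spinal-canal depth). Since `x` is nearly proportional to the body height
`z` across levels, the construction replaces `x` by `k·z` with `k = 0.5`
(L1–L4) or `k = 0.75` (Th1–Th12 and L5) and reads α as the angle of the
triangle with legs `d` and `k·z`:

    α = atan( d / (k·z) )

All perpendiculars are defined against the vertebra's own bottom edge,
never the image axes, which gives the three invariances the test suite
enforces to 1e-9°: film scale, in-plane rigid motion, and mirror
antisymmetry.

The implementation computes the exact `atan` of the constructed triangle
rather than the linearised `d/(k·z)`; the linearisation error
`deg(tan(rad α)) − α` (0.10° at 10°, 3.08° at 30°) is exposed separately as
`small_angle_error` / the `error-table` command, as the intrinsic accuracy
budget of any protractor-free reading.

### Construction details and numerical choices

- **A** is the intersection of the body-quad diagonals. Degenerate
  geometry is declared when the quad area is below 1e-9 mm² or a diagonal
  intersection parameter falls outside [−10, 10].
- **B** is the diagonal intersection of the quadrangle cut from the top and
  bottom edges by the base perpendiculars through the two pedicle points.
  The two feet are ordered along the base edge before forming the
  quadrangle, so annotation order cannot produce a bow-tie.
- Edges are extended infinitely for intersection, but a hit farther than
  2× the quad diagonal beyond the edge segment raises a degenerate-geometry
  error rather than returning a wild extrapolation.
- **D** is the exact midpoint between B and the top-edge intersection of
  B's perpendicular (the protocol allows estimating it by eye; the code
  does not).
- The reported `z_mm` is defined as (construction height)/k, so the
  invariant `α = sign(d)·atan(|d|/(k·z))` holds identically even for
  slant-topped quads where "body height" is otherwise ambiguous.
- Sign convention: α > 0 when B lies toward +x of A's perpendicular in the
  base-edge frame. The clinical protocol reports magnitudes; the sign
  encodes rotation direction and flips under mirror reflection.
- Readings with |α| > 30° are returned with an `over-30deg` flag, never
  suppressed: beyond that the concave pedicle merges with the body contour
  and the method leaves its validated range.

### Concave-pedicle fallback

When one pedicle shadow has merged with the body outline (flagged in the
landmark file), the pedicle is assumed to coincide with the lateral body
contour: the missing inner point is replaced by the point of the
corresponding lateral edge at the same bottom-to-top height fraction as the
visible pedicle. This keeps large rotations measurable but biases them
low, since the true (merged) pedicle position lies past the silhouette
edge; the simulator reproduces exactly this regime.

### Wedged vertebrae

A wedged body's diagonal centre drifts toward the wedge apex (drift d′),
contaminating `d`. `wedge_substitute` replaces the contour with a
parallelogram whose base is parallel to the pedicle suture line and whose
height is the convex (undeformed) side's height, width preserved — which
restores the centre and, on simulated wedged phantoms, strictly reduces
|error| at every tested angle (wedges 5–15°). The convex side is the
taller of the two lateral extents; when the heights agree within a
tolerance (default 0.5 mm) the side is ambiguous and the suture-aligned
bounding rectangle is returned, flagged. `substitute_body` wires this into
a landmark set, taking the suture direction from the pedicle pair when both
points are present and from the bottom edge otherwise.

## The digital rotation device

`simulator` is the computational analog of a mechanical jig that holds a
vertebra at defined rotations from 0° to 45° in 3° increments. The phantom
is parametric: body height `z`, width, pedicle radius `x`, inter-pedicle
gap, optional endplate wedge. Defaults (mm): thoracic z=20, width=30,
gap=17; L1–L4 z=28, width=42, gap=24; L5 z=26, width=46, gap=28 — nominal
adult dimensions of the right order for each region; their exact values are
immaterial to the geometry, which is scale-invariant. `x` defaults to the
anatomical ratio x/z = 1.21 (thoracic) or 0.86 (lumbar); L5's ratio is not
separately tabulated and is set to the lumbar 0.86 (L5 is anatomically
lumbar even though it is *measured* with the thoracic rule).
`criterion_exact_vertebra` overrides `x = k·z`, the phantom for which the
construction is exactly invertible.

Two forward models place the pedicle midpoint offset: `tan`
(`d = x·tan α`, the relation the measurement inverts — the default) and
`sin` (`d = x·sin α`, what orthographic projection of a rotating point
gives). The measurement side is agnostic; the divergence between the two
(measured(sin) = atan(sin α) ≤ α at x = k·z) is surfaced by tests rather
than hidden, because the published relation and the orthographic one
genuinely differ and the film geometry that would arbitrate (source–film
distance, beam divergence) is not modelled.

Deliberate simplifications, hence what the simulator does *not* emulate:
silhouette width is held constant under rotation (the real projected width
changes slightly); no perspective magnification of the posteriorly located
pedicles; no cortical shading, endplate ellipses, or landmark ambiguity —
rater error is modelled as iid Gaussian jitter (default study value 0.5 mm
SD) on every landmark coordinate. Passing tests therefore validate the
*geometry* of the method and its noise propagation, not its performance on
real films, where landmark identification is the dominant error source.

Noise streams are derived per record as
`SeedSequence(seed, spawn_key=(rater, angle_index))`, so any observation is
reproducible in isolation; standard-normal draws are scaled by the noise SD,
making series at different noise levels perfectly correlated (used by the
noise-monotonicity test) and the zero-noise series bit-identical to the
clean one.

The pedicle-visibility limit defaults to 30°: beyond it the concave-side
pedicle is flagged merged and its stored point clamped to the silhouette
edge. The limit is configurable and `None` disables it — the setting used
for the inversion, bias and rater-study experiments, which emulate the
physical device where pedicles remained readable to 45°.

## Validation harness

`rater_study` runs the device series for several phantoms and raters and
tabulates, per level group (Thoracic, L1-L4, L5, All), the bias and SD of
the *residual* measured − defined. Residual SD is reported rather than raw
SD so that the defined-angle spread does not enter; with the defined value
subtracted the table isolates landmarking noise. Default study conditions:
criterion-exact phantoms at Th6, L2 and L5, 16 angles (0–45° by 3°), 10
raters, 0.5 mm jitter, dropout disabled. With anatomical (non-criterion)
ratios the deterministic bias `atan((x/(k·z))·tan α) − α` dominates — it is
verified against that closed form to 1e-9° by a dedicated test — so the
recovery study uses criterion-exact phantoms to make residuals reflect
noise alone. Groups with fewer than two observations are omitted with a
logged notice. SDs use ddof=1. Displayed tables round to two decimals; raw
values are kept internally.

`nash_moe_grade` implements the five-level comparator: grade 0 when the
pedicle pair is symmetric about the midline within 1% of body width; else
the convex-side pedicle (the one migrating toward the midline) is graded by
which third of its hemivertebra it occupies along the base edge, grade 4 at
or past the midline. The segment boundaries are the standard clinical
convention — the scale's defining publication, not this package, fixes
them — with ties at the midline resolved upward to grade 4. With
inner-contour pedicle points at anatomical gaps the neutral position
already sits ~0.4 of the hemivertebra in, so the smallest flagged
asymmetries enter at grade 2; the grade remains nondecreasing in true
rotation, which is the property that matters for a comparator.

## File formats

Landmark and config files are versioned YAML; unknown fields are rejected
rather than ignored, because a silently dropped flag (e.g. a merged-pedicle
marker) would change a reading. Files may declare a `y-down` pixel frame
with a `pixel_spacing_mm`; conversion to millimetres, y-up happens entirely
at the I/O boundary. Result tables are CSV with a provenance header (tool
version, config hash, seed, no timestamps) so identical configs reproduce
byte-identical outputs. Construction overlays are SVG, built with the
stdlib XML tree.

## Known limitations

- The tan-vs-sin forward ambiguity above: accuracy statements inherit
  whichever projection relation the film geometry actually follows.
- The 0.5/0.75 criteria round the anatomical ratios 0.86/1.21; on
  anatomically proportioned (non-criterion) vertebrae this leaves the
  deterministic bias characterised by the closed form above, growing with α.
- Beyond 30° the contour fallback recovers a usable but low-biased reading;
  results there are flagged and should be treated as qualitative.
- The simulated rater is a Gaussian-jitter idealisation; inter-rater SDs
  from the harness are not comparable to human inter-rater SDs on real
  films.
- No pixel-level processing: landmarks must come from an annotation tool or
  the simulator.
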