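# Methods

## The measurement

The quantity produced is the number of body bends in a single-worm video,
under the WormBook convention: the count advances once each time the part of
the body behind the pharynx reaches a maximum bend in the direction opposite
to the bend last counted. The pipeline reduces each frame to one signed
scalar — d_max, the largest-magnitude perpendicular distance from a
curvature peak of the centerline to the chord joining the pharynx point and
the tail — and counts direction reversals of that series.

Working with the peak-to-chord distance rather than raw curvature keeps the
statistic in pixel units, tied to a fixed anatomical chord, and robust to
where exactly along the body the deepest bend sits.

## Pipeline stages and the parameters that matter

**Segmentation.** Dark worm on a bright field. Optional preprocessing:
shadow removal (pixels in a configurable gray band between the worm and
background estimates are replaced by the background mode; band default =
midpoint of the 1st-percentile and modal gray ± 15) or absolute-difference
background subtraction when a worm-free frame is available. Binarization is
an adaptive local threshold with a `window` = 5 px moving window and
`offset` = 5 gray levels; because the window is narrower than the worm, the
threshold yields the worm's rim, and a 3×3 morphological closing plus
interior-hole filling (`hole_max_px` = 5000) recovers the solid body.
Components under `min_area` = 100 px are discarded and the largest survivor
kept. The window sum is computed in exact integer arithmetic so the
foreground decision cannot depend on floating-point summation order — this
is what makes the whole pipeline mirror-equivariant to machine precision.
The boundary is an ordered, closed, 8-connected pixel-center contour traced
with Moore neighbor tracing (Jacob's stopping criterion), oriented clockwise
in image coordinates.

**Head and tail.** Endpoint candidates are the two boundary vertices of
locally extreme sharpness: the interior angle at each vertex over a chord
span of 5% of the perimeter (computed at exact arc-length offsets, so the
result is independent of where the trace started), with candidates required
to be ≥ 25% of the perimeter apart and sharper than 120°. Angles below 8°
are rejected as single-pixel boundary spurs. A hit is then refined to the
geometric apex of its tip (the vertex farthest from the chord joining the
window ends), which fixes a 1–3 px bias on blunt rounded tips. The sharper
endpoint is the tail guess; the end region with higher median gray (disc of
radius 6 px restricted to worm pixels) is the head guess. The polarity
(brighter-is-head by default) is a flag, never hard-coded, because imaging
conditions determine which end appears darker. When the two cues disagree
the pair is flagged and, non-interactively, an `--assume-head` override is
required. Subsequent frames use minimal-motion tracking: the assignment of
the two current endpoints minimizing head–head + tail–tail distance to the
previous frame.

**Centerline.** The boundary is cut at the head/tail vertices into two
sides, each resampled to `n` = 120 points at equal arc length. For each
ventral point V_i, the dorsal partner D_j is searched over j ∈ [i−r, i+r]
(`r` = 10, clamped at the ends; endpoints pair index-to-index); the default
criterion selects the most perpendicular rung — minimal |(V_{i+k} − V_{i−k})
· (D_m − V_i)| with tangent increment `k` = 2 — because the literal
signed-minimum form of the pairing rule can select a degenerate far point
when the window contains points behind the tangent (`--pairing literal`
applies it verbatim; the two agree on symmetric shapes). The pairing is run
in both directions and the midpoint sets averaged, making the centerline
exactly invariant under swapping the side labels (and hence under mirror
reflection). Side labels are arbitrary (no anatomical dorsal/ventral
identification); only cross-frame consistency matters.

The raw paired polyline carries pixel-scale jitter that a second-derivative
quantity like curvature amplifies catastrophically, so the pipeline applies
two light regularizations: two passes of endpoint-preserving 1-2-1
smoothing, then a cubic smoothing-spline refit (`splprep`, residual budget
0.5 px per point) re-evaluated at n points. At the body-wave scale
(wavelength ≈ body length) these are essentially transparent; at the noise
scale they are strongly attenuating. Both are exposed and can be set to 0.

Body length L is the summed Euclidean length of the centerline. Frames
whose centerline properly crosses itself between segments ≥ 15% of the
body apart are flagged coiled and skipped (sub-pixel micro-loops from the
pairing are not coils).

**Features.** Pharynx point: first centerline point at cumulative arc
length ≥ L/10 (the pharynx spans roughly the anterior tenth of an adult
worm). Curvature: Menger three-point curvature with sign from the cross
product of successive segments (positive = clockwise turning in image
coordinates, y down — any fixed convention works since downstream only
consumes sign changes), endpoints copying neighbors, then a centered moving
average over `smooth_window` = 5 points. Inflections: κ_i·κ_{i+1} < 0
records index i+1; a maximal run of exact zeros between opposite signs
counts once, at its midpoint. Peaks: argmax of |κ| per segment between
consecutive boundaries (head, inflections, tail), ties to the lower index;
segments shorter than `min_seg_pts` = 3 or identically flat yield none.
End segments do yield peaks — the dominant bend can sit near either end.
Error checking restores strict alternation: inflection pairs closer than
2% of L merge into the one with larger adjacent |κ|; peaks with |κ| <
0.25/L are dropped and their flanking inflections re-merged, iterating to a
fixed point. These thresholds have no published values; the defaults were
chosen to satisfy the synthetic-data invariants and are all in the config.
Bend angles α are the interior angle at each peak to its two flanking
boundaries; min α is the maximum bending amplitude.

**Counting.** d_max per frame is the signed extreme over peaks of the
perpendicular distance to the pharynx–tail chord, sign from the 2-D cross
product (tail − pharynx) × (peak − pharynx). (The two descriptions of which
rotational direction carries the plus sign contradict each other in the
source material; the cross-product convention is fixed and documented, and
the count depends only on sign changes.) Near-exact magnitude ties between
peaks resolve to the most anterior peak so the choice is stable under
floating-point-level perturbation. The counter scans maximal same-sign runs
of frames with |d_max| ≥ `min_amp_frac`·L_ref (default 0.03, L_ref = median
body length; invalid frames break runs); runs of at least `min_run` = 3
frames qualify; each qualifying run of sign opposite to the last counted
produces one event at the run's |d_max| maximum (earliest frame on ties).
The first qualifying run initializes the direction and counts as one bend
(`--count-first false` to exclude it). The amplitude floor is not part of
the published rule; without it, sub-pixel jitter on a near-straight worm
generates arbitrarily many sign flips. `--peak-scope post-pharynx`
restricts the distance to peaks posterior to the pharynx (the strict
anatomical reading); the default uses the global body maximum.

## The synthetic world

The generator emulates the acquisition the method targets: a ~1 mm adult
worm at ~4 µm/px and 20 fps. Defaults: body length 120 px, amplitude 9.6 px
(8% of body length), wavelength = one body length, 0.5 Hz undulation, 30 s,
200×200 frames, worm gray 60 on background 200, head region +30 gray,
Gaussian noise σ = 2. The midline is a traveling sine wave expressed in arc
length (lateral offset y(s,t) = A·sin(2πs/λ − 2πft), axial coordinate
integrated so total arc length equals the stated body length exactly),
re-centered each frame; an optional drift term translates the worm for
null-test videos. The body is the union of discs along the spine with a
tapered half-width profile (5% of body length mid-body, blunt ~2 px head
cap, sharp ~1 px tail cap, matching the ~5–7 px reported end widths); the
spine is inset by the cap radii so the rendered tip-to-tip extent equals
the stated body length.

Ground truth carries per-frame head/tail/midline and phase, plus an
expected bend count computed only from the analytic midline: the signed
peak distance of the analytic curve to its own pharynx–tail chord, run
through an independent, self-contained implementation of the same sign-run
counting rule. A partial half-period at the clip ends can shift the count
by one; this ±1 is stored as `count_tolerance` rather than hidden.

What the generator does **not** emulate: omega turns and coiling,
self-occlusion, realistic bacterial-lawn texture, illumination drift,
multi-worm scenes, and real optics (PSF blur). A green test establishes
that the geometry and counting logic are correct on clean single-worm
kinematics; it does not establish robustness to those real-world effects.

## Numerical behavior and limitations

- Median body-length recovery on synthetic videos is within ~1.5% of truth;
  individual frames can deviate up to ~2.5% depending on how the tips land
  on the pixel grid and on the small arc-length loss of the smoothing
  stages. d_max is insensitive to this since it is measured transversally.
- Mirror equivariance: reflecting the input video negates the d_max series
  to < 0.01 px and leaves the count identical, by construction (integer
  thresholding, origin-free sharpness, symmetrized pairing, anterior
  tie-breaking).
- Tracking is purely frame-to-frame; a segmentation dropout longer than a
  few frames during a fast turn could in principle swap identity. Invalid
  frames never interpolate the distance series — runs simply break,
  which is conservative for the count.
- Coiled postures are detected and skipped, not resolved; videos dominated
  by coiling will fail with a stage-labeled error once more than
  `max_invalid_frac` = 50% of frames are invalid.
- The DSNT layer is forward math plus loss/metric only; no network or
  training loop ships with the package. The coordinate-matrix convention is
  x_j = (2j − W − 1)/W (1-based, pixel centers), the JS regularizer target
  is an isotropic discretized Gaussian with σ = 1 heatmap cell, and PCK uses
  an inclusive radius (distance ≤ n counts as correct).
- The curvature estimator (Menger) and the sharpness scale (5% of
  perimeter) are package choices where the published description names no
  estimator; both are configurable.
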