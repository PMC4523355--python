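# Methods

This note documents the models, conventions and numerical choices behind
`vidtrack`, what the synthetic-data generator does and does not emulate,
and the known limitations of the approach.

## Segmentation model

Moving individuals are isolated by *dynamic difference imaging*: frame
*I_t* is subtracted from a reference frame a constant offset Δ later
(default Δ = 25 frames = 1 s at 25 fps) and the result thresholded.
Anything stationary over Δ — background texture, illumination gradients,
immobile debris, non-moving individuals — cancels exactly. This is the
right tool for dark-field recordings with heterogeneous backgrounds, where
plain intensity thresholding fails; its price is a systematic bias the
user must manage: immobile individuals are invisible, and an individual
overlapping its own (or another's) position Δ frames later is partially
eroded in the difference image.

Two subtraction modes exist:

* `signed` (default): `max(I_t − I_{t+Δ}, 0)`. For bright particles on a
  dark background, the position occupied at *t+Δ* subtracts to zero, so
  each moving individual appears exactly once per difference frame, at its
  time-*t* position. Detections therefore count individuals directly.
* `abs`: `|I_t − I_{t+Δ}|`. Both the current and the offset position
  appear ("ghost blobs"). Because a ghost trajectory is an exact
  time-shifted copy of the real one, it passes every downstream filter and
  doubles counts; this mode is kept for diagnostics and for thresholding
  studies, not for counting. This is why `signed` is the default: no
  downstream step can distinguish a ghost trajectory from a real one, so
  ghosts must not be created in the first place.

Threshold semantics are inclusive (pixel ≥ θ is foreground) and fixed so
results are bit-reproducible. θ and Δ have no universal values; they must
be validated per optical setup, and `check_threshold_values` renders
raw-vs-binarized panels for that purpose. An optional Gaussian pre-blur
(σ in px, default off) is available for very noisy video; the reference
behaviour is unfiltered.

## Morphometry conventions

Components are labelled with 8-connectivity and components touching the
frame border are kept — the viewing field is open, and discarding border
individuals would bias counts low. Size gating (`min_area`, `max_area`,
px²) happens at labelling time.

Descriptor formulas follow the de-facto particle-analysis standard:

* **Ellipse fit**: eigendecomposition of the second-order central moment
  matrix (with the +1/12 px² diagonal term for finite pixel extent); raw
  axes 4√λ are rescaled by a common factor so that the ellipse area
  π·a·b equals the component's pixel area. The minor axis is floored at
  1 px so single-pixel components stay finite. The orientation is reported
  in degrees in [0, 180), measured from the +x axis with y pointing up.
* **Perimeter**: Crofton formula with 4 directions. Raw boundary-chain
  lengths overestimate smooth outlines by ~5 % (a digitised r = 20 disk
  measures ~131 px against the true 125.7), which would push disk
  circularity to ~0.91; the Crofton estimate is accurate to ~1 % on disks
  and ellipses and handles degenerate components.
* **Shape indices**: circularity 4πA/P² and roundness 4A/(π·major²), both
  clamped to ≤ 1 (rasterisation can push tiny shapes above 1); solidity
  A / convex-hull-pixel area.
* **Gray statistics** are measured on the difference frame by default —
  the image actually analysed — with a `grey_source="raw"` switch.

Linear measures are converted to μm with the user-supplied scale; centroids
stay in pixels (origin top-left, x = column, y = row) because linking
operates in pixel space.

## Linking model

Linking is stage-wise optimal assignment on positions only. At each frame,
detections are matched to "active" tracks (last seen ≤ L frames ago,
default L = 5) by minimising total cost with
`scipy.optimize.linear_sum_assignment`, where

* a link spanning *g* frames is feasible if its displacement *d* satisfies
  d ≤ g·max_disp (linear gap allowance; `fixed` mode available), with
  max_disp = 20 px by default;
* a feasible link costs d²/g — the squared displacement per frame, so a
  bridged gap is paid for the way a diffusing particle would pay for it;
* leaving a track or a detection unmatched costs max_disp² each.

Under this cost model a link at moderate per-frame displacement always
beats leaving both of its ends unmatched, gap closing works throughout the
allowance actually exercised by the data (per-frame displacement up to
~max_disp·√(2/g)), and a track whose particle vanished (left the field,
was occluded) cannot outbid the rightful 1-frame-gap owner of a nearby
detection — a failure mode we observed with cost models that penalise
unmatched gapped tracks more heavily. Exact cost ties are broken toward
the older track by an additive ε = 1e-7 px², which makes the partition
invariant to input row order.

Occlusion handling is deliberately conservative: the losing trajectory
terminates and a new id starts afterwards; no recombination is attempted,
because any recombination rule would impose assumptions on movement that
bias the downstream behavioural statistics. By-frame counting (below)
makes abundance robust to these splits.

Movement metrics per consecutive detection pair: step length (μm),
absolute angle (radians, measured with y up), turning angle (wrapped
difference of successive absolute angles, defined from the second step
on), net squared displacement from the trajectory start (μm²), gross
cumulative path (μm). A zero-length step has no direction: its absolute
angle and any turning angle involving it are NaN rather than an arbitrary
zero. Output tables carry degree columns alongside the radian ones.

## Summaries, filter, counting

`summarize_trajectories` reduces each trajectory to one row: count span
and detection rate (detections / frames spanned, inclusive), duration
((last − first)/fps — gaps count as elapsed time), net and gross
displacement, step-length and turning statistics, mean speed
(gross/duration), and mean/median/SD/IQR of every morphology descriptor.
Variability is the sample SD (NaN below n = 2); the IQR is emitted
alongside as a robust alternative.

The quality filter keeps a trajectory iff net ≥ 50 μm AND duration ≥ 0.2 s
AND detection rate ≥ 0.8 AND median step > 2 μm. The three "at least"
criteria are inclusive, the step criterion strict; a negative step
threshold disables that criterion entirely (so the all-zero setting is the
identity). A 10-frame-span trajectory therefore needs ⌈0.8·10⌉ = 8
detections.

Abundance is computed by frame: count(t) = retained detections on frame t,
averaged over the frames that have a difference image (T − Δ frames).
Counting trajectories instead would double-count individuals whose track
was split by an occlusion.

## Synthetic-video generator

The generator renders what the segmentation/linking chain actually needs to
be tested against: bright ellipses (per-species Normal distributions of
major axis, aspect ratio, speed; truncated at physical bounds) moving as
correlated random walks (per-frame turning ~ wrapped Normal(0, σ_turn),
step ~ Normal(v/fps, σ_v/fps) truncated at 0, body oriented along the
heading), over a static low-frequency background gradient plus per-frame
Gaussian pixel noise, with immobile debris ellipses, Bernoulli per-frame
detection dropout, an open boundary (exit on centre crossing; optional
Poisson entries), and full per-frame ground truth (position, shape,
orientation, species, identity, visibility). One `numpy` Generator seeded
once drives all randomness, so a seed reproduces the frame stack bit for
bit.

Collision avoidance: a step that would bring two bodies closer than the
sum of their semi-major axes plus a margin (default 4 px) is retried at
±60°, ±120°, then 180°; if everything is blocked the individual waits one
frame. Sideways deflection matters: simple reversal produced ping-ponging
pairs whose tracks looked like fast-moving debris (high gross, near-zero
net displacement). Initial individuals are placed ≥ 64 px from the
boundary so the in-view population is not depleted in the first second;
entrants appear on the boundary.

Default study conditions (used by the validation suite) are three species
with major axes 8–14 μm, aspect ratios 1.2–2.5, speeds 110–160 μm/s and
turning SDs 0.06–0.08 rad/frame at 25 fps and 1 μm/px — small, fast,
persistent swimmers in the range of real ciliates. Speeds and persistence
are deliberately well clear of the quality-filter thresholds (a 50 μm net
displacement is covered in ~0.5 s of straight swimming), so on clean
synthetic video the filter separates movers from debris exactly; species
intensities are staggered (250/190/130) the way mixed communities differ
in brightness, which also limits cross-erosion when one individual's
difference blob overlaps another's reference-frame position.

What the generator does **not** emulate: optics (no point-spread function,
no depth of field, no focus drift), 3-D motion, cell division and death,
touching/clustered individuals, motion blur, and shape deformation while
swimming. Passing the synthetic validation therefore demonstrates the
correctness of the algorithmic chain under its stated assumptions — it
does not certify performance on any particular real optical setup, which
is exactly why threshold/overlay validation tools are part of the package.

## Species classification demo

`species_id` is a worked example, not a core feature: a scikit-learn
random forest (500 trees by default, out-of-bag scoring) trained on
trajectory summaries from labelled monocultures and applied to unlabelled
mixtures. Feature sets are `morphology` (mean/median/SD of each descriptor)
and `morphology+movement` (adding displacement, step, speed and turning
summaries). Out-of-bag confusion and per-class support are reported; class
imbalance is surfaced but not corrected — under-represented classes can be
absorbed by similar majority classes, a known forest failure mode, and the
interface accepts any custom feature list for users who want to swap in
other classifiers. Vote fractions accompany predictions so uncertain
assignments can be flagged.

## Numerical and degenerate-input choices

* Difference arithmetic in int16, clipped to [0, 255], output uint8.
* Masks compare with ≥ (inclusive threshold).
* 1-px components: minor axis floored at 1 px, perimeter floored at 1 px,
  shape indices clamped into (0, 1].
* Empty inputs propagate as empty outputs (no errors) everywhere except
  where a result would be meaningless (e.g. < 2 frames of video).
* Single-detection trajectories: duration 0, net 0, step statistics NaN;
  they fail the default filter.
* CSVs are written with pandas' default float formatting; identical inputs
  and config give byte-identical outputs (validated in the tests).

## Limitations

Tracking is 2-D; out-of-plane motion shortens apparent paths. Identity is
not maintained through occlusions (no fingerprinting), so behavioural
statistics are per-fragment, and very crowded scenes will fragment heavily.
Touching individuals are measured as one particle (no watershed
splitting). Slow individuals (displacement ≲ body length per offset) are
eroded or missed by difference segmentation — the offset must be chosen
against the slowest species of interest. AVI support depends on an
available imageio backend; PNG/TIFF sequences are the always-available,
bit-exact interchange format, and the proprietary `.cxd` microscopy format
is recognised but not decoded.
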