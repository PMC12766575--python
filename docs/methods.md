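# Methods

## The assay model

The package models a single fly in an oblong two-zone arena observed at a
fixed frame rate (default 15 fps) for a fixed session (default 900 s). A
single boundary on the long axis splits the arena into the region of
self-administration (ROSA) and the non-self-administration region (NoSA);
each end carries a port (stimulus delivery at the ROSA end, vacuum at the
NoSA end). Every analysis derives from three per-frame primitives:

* **region membership** — a point strictly past the boundary on the ROSA
  side is ROSA; everything else, including the boundary itself, is NoSA.
  Assigning the exact boundary to NoSA is the conservative convention for
  a stimulus that must not trigger on an ambiguous frame; the opposite
  convention is available (`boundary_is_rosa`).
* **depth** — signed penetration along the long axis from the boundary
  toward a region's port: positive inside the region, zero on the
  boundary. Depth is axis-penetration rather than Euclidean distance to
  the port pixel: in an oblong arena it is monotone in port proximity
  while insensitive to lateral wobble, and it makes depth antisymmetric
  between the regions. Euclidean port distance is exposed separately
  (`port_distance`) for users who want the literal measure.
* **step length** — Euclidean displacement between consecutive frames,
  attributed to the *destination* frame, so the step that crosses the
  boundary belongs to the bout it opens and binned distances sum exactly
  to session totals.

Coordinates follow image conventions (origin top-left, x along the long
axis, y down); all intervals are half-open `[start, end)`; frame indexing
is 0-based. Arena dimensions, ports and the pixels-per-unit calibration
are config inputs; the built-in defaults (10 × 2 units, boundary at
mid-length) are placeholders for tests, not measurements.

## Trajectory hygiene

Acquisition CSVs (columns `frame, x, y[, occupation]`; names remappable
via a schema) are read into a contiguous frame stream: unparseable rows
and index gaps become flagged invalid frames. `repair_gaps` fills runs of
at most `max_gap_frames` invalid frames by holding the last valid
position (flagged *imputed*); the default of 15 frames (1 s at 15 fps)
keeps brief occlusions from fragmenting bouts without fabricating
behavior across long losses. Imputed frames contribute occupancy time
(the fly is somewhere, and its last known region is the best estimate)
but never distance: any step touching an unobserved frame counts 0.
A stored occupation-score column is never trusted — occupancy is always
recomputed from geometry, and a ≥ 1% disagreement with the stored column
raises a warning, keeping the hardware ROI auditable against the
analysis ROI.

Undefined quantities (means over zero bouts, indices with zero
denominators) propagate as missing values, never as zeros, so they cannot
deflate group averages.

## Indices

* PI is computed over the last seven minutes (`[480 s, 900 s)`) by
  default, for both terms; it equals `2·(window occupancy) − 1`, an
  identity the tests exploit.
* The operant learning index compares a metric "at 14 min" vs "at 1 min".
  These are read as the 1-min bins `[780, 840)` and `[0, 60)`: the
  underlying metrics (time, distance per bin) are extensive, so
  instantaneous readings would be ill-defined. Per-bin depth is the
  maximum over the bin, clipped at 0 (consistent with the session-level
  "maximum depth"), with a mean-based option.
* A fly already in ROSA at frame 0 starts a bout at t = 0 and counts as
  an entry; a residence still in progress at session end counts toward
  bout number and duration (the stimulus was experienced) but is excluded
  from latency, whose successor is undefined.
* In the T-maze, deaths are subtracted from their recorded arm when
  known; unattributed deaths are subtracted from the non-participating
  (DNP) pool, which leaves the CPI unchanged — the conservative reading
  of "subtracted from the final results". Trials with participation
  ≤ 0.5 (inclusive) are excluded.
* PCA standardizes each metric to z-scores (sample SD, n − 1) and
  eigendecomposes the resulting correlation structure. The retention rule
  "explains variance for more than one variable" is operationalized as
  the Kaiser criterion (eigenvalue > 1), recorded in the result object;
  component signs are fixed so the largest-magnitude loading is positive.

## The simulator

Synthetic sessions come from a **residence-time-driven semi-Markov
process**: the fly alternates ROSA and NoSA residences with durations
drawn independently (exponential by default; gamma available for
non-memoryless latency behavior). The long-run occupancy fraction is then
`E[bout] / (E[bout] + E[away])`, and bout/latency distributions are known
in closed form — which is exactly what parameter-recovery tests need. The
alternative (letting crossings emerge from a spatial walk) would couple
bout statistics to movement parameters and make them uncontrollable.

Within each residence the position follows a correlated random walk:
per-frame speeds are normal (mean 0.5, SD 0.25 units/s, truncated at 0 — a
typical walking fly covers a few mm/s), headings accumulate von Mises
increments (concentration 4), and `port_drift` ∈ [−1, 1] nudges the
heading toward (positive) or away from (negative) the active region's
port, shaping the depth metric without touching the bout law. Walls
reflect; a zone transition teleports the walk one step across the
boundary. A `boundary_margin` (default 0.05 units) keeps positions
strictly off the boundary so the generated trajectory re-derives the
ground-truth occupancy exactly. With zero speed no transition is
physically possible, so the session degenerates to a single truncated
residence in the starting zone. The starting zone is drawn from the
stationary probability by default. All randomness flows from one seed;
identical parameters and seed give bit-identical sessions.

**Valence presets** encode the qualitative appetitive/aversive contrast
observed in such assays — appetitive stimuli elicit fewer but longer
visits with shorter latencies to re-enter and deeper port approach;
aversive stimuli the reverse:

| preset     | mean bout | mean away | port drift | expected occupancy |
|------------|-----------|-----------|------------|--------------------|
| appetitive | 20 s      | 6 s       | +0.5       | ≈ 0.77             |
| aversive   | 6 s       | 14 s      | −0.5       | ≈ 0.30             |
| neutral    | 10 s      | 10 s      | 0          | 0.50               |

These values are fixed generative conditions chosen to yield roughly
35 vs 45 bouts per 15-min session and clearly separated preference
indices; tests assert the directions they construct.

What the simulator does **not** emulate: odor-plume physics, thigmotaxis
and wall-following, grooming pauses, sex or genotype differences,
tracking artifacts other than additive pixel noise, and any within-session
learning — residence parameters are stationary, so operant-learning
indices on synthetic flies scatter around 0. Passing tests therefore
demonstrate the *correctness of the measurement pipeline*, not that real
flies behave like the model.

## Rendering and tracking

`render_frames` draws each frame as a uniform light background (level
180) with a dark Gaussian-profile blob (amplitude 120, SD 3 px by
default) at the fly's pixel position plus i.i.d. Gaussian noise. The
tracker estimates a per-pixel median background over 25 evenly spaced
frames (robust: a moving animal darkens any one pixel in fewer than half
the samples), thresholds the absolute difference image with Otsu's method
floored at 10 gray levels, keeps the largest connected component of at
least 4 px, and returns its intensity-weighted centroid. One animal per
arena is assumed; no identity tracking. Frames without a blob become
invalid trajectory frames for the standard repair path. Sub-pixel
behavior: the thresholded weighted centroid carries a quantization bias
of ~0.2 px, and mild noise can *dither* that bias away, so tracking error
is monotone in noise only above the sub-pixel floor — the property tests
allow 0.05 px of slack accordingly.

## Numerical and scale choices

* Bout segmentation is vectorized run-length encoding; tests compare it
  against an independent `itertools.groupby` oracle on 1,000 random
  series at full session length (13,500 frames).
* Monte-Carlo checks use 3-standard-error tolerances: 300 sessions per
  condition for parameter recovery and valence contrast, 200 random plus
  600 simulated sessions for the conservation suite.
* Tracking validation renders 50 sessions at a reduced 5 fps / 180 s
  (900 frames each), preserving the per-frame geometry while keeping the
  rendered volume proportionate; the blob is kept ≥ 2σ from the boundary
  (margin 0.7 units) so occupancy disagreements isolate tracker error
  rather than boundary ambiguity.
* PCA agreement with a brute-force correlation-matrix eigendecomposition
  is asserted to 1e-8; metrics-table round-trips to 1e-9.

## Known limitations

* The original acquisition stack's tracker is unspecified upstream; this
  tracker is a standard background-subtraction design, with no claim of
  bit-equivalence to any particular implementation.
* Group-level inference (ANOVA, mixed models, post-hoc corrections) is
  out of scope; the package stops at per-fly metrics and descriptive
  summaries.
* `heatmap_matrix` requires homogeneous sessions unless explicitly asked
  to truncate; no resampling across frame rates is attempted.
* The gap-repair policy (hold last position, ≤ 1 s) is a package choice;
  acquisition systems that drop frames differently may warrant other
  settings.
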