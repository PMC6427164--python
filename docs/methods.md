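# Methods

This note records the models, defaults and numerical choices behind
`fintrack`, and what the synthetic-data tests do and do not establish
about real recordings.

## Detection

A clip's background reference is the **per-pixel median** across all
frames. The median is exact whenever each pixel is fish-covered in
fewer than half the frames — true for freely swimming fish in clips of
any realistic length — and requires no background-only footage.
Detection then computes the absolute difference `|frame − reference|`
(absolute, so dark-on-light and light-on-dark polarity are equivalent),
optionally applies a 3×3 median filter against salt-and-pepper noise,
binarizes at `diff_threshold` (default 30 intensity units, on the 0–255
scale), labels 8-connected components, and discards blobs below
`min_area` (default 20 px). Centroids are unweighted means of member
pixel coordinates (x rightward, y downward, pixel centers at integers),
and detections are sorted by (y, x) for determinism. Threshold,
minimum area, connectivity and the filter flag are all exposed because
sensor noise and fish size vary between setups. Cropping to the tank
window (e.g. 640×480 → 380×380) defaults to the centered window.

Out of scope by design: adaptive or mixture background models, shadow
removal and illumination correction — the intended recordings control
lighting physically.

## Tracking

Frame-to-frame identity mapping minimizes the **total Euclidean
distance** between previous track positions and current detections over
all injective matchings of maximal size, with every matched pair within
a gate (default 50 px, an order of magnitude above typical per-frame
fish displacements of 1–4 px). The matching is solved with the
Hungarian algorithm on a cost matrix in which out-of-gate pairs carry a
penalty larger than any feasible total cost (so matching size dominates,
then cost), plus a perturbation of 1e-9·(track·m + detection) that
resolves exact ties toward the lexicographically smallest mapping. A
greedy per-track nearest-neighbor mode exists behind a flag for
comparison; the optimal matching is the default because it is
deterministic and directly checkable against exhaustive enumeration.

Unmatched tracks **coast**: they hold their last position, flagged
unobserved, contributing zero distance to path length. This keeps one
position per track per frame, so velocity sums and heatmaps stay well
defined through detection dropouts. Tracks initialize at the first
frame with at least `n_fish` detections and are backfilled as coasted
before it; matches beyond 80% of the gate are logged as swap suspects.
No Kalman prediction, appearance model, or multi-frame occlusion
reasoning is attempted.

## Velocity

Total path length is the sum of consecutive-frame Euclidean distances.
Two normalizations are reported side by side: **pixel/frame**, distance
divided by `n_c − 1` transitions (the natural denominator for a sum
over `i = 2..n_c`, and the unit of the packaged per-clip table), and
**pixel/s**, distance divided by the clip duration (default 300 s,
i.e. 5-minute clips). The recordings the packaged table derives from do
not state a frame rate, so the two units cannot be interconverted for
that table; both are carried explicitly rather than guessing a rate.
Group tables list each group's clip velocities sorted ascending with a
trailing arithmetic mean, so row pairing is by velocity rank — the
layout of the published table the package reproduces.

## Spatial occupancy

Heatmaps count positions into square bins (`floor(coordinate /
bin_size)`); counts always sum to the number of recorded positions, and
coasted positions can be excluded. Field zones are **configuration,
not physics**: named annuli with optional field-strength labels in mT,
because magnet field geometry is measured, not modeled, in the intended
use. A bin belongs to the zone containing its center point
(deterministic, traversal-order independent; annuli are half-open,
`r_inner ≤ d < r_outer`); overlapping zones are reported and resolved
toward the first listed. Fractions over zones plus the implicit
outside zone form a probability vector.

## Group statistics

The paired t-test uses the sample standard deviation of within-pair
differences (`ddof = 1`) and two-tailed Student-t tail probabilities
(scipy). Degenerate inputs are explicit: all-zero differences give
t = 0, p = 1; identical nonzero differences give infinite t and p = 0
with a `DegenerateVarianceWarning`. Percent difference is
`100·(reference − other)/reference`, reported unrounded and rounded to
one decimal for display. The equivalent regression formulation
(t = coefficient / standard error) is not built separately.

## Embryo endpoints

Hatchability is `100·hatched/total` per dish, one decimal, with embryos
unhatched by the abandonment day (default 20) counted as unhatched;
mean days to hatch averages hatched embryos only. The abnormality rate
is the percentage of embryos flagged with any of the six observed
morphological features. Stage-curve comparison runs the paired t-test
on day-matched mean stages of two groups.

**Calibration caveat.** Under the null (two cohorts from the same
generator configuration) the stage-curve p-values are close to, but not
exactly, uniform: an embryo that runs ahead or behind schedule on one
day stays so on later days, so day-wise differences are positively
serially correlated and the test is mildly anti-conservative (measured
null rejection ≈ 0.12 at α = 0.05 over 1000 replicate pairs; KS
distance from uniform ≈ 0.14). This is a property of applying a paired
t-test to serially correlated daily means — the standard field practice
the package implements — not of the implementation; p-values near the
threshold should be read accordingly.

## Synthetic data

The tank generator is the study-condition stand-in for webcam
recordings: 380×380 frames (the analyzed crop size), 300-frame clips,
1–several fish as hard-edged dark ellipses (semi-axes 7×4 px, intensity
40 on background 200) over additive Gaussian sensor noise (σ = 2 by
default). Motion is a first-order autoregressive velocity model
(`v ← 0.8·v + η + bias`, η isotropic with per-frame scale 1.5 px) —
smooth, fish-like paths giving the tracker realistic ambiguity — with
specular wall reflection and an optional constant-magnitude drift
toward the tank center emulating the center-dwelling preference seen
under field exposure. Trajectory randomness is consumed before
rendering noise, so ground truth depends only on the seed and motion
parameters. Rendering is deliberately not anti-aliased so blob areas
are exactly countable by pixel oracles. A constant-speed trajectory
helper supports velocity-estimator calibration; on wall-bounce frames
the straight-line chord is slightly shorter than the distance traveled.

The embryo generator follows the standard medaka schedule (day 0 stage
14 … day 15 stage 40; intermediate days take the nearest lower listed
stage) with per-day rounded Gaussian stage noise (σ = 1 stage), a
running-maximum monotonicity clamp, Bernoulli abnormality
(default 2/75) and hatch failure (default 0.05), and Gaussian hatch
days (15 ± 1.5 d) never earlier than the day the series reaches stage
40; unhatched embryos never reach stage 40. Noisy stages are not
re-snapped to the discrete stage ladder: re-snapping would collapse
small noise to zero variance and make day-to-day variation degenerate.

What the generator does **not** emulate: fish body articulation and
shape change, water-surface optics and reflections, illumination drift,
occlusions between fish bodies (only path crossings), clutch effects or
dish-level correlation in embryo outcomes. Passing tests therefore
establish algorithmic correctness under controlled conditions — exact
identity preservation for well-separated fish, sub-pixel centroid
accuracy for clean ellipses — not robustness to those real-world
effects.

## Problem sizes and tolerances

Tests and the acceptance script run at the sizes the checks are stated
for: 300-frame clips at 380×380 for tracking and velocity recovery
(errors ≤ 1 px / 5% with margin to spare: measured ≈ 0.25 px and
≤ 0.5%), 1000 random instances up to 4×4 for assignment-vs-enumeration,
10 000 replicates for type-I calibration of the t-test (3 binomial
standard errors around α), quadrature agreement of t tail probabilities
to 1e-8 for df 1–30, and 10 000 seeded cohorts for the binomial
abnormality check. The packaged velocity and hatch tables are
transcribed verbatim; the hatch table's one internally inconsistent row
(dish 5: 14/15 hatched printed as 100%) is preserved as printed and
flagged by `datasets.hatch_table_consistency`.
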