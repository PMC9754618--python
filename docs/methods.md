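# Methods

## Data model

The analysis unit is the *fixation*: a position (x, y) in pixel
coordinates on one of eight reference images (photographs of the
sculpture at 45° steps), an onset and a duration in ms.  Coordinates
use the screen convention — origin at the image's top-left, y
increasing downward.  All invariants (positive durations, reference
image in 1–8, non-decreasing onsets, consecutive ordinals per
participant and sculpture) are enforced at the I/O boundary and assumed
downstream.  The mapping of reference-image index to viewing angle is
metadata only; no computation depends on it.

*Inspection time* is the elapsed time from the onset of the first
fixation to the end of the last fixation on a sculpture.  A
sum-of-durations alternative is available (`inspection="sum"`) because
the elapsed-time reading is a modelling choice, not a logical
necessity; all defaults use the elapsed span.

## Expertise classification

Years of sculpting experience map to four levels: 0 years → layperson,
(0, 5) → novice, [5, 10] → semi-expert, > 10 → expert.  The published
thresholds ("<5", ">5<10", ">10") leave exactly 5 and exactly 10 years
unassigned; we assign both boundaries to the semi-expert band, which
contains the observed semi-expert range (6–9 years) and respects the
strict ">10" for experts.  Both cut points are configurable
(`novice_max`, `semi_expert_max`).  Pairwise *divergence* is the
absolute level difference; with four groups of g participants, the
divergence groups hold 4·g(g−1)/2 and (4−d)·g² pairs (d = 1, 2, 3) —
40/75/50/25 for g = 5.

## Global/local viewing

A fixation is *local* iff its duration strictly exceeds the threshold
(default 187 ms; exactly-threshold durations are global).  The
threshold can be recomputed as the cohort's mean fixation duration
(`threshold="cohort_mean"`), which is how the default value arises on
real data.  The global/local ratio is the count ratio n_global/n_local;
it is undefined (NaN, warned, excluded from group means) when a
participant has no local fixation — deliberately not coerced to a
number, since such participants distorted threshold choices in earlier
two-dimensional work.  The switching rate divides label transitions
between consecutive fixations by inspection time in seconds.  Group
summaries report the sample mean and sample SD (n−1); with equal group
sizes the cohort "total" equals the unweighted mean of the level
means, an identity the tests exploit.

## Scanpath distance

Two scanpaths are compared in a 3-D space: (x, y, z) with
z = duration × c.  The conversion factor c is computed cohort-wide per
sculpture as sculpture height (px) / longest fixation (ms), so the
duration axis's largest expansion equals the y axis's; published
per-sculpture factors can be supplied as overrides.  The sculpture
height in px is an input (the bounding-box height of the silhouette on
the reference images); it is not derivable from fixation data.

The distance itself is the double-mapping form: every fixation of S is
matched to its nearest fixation of T and vice versa; the summed pair
distances are divided by max(|S|, |T|).  Both directions are included
so that no fixation is ignored when the two viewers differ in fixation
count, and the normalisation keeps the measure comparable across
counts.  Nearest-neighbour search is exact (full pairwise distance
matrix via `scipy.spatial.distance.cdist`); ties resolve to the lower
ordinal, which cannot change the distance but keeps mapping traces
deterministic.

Because fixations are spread over eight reference images, the distance
is evaluated per image and averaged over the images on which *both*
participants have at least one fixation.  Images fixated by only one
participant are skipped (and counted in the warning stream) rather
than imputed with a penalty: the per-image mean is a similarity
summary over computable comparisons, and any penalty constant would be
arbitrary.  If two participants share no image the pair is undefined
(NaN) and excluded, with a warning, from the divergence pooling.  The
divergence summary pools raw off-diagonal pair distances (the zero
diagonal — self-comparison — is excluded); with equal cell sizes this
coincides with averaging per-cell means.

## Basic-feature (AOI) metrics

Basic features are polygons per reference image sharing one feature
identity across perspectives (the cross-view correspondence is input,
as produced by manual expert mapping).  Hit testing is
boundary-inclusive (`shapely` `covers`); overlapping polygons resolve
to the smallest area, then lexicographic feature id.  A fixation on an
image without polygons hits nothing.

Metrics per participant and sculpture: distinct features fixated;
percentage of fixations on any feature; revisits per minute.  A
*revisit* is a re-entry into a feature after at least one fixation
outside it following a prior visit; "outside" includes fixations
inside another feature, so the sequence A, B, A, B contains two
revisits.  Operationally, revisits of a feature = (number of maximal
runs of consecutive hits of that feature) − 1, which the tests verify
against an independent state machine over all short sequences.
Revisits are summed across features and normalised by the same
per-sculpture inspection time as the switching rate.  Dwell time per
feature is deliberately not reported (the hit sequence makes it a
one-line extension).

## Synthetic cohort generator

The generator emulates the study design: four expertise groups of five
participants, two sculptures ("moses", small and abstract; "daphne",
tall and detailed) seen from eight perspectives.  What it models:

* **Durations** — a two-component lognormal mixture (right-skewed, the
  standard shape for fixation durations): global mode median 100 ms
  (σ = 0.30), local mode median 400 ms (σ = 0.35).  Medians sit well
  clear of the 187 ms threshold so label leakage is small but nonzero.
* **Mode sequence** — a two-state Markov chain: keep the current mode
  with probability `switch_persistence` (0.75), otherwise resample it
  as local with probability `p_local` (0.33).  This parameterisation
  makes the stationary local share exactly `p_local` while persistence
  1.0 freezes the mode; a symmetric-persistence chain could not honor
  an asymmetric marginal.  The implied expectations — global/local
  ratio ≈ 1.96, switch rate ≈ 0.52 Hz, mean duration ≈ 210 ms — sit at
  the magnitudes real sculpture-viewing cohorts produce.
* **Positions** — per fixation, a reference image uniform on 1–8; with
  probability `aoi_attraction` (0.05) the fixation lands uniformly
  inside a basic feature (with probability `revisit_bias` = 0.3 a
  previously visited one), otherwise it scatters with Gaussian jitter
  (σ = 70 px) around the group's gaze centre.  Gaze centres are offset
  60 px per expertise level, so pairwise scanpath distance grows with
  divergence — the structural analogue of the expertise effect the
  distance measure is meant to detect.  AOIs are axis-aligned
  rectangles (6% of each image dimension) whose centres drift slightly
  between reference images.
* **Timing** — onsets are cumulative (duration + exponential
  inter-fixation gap, mean 50 ms); fixation counts are Poisson with
  mean `n_fix` (120 per sculpture by default, ≈ 30 s of viewing).
* **Metadata** — years of experience uniform within the level's
  observed band (0; 0.25–4.5; 6–9; 14–29), so classification recovers
  the generating level exactly.

Randomness is keyed by (seed, participant index, sculpture index)
through `numpy.random.default_rng` sequence seeds, so adding
participants or sculptures never perturbs existing data.

What the generator does **not** model: head movement and mapping
error, tracker noise or data loss, saccades (a 30 Hz mobile tracker
cannot resolve them, which is also why no saccade-amplitude-based
ambient/focal classifier is offered), systematic walking order around
the sculpture (reference images are sampled independently), or
duration differences between expertise groups.  Passing tests on
synthetic cohorts therefore demonstrate correctness of the *pipeline's
computations* and its sensitivity to built-in spatial separation — not
that real expertise groups differ.

### Closed-form expectations

`expected_metrics` returns each group's analytic global/local ratio
(1 − p_ℓ)/p_ℓ with p_ℓ = p·a + (1−p)·b, where a and b are the
lognormal tail probabilities above the threshold in the local and
global modes (threshold leakage), and the expected switch rate from
the chain's transition matrix combined with the per-mode label
probabilities, divided by the mean step time.  Parameter-recovery
checks compare group ratios *pooled over fixation counts* (and both
sculptures) rather than means of per-participant ratios: the latter
carry an upward Jensen bias of order (1 + CV²) that the pooled
estimator avoids.

## Numerical and formatting choices

* Printed tables use round-half-up at the printed precision (two
  decimals for ratios/Hz/percentages, integers for distances).
* Distance computations are exact enumeration; oracle comparisons in
  the tests use 1e-9 relative tolerance.
* Degenerate cases are flagged, never silent: empty scanpaths,
  undefined ratios, single-member groups (SD reported as 0 with a
  degeneracy flag), unshared reference images, missing matrix cells.
* The pipeline records every warning and design toggle in
  `manifest.json` so runs are auditable; outputs are deterministic
  functions of inputs.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
cohorts chosen at sizes that exercise every code path while keeping
the whole suite near interactive speed: oracle equivalence up to 50
fixations per path, point-in-polygon checks at 1,000 points per
polygon, exhaustive revisit enumeration for sequences up to length 6
over two features, parameter recovery at 20 participants per group and
200 fixations per sculpture, and divergence-ordering checks at the
study's own 4 × 5 design with 60 fixations per sculpture.

## Known limitations

* The distance is computed between participants only; no per-subject
  summary statistic exists by construction, so group comparisons go
  through divergence pooling.
* Cross-sculpture distances, dynamic-time-warping or
  MultiMatch/ScanMatch alternatives, and mesh-based (true 3-D surface)
  mapping are out of scope; fixations live on 2-D reference images.
* No inferential statistics are produced — the intended use is
  descriptive comparison, mirroring small-N exploratory designs.
* Fixations outside the sculpture silhouette are retained; the input
  is trusted to contain exactly the fixations to analyse.
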