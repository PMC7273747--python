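# Methods

This note documents the measurement model implemented by `posturokit`,
the choices made where the underlying device conventions are
under-specified, and what the synthetic validation does and does not
establish.

## Recording model

A session is a stack of frames from a rectangular grid of force sensors,
each reporting grams. Defaults: 45 × 45 sensors (2025, matching a
~2,000-sensor plate) with 25/45 ≈ 0.556 cm pitch on a 25 × 25 cm floor,
30 Hz, 300 s. Sensor (row, col) is centred at
`origin + (col·pitch_x, row·pitch_y)` with the origin half a pitch in
from the plate corner; all downstream coordinates use this convention.
Units are seconds, grams and centimetres throughout. The on-disk dialect
(long-format CSV of non-zero cells + JSON sidecar) stores floats as
shortest round-tripping decimals and timestamps as hex floats, so save →
load is bit-exact.

## Contact detection and tracking

A body part is detected per frame as a connected component (8-connected
by default; configurable) of strictly positive sensors that (i) spans at
least 2 sensors, (ii) has a maximum-weight ("central") sensor of at least
0.7 g, and (iii) has a sensor adjacent to the central one reporting at
least 0.3 g. "Central" is read as the component's maximum-weight sensor —
the most conservative per-blob interpretation of the device's rule. Blob
weight is the sum of member sensors; its position is the weight-weighted
mean of member-sensor centres.

Blobs are linked frame-to-frame by optimal assignment on centroid
distance, gated at 1.5 cm; a track missing for more than 3 frames is
closed. A stepping paw travels 3–5 cm per step, beyond the gate, so
locomotion naturally yields one short track per stance; step series are
therefore pooled over all tracks sharing a paw label.

With an isotropic Gaussian footprint on this grid the detection rules
imply a minimum detectable load: a contact centred on a sensor-cell
corner splits across four equidistant sensors (≤ 0.25 of the load each),
so the 0.7 g central rule requires ≈ 3 g; a cell-centred contact caps the
best adjacent sensor at 0.125 of the load, so the 0.3 g rule requires
≈ 2.4 g. Loads of 5 g and above are detected at any sub-pixel placement;
the simulator's contacts are ≥ 10 g.

### Paw labelling

The reference workflow has an operator label each contact zone from
video. The package accepts such labels as a hint file (`zone_id,label`)
and otherwise labels automatically: per frame, the body centre is the
*unweighted* mean of the grounded centroids (exactly the body centre for
a diagonal stance couplet, and — unlike a load-weighted mean — immune to
weight shifts), and the heading is a short centred chord (±0.2 s) of the
body-centre path, accepted only when both half-chords exceed 0.5 cm and
point the same way; otherwise the last heading is kept. This guard
matters: at walk-to-stop transitions the centre moves by a fraction of a
step in an arbitrary direction, and an unguarded chord there can flip the
heading for an entire stationary bout. Each grounded zone then votes,
weighted by its contact weight, for the quadrant it occupies
(front/rear × left/right); zones lying inside the hull of the other
grounded zones (the abdomen) are excluded from paw candidacy. A track's
label is its strongest vote; two time-overlapping tracks never share a
paw label (the stronger vote wins, the weaker falls through to its next
choice or OTHER).

## Static/dynamic segmentation (700 ms rule)

The device convention is that the animal is static when every area in
contact with the sensors is stationary for at least 700 ms. Per zone
track, each pair of consecutive grounded samples is flagged stationary
when the centroid moved at most one sensor pitch (0.556 cm — the grid's
natural noise floor; ties count as stationary). A maximal run of k
flagged pairs spans k + 1 frames including the anchor frame the first
displacement is measured from; the zone is *settled* at those frames iff
the span is ≥ 700 ms. At 30 Hz a bout of 21 identical positions
(20 zero displacements + anchor) is exactly long enough; 20 frames are
not. A frame is provisionally static iff at least one zone is grounded
and every grounded zone is settled; maximal provisional runs ≥ 700 ms
become STATIC segments, everything else (including contact-free frames)
is DYNAMIC. The per-zone span requirement is essential: a run-length test
applied only to the whole-animal conjunction would classify steady gait
as static, because each mid-stance paw is instantaneously stationary and
landings are new contacts.

Episodes that are STATIC with all four paws grounded ("static-quadruped
episodes", ≥ 2 frames) are the substrate of the postural measures.

## Biomarkers

**Lateral weight distribution.** Per qualifying frame (requested mobility
state, paw-borne weight > 0): left share = (FLw + RLw)/ΣW, ungrounded
paws contributing 0 g. The session value is the unweighted mean over
frames × 100; at fixed sampling rate this equals a time average.

**Abdomen-support time.** Frames where an OTHER zone is grounded and its
centroid lies inside the convex hull of the four paw centroids (boundary
inclusive; the hull is used rather than the possibly self-intersecting
quadrilateral because it is well defined for any corner ordering). Frames
with fewer than four grounded paws are skipped. Counts are split by
mobility state and divided by the rate.

**Circling.** For each front paw, stance bouts are reduced to one mean
position each; bouts longer than 500 ms are excluded and break the
series (the filter that separates fast circling from thigmotaxis — the
spatial paths are identical, only the support tempo differs). Successive
step positions are converted to polar angles about the arena centre
(configurable origin); increments are wrapped to (−180°, 180°] and
accumulated with carry: each +360° crossing is one left lap (−360° one
right lap), with the remainder kept, so 720° counts two laps. The
accumulator resets at series breaks. Because the within-run sum
telescopes to the net angle of the endpoints, position noise does not
accumulate along a run. A 10⁻⁹-degree tolerance at the crossing keeps
exactly-360° step sequences from losing a lap to float rounding. Session
counts are the mean over FL and FR (possibly half-integral); an absent or
step-less front paw contributes 0.

**Support surface.** Convex-hull area of the four paw positions
(degenerate layouts give 0), evaluated per static-quadruped frame; the
session reports the maximum, which indexes transient instability better
than a mean.

**Barycenter, sway, speed, SFA.** The barycenter is the exact weighted
mean of the four paw positions (no smoothing) at each static-quadruped
frame; by construction it lies inside the paw hull. Body sway is the
area of the ellipse containing 90% of the barycenter cloud: the 10% of
points with the largest Mahalanobis distance from the initial mean/
covariance are eliminated (suppressing excursions from quasi-voluntary
movements), the mean and covariance are refitted on the retained points,
and the refitted covariance is divided by the bivariate-normal
90%-truncation consistency factor
F<sub>χ²(4)</sub>(χ²₂⁻¹(0.90))/0.90 ≈ 0.7442 — the standard correction
used by trimmed covariance estimators (e.g. MCD). The ellipse is then
the c = χ²₀.₉₀,₂ ≈ 4.6052 level set, area π·c·√det Σ. Without the
correction the trimmed fit underestimates Gaussian sway by a factor
0.744 and the ellipse does not cover 90% of the distribution; with it,
both the closed-form area and the 90% Monte-Carlo coverage hold (the
test suite checks both, across anisotropy ratios 1–10). `trim=0` gives
the plain, untrimmed 90% ellipse. At least 10 samples are required;
collinear clouds return area 0 with a warning.

Barycenter speed is path length divided by trace duration, per episode;
episodes are never concatenated (no phantom jumps). Session sway and
speed are duration-weighted means over episodes (episodes too short for
a quantity are excluded from that mean), and SFA = speed/area is the
ratio of the session aggregates, not the mean of per-episode ratios —
robust to short episodes with near-zero area.

**Normalisation and scores.** Postural biomarkers are normalised per
animal by the pre-operative value (ratio; the pre-op session is 1 by
construction). A zero baseline (e.g. abdomen time, typically 0 pre-op)
makes the ratio undefined: the series is kept absolute and flagged. The
qualitative scale is the cumulative sum of observed-symptom weights
(tumbling 5, retropulsion 4, circling 3, bobbing 2, head-tilt 1; range
0–15). Pearson r between quantitative and qualitative series uses the
two-sided t test with n − 2 df; the correlation table defaults to the
lesioned group only, with pooling as an option. Group-level inference
(RM-ANOVA, post-hoc tests) is deliberately left to standard statistics
packages; the module exports tidy per-animal tables for that purpose.

## Synthetic sessions and ground truth

The simulator emulates the study conditions so that every stage can be
validated blind:

- **Gait**: diagonal couplets (FL+RR alternating with FR+RL), 600 ms
  stances, 100 ms swings, 5 cm steps, along a slow loop 6 cm from the
  arena centre. The 600 ms supports sit above the 500 ms circling filter,
  so ordinary locomotion accrues no laps and doubles as a built-in
  thigmotaxis control; a dedicated `thigmotaxis` preset walks a circling
  arc with 800 ms supports.
- **Stationary bouts**: all four paws planted at the body's anchor
  points; paw *loads* (not positions) oscillate gently (two
  incommensurate sinusoids, ≈ 4% of the lateral split, plus 0.5 g load
  noise), which moves the barycenter ~1–3 mm — realistic quiet-stance
  sway without violating the stationarity of the contacts.
- **Weight asymmetry**: target left fractions are imposed exactly per
  frame (left paws share f·W, right paws (1−f)·W), separately for static
  and dynamic states, so the scheduled laterality is ground truth by
  construction.
- **Circling**: fast steps (250 ms stances) around a 3 cm orbit of the
  arena centre; each paw's step positions lie on a circle about the
  origin, so each of the 8 steps per lap advances the polar angle by
  exactly 45°. Episodes carry two extra steps of margin and are bracketed
  by 1 s holds, which break the step series cleanly on both sides. The
  orbit entry angle continues the walking heading, keeping the labelling
  heuristic's heading estimate valid through the transition.
- **Abdomen**: a broad (σ = 0.8 cm) 40 g blob at the body centre —
  inside the paw hull by construction — during scheduled intervals.
- **Rendering**: each contact becomes a truncated (2σ) Gaussian footprint
  (σ = 0.4 cm for paws), normalised to integrate exactly to its load, on
  a window of at least 3 × 3 sensors (so sub-pixel footprints still
  activate ≥ 2 sensors); Gaussian sensor noise (σ = 0.05 g) is added to
  active sensors and clipped at zero. Body weight defaults to 400 g (an
  adult rat).

Ground truth carries both the *scheduled* quantities (bout spans, lap
counts, target fractions — exact by construction) and *derived*
quantities obtained by applying the rule definitions to the noise-free
trajectories. All randomness derives from a single seed; identical seeds
give bit-identical sessions.

**What passing these tests shows — and what it does not.** Recovery of
scheduled laterality (±2 points), exact lap counts, abdomen time to one
frame per bout and static boundaries to one frame demonstrates that the
measurement chain (rendering → detection → tracking → labelling →
segmentation → biomarkers) is self-consistent and unbiased under the
modelled conditions. The simulator does not model limb dynamics, paw-
shape variation, partial footfalls, grooming, rearing, wall contacts or
sensor drift; on real recordings the automatic paw labelling in
particular should be spot-checked, and the operator hint-file override
exists precisely for that correction workflow.

## Numerical conventions and degenerate inputs

- Ties: displacement exactly at the stationarity tolerance is
  stationary; a bout exactly 700 ms is static; a point on the hull
  boundary is "between the paws"; a 500 ms support is kept by the
  circling filter (only *longer* supports are excluded).
- Angle wrap is to (−180°, 180°]; an exact −180° difference maps to
  +180°.
- Undefined results (no qualifying frames, zero total weight, zero
  baseline, zero variance) raise a dedicated `UndefinedResult` (or are
  flagged/NaN in table outputs) rather than returning silent zeros.
- Problem sizes in the validation suite: full-session tests use the
  complete 5-minute, 9000-frame sessions; estimator oracles use 10⁵
  samples (sway) and 10³ random quadrilaterals (hull); the mobility rule
  is exercised on 100 random bout schedules.

## Known limitations

- The sensor grid layout of the real device is unpublished; 45 × 45 is
  an assumption consistent with the sensor count and plate size, and the
  geometry is configurable.
- Whether the device treats adjacency as 4- or 8-connected is unknown;
  8 is the default, 4 is available.
- The polar-angle origin for circling is arena-fixed (plate centre) by
  default and configurable; an animal-centric origin would require body
  tracking that floor sensors alone cannot provide.
- Automatic labelling assumes a roughly quadrupedal configuration;
  highly atypical postures (tumbling) will demote zones to OTHER and
  those frames drop out of paw-based biomarkers — mirroring the
  reference workflow, where unidentifiable sequences are removed.
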