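# posturokit

Quantitative posturo-locomotor phenotyping of freely moving rodents from
pressure-sensor plate recordings.

Unilateral vestibular lesions produce a characteristic syndrome — postural
imbalance, circling, abdominal support — that is traditionally graded with
subjective observer scales. `posturokit` extracts objective, parametric
biomarkers of this syndrome from raw force-sensor-plate data (a grid of
~2,000 sensors under a 25 × 25 cm arena, sampled at 30 Hz), the rodent
analogue of clinical posturography. It is written for behavioural
neuroscientists and pharmacologists who need sensitive, reproducible
readouts of vestibular deficit and compensation.

## What it computes

From each 5-minute session the pipeline detects body-contact zones
(central sensor ≥ 0.7 g with an adjacent sensor ≥ 0.3 g, ≥ 2 active
sensors), tracks and labels the four paws, and splits time into *static*
and *dynamic* periods (every contact stationary for ≥ 700 ms). It then
measures:

- **Lateral weight distribution** — percent of paw-borne weight on the
  left vs right limbs, per mobility state.
- **Abdomen-support time** — time spent leaning on a body part located
  between the four paws, per mobility state.
- **Circling laps** — per front paw, the polar angle of successive steps
  about the arena centre; the wrapped per-step increment
  θₙ = atan2(yₙ₊₁, xₙ₊₁) − atan2(yₙ, xₙ) is accumulated, and every ±360°
  crossing counts one lap (left/right). Steps with supports longer than
  500 ms are excluded, so slow wall-following (thigmotaxis) counts no laps.
- **Support surface** — convex-hull area of the four paw positions; the
  session maximum indexes instability.
- **Barycenter statokinesiograms** — the bearing-force barycenter
  Bar = Σᵢ wᵢ·pᵢ / Σᵢ wᵢ over the four paws, traced whenever the animal is
  static on all four paws (the centre-of-pressure analogue).
- **Body sway** — area of the confidence ellipse containing 90% of the
  barycenter cloud (10% most extreme points trimmed;
  area = π · χ²₀.₉₀,₂ · √det Σ).
- **Barycenter speed** and **SFA** (speed / sway area), a proxy for the
  energy spent stabilising posture.

A seedable synthetic-session simulator (`posturokit.synthetic_rat`)
renders sham, acute-lesion and compensated phenotypes with exact ground
truth, so the whole chain is testable without animal data. Observer
symptom scores (tumbling 5, retropulsion 4, circling 3, bobbing 2,
head-tilt 1), per-animal baseline normalisation and quantitative-vs-
qualitative Pearson correlation tables live in `posturokit.session_stats`.

## Worked example

```python
from posturokit import analyze_recording, preset_config, simulate_session

cfg = preset_config("uvn_d1", seed=42)          # acute left-lesion phenotype
rec, truth = simulate_session(cfg, animal_id="rat07", session_label="D1", group="UVN")
report = analyze_recording(rec)
print(f"static weight   left/right : {report.static_left_pct:.1f} / {report.static_right_pct:.1f} %")
print(f"circling laps   left/right : {report.left_laps:.1f} / {report.right_laps:.1f}")
print(f"abdomen support (static)   : {report.abdomen_static_s:.2f} s")
print(f"body sway (90% ellipse)    : {report.sway_area_cm2:.3f} cm^2")
print(f"SFA (speed / sway area)    : {report.sfa:.2f} 1/(cm*s)")
```

prints

```
static weight   left/right : 35.3 / 64.7 %
circling laps   left/right : 3.0 / 0.0
abdomen support (static)   : 10.00 s
body sway (90% ellipse)    : 0.379 cm^2
SFA (speed / sway area)    : 2.52 1/(cm*s)
```

The session was generated with 35% of static weight on the (lesioned)
left side, three fast left laps and 10 s of abdominal support — the
analysis, run blind on the rendered sensor frames, recovers all of them.

The same pipeline is available from the shell:

```bash
posturokit simulate --preset uvn_d1 --seed 42 -o session/
posturokit analyze session/recording.csv.gz --out report.json
posturokit segment session/recording.csv.gz --out segments.csv
```

Recordings use an open plain-text dialect: a long-format CSV
(`frame_index,t,row,col,weight_g`, zero cells omitted, gzip optional) plus
a JSON sidecar with plate geometry and metadata. Round trips are
bit-exact.

## Layout

| module | contents |
| --- | --- |
| `recording_io` | recording format, geometry, validation |
| `contact_detection` | blob thresholds, tracking, paw labelling |
| `mobility_segmentation` | 700 ms static/dynamic rule, static-quadruped episodes |
| `behavior_biomarkers` | laterality, abdomen time, circling laps |
| `posturography` | barycenter, support surface, sway ellipse, speed, SFA |
| `synthetic_rat` | trajectory simulator, footprint renderer, ground truth |
| `session_stats` | symptom scores, baseline normalisation, correlations |
| `pipeline` / `cli` | end-to-end `SessionReport` and the `posturokit` command |
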