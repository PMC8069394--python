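# Methods

## Pipeline

A session is an ordered stream of 25-joint skeleton frames at a nominal
10 Hz over a nominal 30 s. Analysis proceeds in three stages:

1. **Segmentation.** The spine-middle (joint 7) vertical coordinate is
   extracted, gaps from joint dropout are linearly interpolated in time, and
   the series is smoothed with a centered moving average. Stand-up events are
   the peaks of this trajectory, found with a prominence floor and a minimum
   peak separation; a valley is placed at the global minimum between
   consecutive peaks, one before the first peak, and one after the last peak
   when the trajectory drops by at least the prominence floor again. The
   alternating valley/peak list is paired into ascending (valley→peak) and
   descending (peak→valley) phases that tile the interval between the first
   and last extremum. NSU is the peak count — a trailing ascent with no
   following valley still counts, it just contributes no descending phase.
2. **Indicators.** Per frame: trunk flexion (UBFA), knee angles (LLFA, per
   side), shoulder twist (UBTA) and the three-joint COM. Per phase: UBFA
   range (max − min), LLFA/UBTA phase means, COM AP/ML dispersion, and the
   phase rise/descent speed (UfV) from the bounding extrema. Session values
   average per-phase values by phase kind; "Stand" rows aggregate ascending
   phases, "Sit" rows descending ones.
3. **Cohort.** Session rows aggregate to mean ± sd ± n; one-sample t-tests
   (scipy, with one- or two-sided alternatives) compare a cohort against
   literature reference means. A packaged reference file carries
   healthy-elderly means for the COM dispersions (0.01, 0.03, 0.03, 0.04 cm)
   and the rise/descent speeds (0.78, 0.71 m/s), with one-tailed directions
   expressing "the frail cohort sways more and rises slower". No published
   mean is available in-package for the UBFA-range rows; that two-tailed
   comparison requires a user-supplied reference file.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| smoothing window | 0.5 | s | 5 samples at 10 Hz; depth-camera jitter is centimeter-order and would otherwise spawn spurious extrema. 0 disables smoothing. |
| peak prominence | 0.10 | m | seat-to-stand spine excursions are ~0.2–0.4 m; 0.10 m rejects sway without missing shallow rises |
| peak separation | 1.5 | s | ~4–5 cycles in 30 s implies ≥3 s periods; 1.5 s merges double-detections within one rise |
| spine dropout limit | 10% | — | beyond this, interpolation dominates the trajectory and the session is refused |
| COM dispersion statistic | sd | cm | the common postural-sway summary; range and mean absolute deviation are selectable and recorded in output metadata |

Angle conventions: all arctangents are two-argument `atan2` with explicit
folding, making every angle invariant under skeleton translation and uniform
scaling. UBFA folds by orientation (negative + 180°), so a vertical trunk is
exactly 90°; LLFA normalizes into [0°, 360°) and reflects (360° − a), which
makes it equal the interior knee angle from the dot-product definition —
a randomized oracle test holds to 1e-9 degrees. UBTA uses a single-argument
arctan of Δy/Δx in (−90°, 90°); with joint 3 = left shoulder, joint 5 = right
shoulder and ML positive toward the subject's right, a forward left shoulder
is negative. Degenerate geometry (coincident trunk joints, zero-length
sagittal leg projection, mediolaterally aligned shoulders) raises an
undefined-angle error per frame; series computation converts it to a missing
sample for that indicator only.

One documented tension in the trunk convention: under the folded-atan2
reading, sitting is ≈90° and a fully extended trunk cannot exceed 180°
while also passing through 90° at vertical; descriptions that place full
standing extension "at approximately 180°" correspond to a 90°-shifted
convention. The fold convention is the default; a configurable constant
UBFA offset (default 0°) is provided for users who want the shifted scale.
The identity of joint 2 is treated as "the upper-trunk reference" — the
skeleton figure naming is not fully published, and the non-anchored joint
names in `stskit.joints` are likewise assumed from the standard 25-joint
skeleton.

Whether cohort COM rows use per-phase or whole-session dispersion is
likewise open; per-phase dispersion (then averaged by phase kind) is adopted
to match the Stand/Sit row structure.

## Session logs and dialects

The canonical log is a JSON array of events `{"t_ms", "score", "joints"}`
with 25 `[x, y, z]` triples in meters (null = untracked); a JSON-Schema
document ships in `stskit/data/session.schema.json`. Readers sort events by
time and collapse duplicate timestamps to the last occurrence, because
store-and-forward transport can reorder or repeat events. Dialects map
foreign field names, time units and device-native axes onto the canonical
convention; the bundled `removes` dialect uses *assumed* field names (the
deposited files' exact keys are not printed anywhere accessible to this
build) and the depth-camera native axis mapping (y up, x mirrored toward the
subject's left, z from camera to subject). Both are configurable through a
user dialect file.

## Synthetic generator

The generator emulates the study conditions: 30 s sessions at 10 Hz,
5 stand-up cycles of 6 s by default, spine-middle seat→stand excursion
0.85 → 1.15 m, trunk flexion range 80°, knee sweep 90° → 180°, shoulder
twist sd 2°, whole-body sway sd 4 mm AP / 1 mm ML, and i.i.d. Gaussian joint
noise of 0.01 m per coordinate (centimeter-order depth-camera accuracy).
The vertical profile is a raised cosine per cycle, so velocity is continuous
and peak detection is exercised realistically; trunk and knee angles sweep
monotonically in phase with the rise, making the injected per-phase ranges
exact ground truth. Joints outside the indicator equations hang off a rigid
template attached to the trunk. One master seed drives everything;
per-session streams derive by seed-sequence spawning, so cohorts are
order-independent and byte-reproducible.

What it does **not** emulate: anterior-posterior trunk translation during
the rise (the synthetic COM sway is pure noise, so synthetic COM dispersions
reflect the injected sds plus joint noise, not postural strategy), partial
or failed rises, pauses, occlusion bursts or correlated sensor error,
inter-subject anthropometric variation, and the in-game score dynamics
(score is a simple cycle counter). Passing recovery tests therefore
demonstrates the pipeline's correctness on idealized kinematics with
realistic noise amplitude, not clinical validity on patient data.

## Problem sizes and numerical notes

The test suite and the acceptance script run at the study's own scales:
300-frame sessions, 13-session cohorts, 200 seeded sessions (25 repetitions
× 1–8 cycles at 0.02 m noise) for the cycle-count recovery rate, and
randomized-pose oracles with 20–100 draws. Noise-free generator→pipeline
consistency is checked with smoothing disabled, where recovery is exact up
to one sample period (smoothing attenuates raised-cosine peaks by ~1% at the
default window, which is visible in velocity but irrelevant to counting).
Plateau extrema take their earliest sample; ties in valley placement break
toward the earlier index. Degenerate inputs (flat sessions, zero segments,
single-sample phases, zero-variance t-tests) return empty results or NaN
markers rather than raising, except where a contract is genuinely violated.

## Limitations

- The released patient dataset is not redistributed; cohort-reproduction
  checks require downloading it separately, and the `removes` dialect's key
  names may need a one-line dialect config once the real files are at hand.
- COM here is a three-joint proxy, not a biomechanical center of mass.
- No handling of multiple people in frame, sensor re-calibration drift, or
  sessions shorter than three samples.
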