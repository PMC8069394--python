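# stskit — sit-to-stand exergame kinematics

`stskit` analyzes 30-second sit-to-stand (STS) exercise sessions recorded by
a depth camera as 25-joint skeleton time series (~10 Hz). The 30 s STS is a
standard functional assessment for frail elderly people: the subject stands
up and sits down as many times as possible, and the count plus the movement
quality summarize lower-limb strength and balance. This package is for
researchers and rehabilitation engineers who need to turn raw exergame
skeleton logs into the indicator tables and session graphs a therapist reads.

## What it computes

All positions use the mediolateral (x) / anteroposterior (y) / vertical (z)
convention, in meters. With joint 7 = spine middle, 2 = upper trunk,
3/5 = left/right shoulder, 17/19 = right/left hip, 20/21 = knees,
22/24 = ankles:

- **NSU** — number of sit-up occurrences: peaks of the spine-middle vertical
  trajectory z₇(t), detected with a prominence floor and minimum separation.
  Each valley→peak stretch is an *ascending* phase, peak→valley *descending*;
  every other indicator is computed per phase.
- **UBFA** (upper-body flexion angle) = atan2(z₂−z₇, y₂−y₇), folded into
  [0°, 180°]; 90° when the trunk is vertical (sitting), larger at full
  standing extension. Reported as the per-phase range (max − min).
- **LLFA** (lower-limb flexion angle, per side) = 180° + θ_femur − θ_tibia
  with θ = atan2(Δz, Δy) of the hip→knee and knee→ankle segments, folded
  into [0°, 180°]; equals the interior knee angle (180° = straight leg).
- **UBTA** (upper-body twist angle) = arctan((y₅−y₃)/(x₅−x₃)): axial-plane
  shoulder-line rotation; negative when the left shoulder is forward.
- **COM** = mean of joints 17, 19, 7; its within-phase AP/ML sample standard
  deviation (in cm) summarizes sway.
- **UfV** (upper-frame velocity) = (z_peak − z_valley)/(t_peak − t_valley)
  per phase, sign-flipped for descents so both speeds are positive, in m/s.

Cohort tables report mean ± sd per indicator over sessions, and one-sample
t-tests compare a cohort against packaged healthy-elderly literature means
(COM dispersions and UfV).

A seeded synthetic generator produces full 25-joint STS sessions with known
ground truth (cycle count and times, trunk range, knee angles, rise speed,
injected sway and sensor noise), so the entire pipeline is testable with no
data downloads.

## Worked example

```python
import stskit as sk

session, truth = sk.generate_sts_session(sk.SyntheticConfig(seed=42))
ind = sk.compute_session_indicators(session)
print(f"NSU = {ind.nsu} (true {truth.nsu})")
for name, value in ind.summary_row().items():
    print(f"{name:24s} {value:8.3f}")
```

prints

```
NSU = 5 (true 5)
NSU                         5.000
Stand UBFA range (deg)     83.410
Sit UBFA range (deg)       83.306
Stand LLFA (deg)          134.171
Sit LLFA (deg)            135.309
Stand UBTA (deg)            0.024
Sit UBTA (deg)              0.116
COM stand AP (cm)           0.757
COM sit AP (cm)             0.771
COM stand ML (cm)           0.648
COM sit ML (cm)             0.591
UfVup (m/s)                 0.104
UfVdown (m/s)               0.099
```

All five stand-up cycles were found. The trunk swept ≈83° per phase (the
generator injected 80°; centimeter-level joint noise widens the observed
range slightly), the mean knee angle per phase is ≈135°, shoulder twist is
near zero, sway is sub-centimeter, and the spine rose at ≈0.10 m/s — the
kinematic profile of a slow, controlled STS performance.

The same pipeline runs from the shell and composes end to end:

```
stskit simulate --cycles 5 --n-sessions 13 --seed 1 --out sessions/
stskit analyze sessions/session_00.json --out report/
stskit cohort sessions/ --packaged-reference --out report/
```

`analyze` writes per-session indicators (JSON/CSV) and the therapist-style
graphs: COM height with ascending/descending phase shading and marked peaks,
UBFA/LLFA/UBTA time series, and the COM trace on the transverse plane.
`cohort` writes the mean ± sd summary CSV and the reference-comparison CSV
(indicator, n, mean, sd, reference, tails, t, p).

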