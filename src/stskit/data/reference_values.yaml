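# Literature reference means for the sit-to-stand indicators.
#
# The COM-dispersion and upper-frame-velocity rows are healthy-elderly means;
# the one-tailed direction states the alternative expected for a frail cohort
# relative to them (more sway, slower rises). UBFA-range comparisons against
# a frail-elderly reference are two-tailed; no published mean ships here, so
# supply one via a user reference file to run that comparison.
references:
  - indicator: "COM stand AP (cm)"
    mean: 0.01
    units: cm
    tails: one
    direction: greater
    source: healthy-elderly
  - indicator: "COM sit AP (cm)"
    mean: 0.03
    units: cm
    tails: one
    direction: greater
    source: healthy-elderly
  - indicator: "COM stand ML (cm)"
    mean: 0.03
    units: cm
    tails: one
    direction: greater
    source: healthy-elderly
  - indicator: "COM sit ML (cm)"
    mean: 0.04
    units: cm
    tails: one
    direction: greater
    source: healthy-elderly
  - indicator: "UfVup (m/s)"
    mean: 0.78
    units: m/s
    tails: one
    direction: less
    source: healthy-elderly
  - indicator: "UfVdown (m/s)"
    mean: 0.71
    units: m/s
    tails: one
    direction: less
    source: healthy-elderly
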