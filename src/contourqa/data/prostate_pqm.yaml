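# Plan-quality scorecard for the prostate site (prescription 6000 cGy in
# 20 fractions). Linear objectives carry two (value, score) thresholds:
# the ideal threshold with the peak score and the minimally acceptable
# threshold with the lower score; interpolation between them is linear.
site: prostate
prescription_cgy: 6000
objectives:
  - structure: PTV
    statistic: D99%
    direction: at-least
    function: linear
    thresholds:
      - {value: 6000, score: 5}
      - {value: 5700, score: 4}
  - structure: PTV
    statistic: D0.1cc
    direction: at-most
    function: linear
    thresholds:
      - {value: 6300, score: 5}
      - {value: 6420, score: 4}
  - {structure: Rectum, statistic: V4500cGy%, direction: at-most, function: threshold, thresholds: [{value: 15, score: 3}]}
  - {structure: Rectum, statistic: V2800cGy%, direction: at-most, function: threshold, thresholds: [{value: 35, score: 3}]}
  - {structure: Rectum, statistic: V900cGy%, direction: at-most, function: threshold, thresholds: [{value: 80, score: 3}]}
  - {structure: Bladder, statistic: V4500cGy%, direction: at-most, function: threshold, thresholds: [{value: 25, score: 3}]}
  - {structure: Bladder, statistic: V2800cGy%, direction: at-most, function: threshold, thresholds: [{value: 50, score: 3}]}
  - {structure: Anal Canal, statistic: V4500cGy%, direction: at-most, function: threshold, thresholds: [{value: 15, score: 3}]}
  - {structure: Anal Canal, statistic: V2800cGy%, direction: at-most, function: threshold, thresholds: [{value: 35, score: 3}]}
  - {structure: Anal Canal, statistic: V900cGy%, direction: at-most, function: threshold, thresholds: [{value: 80, score: 3}]}
  - {structure: Femur Right, statistic: V3500cGy%, direction: at-most, function: threshold, thresholds: [{value: 1, score: 2}]}
  - {structure: Femur Left, statistic: V3500cGy%, direction: at-most, function: threshold, thresholds: [{value: 1, score: 2}]}
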