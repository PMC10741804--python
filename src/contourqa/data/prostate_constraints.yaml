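# Planning dose constraints for the prostate site (6000 cGy x 20 fx).
# Purely descriptive pass/fail checks; no points attached.
site: prostate
prescription_cgy: 6000
constraints:
  - {structure: PTV, statistic: Dmin, comparator: ">", limit: 5700}
  - {structure: PTV, statistic: Dmax, comparator: "<", limit: 6420}
  - {structure: Rectum, statistic: V4500cGy%, comparator: "<", limit: 15}
  - {structure: Rectum, statistic: V2800cGy%, comparator: "<", limit: 35}
  - {structure: Rectum, statistic: V900cGy%, comparator: "<", limit: 80}
  - {structure: Bladder, statistic: V4500cGy%, comparator: "<", limit: 25}
  - {structure: Bladder, statistic: V2800cGy%, comparator: "<", limit: 50}
  - {structure: Anal Canal, statistic: V4500cGy%, comparator: "<", limit: 15}
  - {structure: Anal Canal, statistic: V2800cGy%, comparator: "<", limit: 35}
  - {structure: Anal Canal, statistic: V900cGy%, comparator: "<", limit: 80}
  - {structure: Femur Left, statistic: V3100cGy%, comparator: "<", limit: 1}
  - {structure: Femur Right, statistic: V3100cGy%, comparator: "<", limit: 1}
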