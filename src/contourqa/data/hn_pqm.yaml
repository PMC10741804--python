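# Plan-quality scorecard for the head-and-neck site (prescription
# 7095 cGy in 33 fractions). All objectives use threshold scoring.
site: head-and-neck
prescription_cgy: 7095
objectives:
  - {structure: BrachialPlexus_C, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 6000, score: 3}]}
  - {structure: BrachialPlexus_O, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 6270, score: 3}]}
  - {structure: Brain, statistic: V6000cGy%, direction: at-most, function: threshold, thresholds: [{value: 3, score: 3}]}
  - {structure: Brainstem, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 5000, score: 5}]}
  - {structure: Chiasm, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 5400, score: 5}]}
  - {structure: Cochlea_Contralateral, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 1000, score: 2}]}
  - {structure: Cochlea_Ipsilateral, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 3500, score: 2}]}
  - {structure: Esophagus, statistic: V3500cGy%, direction: at-most, function: threshold, thresholds: [{value: 50, score: 1}]}
  - {structure: Esophagus, statistic: V5000cGy%, direction: at-most, function: threshold, thresholds: [{value: 40, score: 1}]}
  - {structure: Esophagus, statistic: V7000cGy%, direction: at-most, function: threshold, thresholds: [{value: 20, score: 1}]}
  - {structure: Eye_L, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 4500, score: 5}]}
  - {structure: Eye_R, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 4500, score: 5}]}
  - {structure: Larynx, statistic: Dmean, direction: at-most, function: threshold, thresholds: [{value: 4000, score: 2}]}
  - {structure: Larynx, statistic: V5000cGy%, direction: at-most, function: threshold, thresholds: [{value: 27, score: 2}]}
  - {structure: Lens_L, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 400, score: 4}]}
  - {structure: Lens_R, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 400, score: 4}]}
  - {structure: Mandible, statistic: V5000cGy%, direction: at-most, function: threshold, thresholds: [{value: 31, score: 3}]}
  - {structure: OpticNerve_L, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 5400, score: 5}]}
  - {structure: OpticNerve_R, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 5400, score: 5}]}
  - {structure: Oral Cavity, statistic: Dmean, direction: at-most, function: threshold, thresholds: [{value: 3000, score: 3}]}
  - {structure: Oral Cavity, statistic: V3000cGy%, direction: at-most, function: threshold, thresholds: [{value: 73, score: 2}]}
  - {structure: Oral Cavity, statistic: V4000cGy%, direction: at-most, function: threshold, thresholds: [{value: 20, score: 2}]}
  - {structure: Parotid_Contralateral, statistic: Dmean, direction: at-most, function: threshold, thresholds: [{value: 2000, score: 2}]}
  - {structure: Parotid_Contralateral, statistic: Dmedian, direction: at-most, function: threshold, thresholds: [{value: 2000, score: 4}]}
  - {structure: Parotid_Ipsilatateral, statistic: Dmean, direction: at-most, function: threshold, thresholds: [{value: 2600, score: 2}]}
  - {structure: Parotid_Ipsilatateral, statistic: Dmedian, direction: at-most, function: threshold, thresholds: [{value: 2600, score: 4}]}
  - {structure: PharynxConst, statistic: V5000cGy%, direction: at-most, function: threshold, thresholds: [{value: 70, score: 2}]}
  - {structure: Pituitary, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 5000, score: 5}]}
  - {structure: SpinalCord, statistic: Dmax, direction: at-most, function: threshold, thresholds: [{value: 4000, score: 5}]}
  - {structure: Submandibular_Co, statistic: Dmean, direction: at-most, function: threshold, thresholds: [{value: 3900, score: 3}]}
  - {structure: Submandibular_Ho, statistic: Dmean, direction: at-most, function: threshold, thresholds: [{value: 5000, score: 3}]}
  - {structure: Thyroid, statistic: Dmean, direction: at-most, function: threshold, thresholds: [{value: 4500, score: 1}]}
  - {structure: Thyroid, statistic: V4000cGy%, direction: at-most, function: threshold, thresholds: [{value: 50, score: 1}]}
  - {structure: Thyroid, statistic: V3000cGy%, direction: at-most, function: threshold, thresholds: [{value: 60, score: 1}]}
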