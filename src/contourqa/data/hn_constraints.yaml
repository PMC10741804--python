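# Planning dose constraints for the head-and-neck site (7095 cGy x 33 fx).
site: head-and-neck
prescription_cgy: 7095
constraints:
  - {structure: PTV7095, statistic: Dmin, comparator: ">", limit: 6953}
  - {structure: PTV7095, statistic: Dmax, comparator: "<", limit: 7591}
  - {structure: PTV6270, statistic: Dmin, comparator: ">", limit: 5956}
  - {structure: PTV5610, statistic: Dmin, comparator: ">", limit: 5329}
  - {structure: Brain, statistic: V6000cGy%, comparator: "<", limit: 3}
  - {structure: Brainstem, statistic: Dmax, comparator: "<", limit: 5000}
  - {structure: Cochlea, statistic: Dmean, comparator: "<", limit: 4500}
  - {structure: Spinal Cord, statistic: Dmax, comparator: "<", limit: 3600}
  - {structure: PRV_Spinal Cord, statistic: Dmax, comparator: "<", limit: 4000}
  - {structure: Oral Cavity, statistic: Dmean, comparator: "<", limit: 3000}
  - {structure: Oral Cavity, statistic: V3000cGy%, comparator: "<", limit: 73}
  - {structure: Oral Cavity, statistic: V4000cGy%, comparator: "<", limit: 20}
  - {structure: Ipsilateral Parotid, statistic: Dmean, comparator: "<", limit: 2600}
  - {structure: Contralateral Parotid, statistic: Dmean, comparator: "<", limit: 2000}
  - {structure: Ipsilateral Submandibular, statistic: Dmean, comparator: "<", limit: 5000}
  - {structure: Contralateral Submandibular, statistic: Dmean, comparator: "<", limit: 3900}
  - {structure: Mandible, statistic: V5000cGy%, comparator: "<", limit: 31}
  - {structure: Arytenoid Cartilage, statistic: V5000cGy%, comparator: "<", limit: 50}
  - {structure: Pharynx Constrictor Muscle, statistic: V5000cGy%, comparator: "<", limit: 70}
  - {structure: Constrictor Muscle-PTV, statistic: Dmean, comparator: "<", limit: 5000}
  - {structure: Constrictor Muscle-PTV, statistic: V5000cGy%, comparator: "<", limit: 31}
  - {structure: Constrictor Muscle-PTV, statistic: V5000cGycc, comparator: "<", limit: 31}
  - {structure: Thyroid, statistic: Dmean, comparator: "<", limit: 4500}
  - {structure: Thyroid, statistic: V4000cGy%, comparator: "<", limit: 50}
  - {structure: Thyroid, statistic: V3000cGy%, comparator: "<", limit: 60}
  - {structure: Brachial Plexus, statistic: V6000cGycc, comparator: "<", limit: 0.1}
  - {structure: Esophagus, statistic: V3500cGy%, comparator: "<", limit: 50}
  - {structure: Esophagus, statistic: V5000cGy%, comparator: "<", limit: 40}
  - {structure: Esophagus, statistic: V7000cGy%, comparator: "<", limit: 20}
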