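# Canonical structure name -> aliases seen in clinical exports and
# scorecard/constraint configs. Matching ignores case, spaces,
# underscores and hyphens.
PTV: [PTV_High, PTV1]
CTV: [CTV_High, CTV1, Prostate]
Rectum: []
Bladder: []
Anal Canal: [AnalCanal]
Left Femur: [Femur Left, Femur_L, Left Femoral Head, Femoral Head Left, FemoralHead_L]
Right Femur: [Femur Right, Femur_R, Right Femoral Head, Femoral Head Right, FemoralHead_R]
Brain: []
Brainstem: [Brain Stem]
Chiasm: [Optic Chiasm]
Contralateral Cochlea: [Cochlea_Contralateral, Cochlea_C]
Ipsilateral Cochlea: [Cochlea_Ipsilateral, Cochlea_I, Cochlea_O, Cochlea_H]
Esophagus: []
Left Eye: [Eye_L, Eye Left]
Right Eye: [Eye_R, Eye Right]
Larynx: []
Left Lens: [Lens_L, Lens Left]
Right Lens: [Lens_R, Lens Right]
Mandible: []
Left Optic Nerve: [OpticNerve_L, Optic Nerve Left]
Right Optic Nerve: [OpticNerve_R, Optic Nerve Right]
Oral Cavity: [OralCavity, Oralcavity]
Contralateral Parotid: [Parotid_Contralateral, Parotid_C]
Ipsilateral Parotid: [Parotid_Ipsilateral, Parotid_Ipsilatateral, Parotid_H, Parotid_O]
Pharynx Constrictor Muscle: [PharynxConst, Constrictor Muscle, Pharyngeal Constrictor]
Pituitary: []
Spinal Cord: [SpinalCord]
Contralateral Submandibular: [Submandibular_Co, Contralateral Submandibular Gland, Submandibular_C]
Ipsilateral Submandibular: [Submandibular_Ho, Ipsilateral Submandibular Gland, Submandibular_I]
Thyroid: []
Trachea: []
Contralateral Brachial Plexus: [BrachialPlexus_C]
Ipsilateral Brachial Plexus: [BrachialPlexus_O, BrachialPlexus_I, BrachialPlexus_H]
Arytenoid Cartilage: [Arytenoid]
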