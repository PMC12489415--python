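{
 "missing_code": 999,
 "variables": {
  "ACADEMIC_1": {
   "high": 5,
   "kind": "substance",
   "low": 0,
   "threshold": 3
  },
  "ANXIETY_1": {
   "kind": "binary"
  },
  "BINGE_1": {
   "high": 4,
   "kind": "substance",
   "low": 0,
   "threshold": 3
  },
  "BULLYING_1": {
   "kind": "binary"
  },
  "CANNABIS_1": {
   "dialects": {
    "early": {
     "high": 4,
     "low": 0,
     "threshold": 2
    },
    "late": {
     "high": 5,
     "low": 0,
     "threshold": 3
    }
   },
   "kind": "substance"
  },
  "COCAINE_1": {
   "high": 5,
   "kind": "substance",
   "low": 0,
   "threshold": 3
  },
  "EATING_1": {
   "kind": "binary"
  },
  "EMERGE_1": {
   "kind": "binary"
  },
  "FANXIETY_1": {
   "kind": "binary"
  },
  "FMOOD_1": {
   "kind": "binary"
  },
  "FPSYCHOTIC_1": {
   "kind": "binary"
  },
  "FSUBSTANCE_1": {
   "kind": "binary"
  },
  "GAD7_1_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_1_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_2_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_2_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_3_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_3_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_4_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_4_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_5_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_5_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_6_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_6_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_7_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_7_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "GAD7_DIFF_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "MOOD_1": {
   "kind": "binary"
  },
  "NEURO_1": {
   "kind": "binary"
  },
  "OPIATE_1": {
   "high": 4,
   "kind": "substance",
   "low": 0,
   "threshold": 2
  },
  "PDEATH_1": {
   "kind": "binary"
  },
  "PHQ9_1_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_1_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_2_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_2_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_3_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_3_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_4_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_4_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_5_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_5_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_6_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_6_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_7_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_7_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_8_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_8_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_9_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_9_2": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHQ9_DIFF_1": {
   "high": 3,
   "kind": "ordinal",
   "low": 0
  },
  "PHYSABUSE_1": {
   "kind": "binary"
  },
  "PSYCHEDELIC_1": {
   "high": 4,
   "kind": "substance",
   "low": 0,
   "threshold": 2
  },
  "PSYCHOTIC_1": {
   "kind": "binary"
  },
  "REJECTED_1": {
   "kind": "binary"
  },
  "RXMISUSE_1": {
   "high": 5,
   "kind": "substance",
   "low": 0,
   "threshold": 3
  },
  "SABUSE_1": {
   "kind": "binary"
  },
  "SELFHARM_1": {
   "kind": "binary"
  },
  "SLEEPING_1": {
   "high": 4,
   "kind": "substance",
   "low": 0,
   "threshold": 2
  },
  "STIM_1": {
   "high": 4,
   "kind": "substance",
   "low": 0,
   "threshold": 2
  },
  "STREET_1": {
   "high": 5,
   "kind": "substance",
   "low": 0,
   "threshold": 3
  },
  "STRESS_1_1": {
   "high": 4,
   "kind": "ordinal",
   "low": 0
  },
  "STRESS_2_1": {
   "high": 4,
   "kind": "ordinal",
   "low": 0
  },
  "STRESS_3_1": {
   "high": 4,
   "kind": "ordinal",
   "low": 0
  },
  "STRESS_4_1": {
   "high": 4,
   "kind": "ordinal",
   "low": 0
  },
  "SUBSTANCE_1": {
   "kind": "binary"
  },
  "SUICATMP_1": {
   "kind": "binary"
  },
  "SUICIDEA_1": {
   "kind": "binary"
  },
  "WISHDEAD_1": {
   "kind": "binary"
  }
 }
}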