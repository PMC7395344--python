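{
  "comment": "Analysis-table comorbidity categories -> ICD code prefixes. A documented standard mapping (editable); prefix matching on normalized codes.",
  "categories": {
    "diabetes_with_complication": {
      "icd9_prefixes": ["250.4", "250.5", "250.6", "250.7"],
      "icd10_prefixes": ["E10.2", "E10.3", "E10.4", "E10.5", "E10.7", "E11.2", "E11.3", "E11.4", "E11.5", "E11.7", "E13.2", "E13.3", "E13.4", "E13.5", "E13.7"]
    },
    "diabetes_without_complication": {
      "icd9_prefixes": ["250.0", "250.1", "250.2", "250.3", "250.8", "250.9"],
      "icd10_prefixes": ["E10.0", "E10.1", "E10.6", "E10.8", "E10.9", "E11.0", "E11.1", "E11.6", "E11.8", "E11.9", "E13.0", "E13.1", "E13.6", "E13.8", "E13.9"]
    },
    "hypertension": {
      "icd9_prefixes": ["401", "402", "403", "404", "405"],
      "icd10_prefixes": ["I10", "I11", "I12", "I13", "I15"]
    },
    "cardiovascular_disease": {
      "icd9_prefixes": ["410", "411", "412", "413", "414", "428"],
      "icd10_prefixes": ["I20", "I21", "I22", "I23", "I24", "I25", "I42", "I50"]
    },
    "peripheral_vascular_disease": {
      "icd9_prefixes": ["440", "441", "443"],
      "icd10_prefixes": ["I70", "I71", "I72", "I73", "I74", "I77.1", "I79"]
    },
    "ckd_stages_3_5": {
      "icd9_prefixes": ["585.3", "585.4", "585.5", "585.6"],
      "icd10_prefixes": ["N18.3", "N18.4", "N18.5", "N18.6"]
    },
    "ckd_stage_4": {
      "icd9_prefixes": ["585.4"],
      "icd10_prefixes": ["N18.4"]
    },
    "ckd_stage_5": {
      "icd9_prefixes": ["585.5", "585.6"],
      "icd10_prefixes": ["N18.5", "N18.6"]
    },
    "any_malignancy": {
      "icd9_prefixes": ["14", "15", "16", "17", "18", "190", "191", "192", "193", "194", "195", "200", "201", "202", "203", "204", "205", "206", "207", "208"],
      "icd10_prefixes": ["C"]
    },
    "liver_disease": {
      "icd9_prefixes": ["570", "571", "572", "573"],
      "icd10_prefixes": ["K70", "K71", "K72", "K73", "K74", "K75", "K76", "K77"]
    },
    "depression": {
      "icd9_prefixes": ["296.2", "296.3", "300.4", "311"],
      "icd10_prefixes": ["F32", "F33", "F34.1"]
    },
    "aids": {
      "icd9_prefixes": ["042", "043", "044"],
      "icd10_prefixes": ["B20", "B21", "B22", "B24"]
    },
    "neurologic_conditions": {
      "icd9_prefixes": ["290", "330", "331", "332", "333", "334", "335", "336", "337", "340", "341", "342", "343", "344", "345", "348", "349", "430", "431", "432", "433", "434", "435", "436", "437", "438"],
      "icd10_prefixes": ["F00", "F01", "F02", "F03", "G", "I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67", "I68", "I69"]
    },
    "fractures": {
      "icd9_prefixes": ["805", "806", "807", "808", "809", "810", "811", "812", "813", "820", "821", "822", "823", "824"],
      "icd10_prefixes": ["S12", "S22", "S32", "S42", "S52", "S72", "S82", "T08"]
    },
    "osteoporosis": {
      "icd9_prefixes": ["733.0"],
      "icd10_prefixes": ["M80", "M81"]
    }
  },
  "nested": {
    "ckd_stages_3_5": ["ckd_stage_4", "ckd_stage_5"]
  }
}
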