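{
  "comment": "Charlson comorbidity categories with original weights; ICD-9-CM and ICD-10 code prefixes per the Quan 2005 coding algorithms. Prefix matching on normalized codes (uppercase, dot retained).",
  "categories": {
    "myocardial_infarction": {
      "weight": 1,
      "icd9_prefixes": ["410", "412"],
      "icd10_prefixes": ["I21", "I22", "I25.2"]
    },
    "congestive_heart_failure": {
      "weight": 1,
      "icd9_prefixes": ["398.91", "402.01", "402.11", "402.91", "404.01", "404.03", "404.11", "404.13", "404.91", "404.93", "425.4", "425.5", "425.6", "425.7", "425.8", "425.9", "428"],
      "icd10_prefixes": ["I09.9", "I11.0", "I13.0", "I13.2", "I25.5", "I42.0", "I42.5", "I42.6", "I42.7", "I42.8", "I42.9", "I43", "I50", "P29.0"]
    },
    "peripheral_vascular_disease": {
      "weight": 1,
      "icd9_prefixes": ["093.0", "437.3", "440", "441", "443.1", "443.2", "443.3", "443.4", "443.5", "443.6", "443.7", "443.8", "443.9", "447.1", "557.1", "557.9", "V43.4"],
      "icd10_prefixes": ["I70", "I71", "I73.1", "I73.8", "I73.9", "I77.1", "I79.0", "I79.2", "K55.1", "K55.8", "K55.9", "Z95.8", "Z95.9"]
    },
    "cerebrovascular_disease": {
      "weight": 1,
      "icd9_prefixes": ["362.34", "430", "431", "432", "433", "434", "435", "436", "437", "438"],
      "icd10_prefixes": ["G45", "G46", "H34.0", "I60", "I61", "I62", "I63", "I64", "I65", "I66", "I67", "I68", "I69"]
    },
    "dementia": {
      "weight": 1,
      "icd9_prefixes": ["290", "294.1", "331.2"],
      "icd10_prefixes": ["F00", "F01", "F02", "F03", "F05.1", "G30", "G31.1"]
    },
    "chronic_pulmonary_disease": {
      "weight": 1,
      "icd9_prefixes": ["416.8", "416.9", "490", "491", "492", "493", "494", "495", "496", "497", "498", "499", "500", "501", "502", "503", "504", "505", "506.4", "508.1", "508.8"],
      "icd10_prefixes": ["I27.8", "I27.9", "J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47", "J60", "J61", "J62", "J63", "J64", "J65", "J66", "J67", "J68.4", "J70.1", "J70.3"]
    },
    "rheumatologic_disease": {
      "weight": 1,
      "icd9_prefixes": ["446.5", "710.0", "710.1", "710.2", "710.3", "710.4", "714.0", "714.1", "714.2", "714.8", "725"],
      "icd10_prefixes": ["M05", "M06", "M31.5", "M32", "M33", "M34", "M35.1", "M35.3", "M36.0"]
    },
    "peptic_ulcer_disease": {
      "weight": 1,
      "icd9_prefixes": ["531", "532", "533", "534"],
      "icd10_prefixes": ["K25", "K26", "K27", "K28"]
    },
    "mild_liver_disease": {
      "weight": 1,
      "icd9_prefixes": ["070.22", "070.23", "070.32", "070.33", "070.44", "070.54", "070.6", "070.9", "570", "571", "573.3", "573.4", "573.8", "573.9", "V42.7"],
      "icd10_prefixes": ["B18", "K70.0", "K70.1", "K70.2", "K70.3", "K70.9", "K71.3", "K71.4", "K71.5", "K71.7", "K73", "K74", "K76.0", "K76.2", "K76.3", "K76.4", "K76.8", "K76.9", "Z94.4"]
    },
    "diabetes_without_complication": {
      "weight": 1,
      "icd9_prefixes": ["250.0", "250.1", "250.2", "250.3", "250.8", "250.9"],
      "icd10_prefixes": ["E10.0", "E10.1", "E10.6", "E10.8", "E10.9", "E11.0", "E11.1", "E11.6", "E11.8", "E11.9", "E12.0", "E12.1", "E12.6", "E12.8", "E12.9", "E13.0", "E13.1", "E13.6", "E13.8", "E13.9", "E14.0", "E14.1", "E14.6", "E14.8", "E14.9"]
    },
    "diabetes_with_complication": {
      "weight": 2,
      "icd9_prefixes": ["250.4", "250.5", "250.6", "250.7"],
      "icd10_prefixes": ["E10.2", "E10.3", "E10.4", "E10.5", "E10.7", "E11.2", "E11.3", "E11.4", "E11.5", "E11.7", "E12.2", "E12.3", "E12.4", "E12.5", "E12.7", "E13.2", "E13.3", "E13.4", "E13.5", "E13.7", "E14.2", "E14.3", "E14.4", "E14.5", "E14.7"]
    },
    "hemiplegia_paraplegia": {
      "weight": 2,
      "icd9_prefixes": ["334.1", "342", "343", "344.0", "344.1", "344.2", "344.3", "344.4", "344.5", "344.6", "344.9"],
      "icd10_prefixes": ["G04.1", "G11.4", "G80.1", "G80.2", "G81", "G82", "G83.0", "G83.1", "G83.2", "G83.3", "G83.4", "G83.9"]
    },
    "renal_disease": {
      "weight": 2,
      "icd9_prefixes": ["403.01", "403.11", "403.91", "404.02", "404.03", "404.12", "404.13", "404.92", "404.93", "582", "583.0", "583.1", "583.2", "583.4", "583.6", "583.7", "585", "586", "588.0", "V42.0", "V45.1", "V56"],
      "icd10_prefixes": ["I12.0", "I13.1", "N03.2", "N03.3", "N03.4", "N03.5", "N03.6", "N03.7", "N05.2", "N05.3", "N05.4", "N05.5", "N05.6", "N05.7", "N18", "N19", "N25.0", "Z49.0", "Z49.1", "Z49.2", "Z94.0", "Z99.2"]
    },
    "any_malignancy": {
      "weight": 2,
      "icd9_prefixes": ["14", "15", "16", "170", "171", "172", "174", "175", "176", "179", "18", "190", "191", "192", "193", "194", "195.8", "200", "201", "202", "203", "204", "205", "206", "207", "208", "238.6"],
      "icd10_prefixes": ["C0", "C1", "C2", "C30", "C31", "C32", "C33", "C34", "C37", "C38", "C39", "C40", "C41", "C43", "C45", "C46", "C47", "C48", "C49", "C5", "C6", "C70", "C71", "C72", "C73", "C74", "C75", "C76", "C81", "C82", "C83", "C84", "C85", "C88", "C90", "C91", "C92", "C93", "C94", "C95", "C96", "C97"]
    },
    "moderate_severe_liver_disease": {
      "weight": 3,
      "icd9_prefixes": ["456.0", "456.1", "456.2", "572.2", "572.3", "572.4", "572.5", "572.6", "572.7", "572.8"],
      "icd10_prefixes": ["I85.0", "I85.9", "I86.4", "I98.2", "K70.4", "K71.1", "K72.1", "K72.9", "K76.5", "K76.6", "K76.7"]
    },
    "metastatic_solid_tumor": {
      "weight": 6,
      "icd9_prefixes": ["196", "197", "198", "199"],
      "icd10_prefixes": ["C77", "C78", "C79", "C80"]
    },
    "aids_hiv": {
      "weight": 6,
      "icd9_prefixes": ["042", "043", "044"],
      "icd10_prefixes": ["B20", "B21", "B22", "B24"]
    }
  },
  "hierarchy": [
    ["diabetes_with_complication", "diabetes_without_complication"],
    ["metastatic_solid_tumor", "any_malignancy"],
    ["moderate_severe_liver_disease", "mild_liver_disease"]
  ]
}
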