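{
  "resourceType": "CodeSystem",
  "url": "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
  "version": "2023",
  "name": "ICD10GM_SyntheticSubset",
  "description": "Synthetic test subset of ICD-10-GM; NOT the published code system.",
  "status": "active",
  "caseSensitive": true,
  "content": "fragment",
  "concept": [
    {"code": "E11.9", "display": "Type 2 diabetes mellitus without complications"},
    {"code": "I10.00", "display": "Essential hypertension, benign"},
    {"code": "I21.4", "display": "Acute subendocardial myocardial infarction"},
    {"code": "C71.1", "display": "Malignant neoplasm of frontal lobe"},
    {"code": "J44.19", "display": "COPD with acute exacerbation"},
    {"code": "N18.5", "display": "Chronic kidney disease, stage 5"}
  ]
}
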