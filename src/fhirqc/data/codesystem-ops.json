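{
  "resourceType": "CodeSystem",
  "url": "http://fhir.de/CodeSystem/bfarm/ops",
  "version": "2023",
  "name": "OPS_SyntheticSubset",
  "description": "Synthetic test subset of the German procedure classification (OPS). Codes use the lowercase letter extensions of the real system; this is NOT the published code system.",
  "status": "active",
  "caseSensitive": true,
  "content": "fragment",
  "concept": [
    {"code": "1-100", "display": "Clinical examination (synthetic)"},
    {"code": "1-20a", "display": "Functional assessment (synthetic)"},
    {"code": "3-200", "display": "Native CT of skull (synthetic)"},
    {"code": "5-470", "display": "Appendectomy (synthetic)"},
    {"code": "5-470a", "display": "Appendectomy, laparoscopic (synthetic)"},
    {"code": "5-511.1", "display": "Cholecystectomy (synthetic)"},
    {"code": "5-790.0e", "display": "Fracture reposition (synthetic)"},
    {"code": "8-98f", "display": "Complex intensive care treatment (synthetic)"},
    {"code": "8-980", "display": "Intensive care monitoring (synthetic)"},
    {"code": "9-984.7", "display": "Care of disabled patients (synthetic)"}
  ]
}
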