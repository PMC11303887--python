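{
  "resourceType": "CodeSystem",
  "url": "https://fhirqc.example.org/fhir/CodeSystem/inhouse-lab-flags",
  "version": "1.0",
  "name": "InhouseLabFlags_Synthetic",
  "description": "Synthetic in-house code system emulating site-local codings for invalid or absent laboratory measurements.",
  "status": "active",
  "caseSensitive": true,
  "content": "complete",
  "concept": [
    {"code": "invalid", "display": "Invalid measurement"},
    {"code": "not-measurable", "display": "Measurement not possible"},
    {"code": "material-error", "display": "Pre-analytic material error"}
  ]
}
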