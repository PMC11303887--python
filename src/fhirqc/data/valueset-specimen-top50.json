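{
  "resourceType": "ValueSet",
  "url": "https://fhirqc.example.org/fhir/ValueSet/specimen-top50",
  "name": "SpecimenTop50",
  "description": "Enumerated subset of the most common specimen codes (synthetic stand-in for the top-50 list).",
  "status": "active",
  "compose": {
    "include": [
      {
        "system": "http://snomed.info/sct",
        "concept": [
          {"code": "119361006"},
          {"code": "119364003"},
          {"code": "122555007"},
          {"code": "258580003"},
          {"code": "122575003"}
        ]
      }
    ]
  }
}
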