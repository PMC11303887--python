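{
  "resourceType": "ValueSet",
  "url": "https://fhirqc.example.org/fhir/ValueSet/ops-all",
  "name": "OPS_All",
  "description": "All codes of the shipped synthetic OPS fragment.",
  "status": "active",
  "compose": {
    "include": [
      {"system": "http://fhir.de/CodeSystem/bfarm/ops"}
    ]
  }
}
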