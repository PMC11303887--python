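{
  "resourceType": "ValueSet",
  "url": "https://fhirqc.example.org/fhir/ValueSet/atc-all",
  "name": "ATC_All",
  "description": "All codes of the shipped synthetic ATC fragment.",
  "status": "active",
  "compose": {
    "include": [
      {"system": "http://fhir.de/CodeSystem/bfarm/atc"}
    ]
  }
}
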