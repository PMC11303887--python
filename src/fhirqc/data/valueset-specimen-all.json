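{
  "resourceType": "ValueSet",
  "url": "https://fhirqc.example.org/fhir/ValueSet/specimen-snomed",
  "name": "SpecimenSnomed",
  "description": "Descendants of the SNOMED CT Specimen concept (anchor excluded).",
  "status": "active",
  "compose": {
    "include": [
      {
        "system": "http://snomed.info/sct",
        "filter": [
          {"property": "concept", "op": "descendent-of", "value": "123038009"}
        ]
      }
    ]
  }
}
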