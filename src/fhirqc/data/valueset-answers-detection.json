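{
  "resourceType": "ValueSet",
  "url": "https://fhirqc.example.org/fhir/ValueSet/answers-detection",
  "name": "AnswersDetection",
  "description": "Answer-list style ValueSet (detected/not detected).",
  "status": "active",
  "compose": {
    "include": [
      {
        "system": "http://loinc.org",
        "concept": [
          {"code": "LA11882-0", "display": "Detected"},
          {"code": "LA11883-8", "display": "Not detected"}
        ]
      }
    ]
  }
}
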