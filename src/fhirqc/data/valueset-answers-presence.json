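{
  "resourceType": "ValueSet",
  "url": "https://fhirqc.example.org/fhir/ValueSet/answers-presence",
  "name": "AnswersPresence",
  "description": "Answer-list style ValueSet (positive/negative) bound to qualitative codes that carry an answer list.",
  "status": "active",
  "compose": {
    "include": [
      {
        "system": "http://loinc.org",
        "concept": [
          {"code": "LA6576-8", "display": "Positive"},
          {"code": "LA6577-6", "display": "Negative"}
        ]
      }
    ]
  }
}
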