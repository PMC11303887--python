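{
  "resourceType": "ValueSet",
  "url": "https://fhirqc.example.org/fhir/ValueSet/qualitative-general",
  "name": "QualitativeGeneral",
  "description": "General-purpose qualitative result ValueSet containing several representations of the same concept (e.g. absence); reduced to canonical representatives at profile-forge time.",
  "status": "active",
  "compose": {
    "include": [
      {
        "system": "http://snomed.info/sct",
        "concept": [
          {"code": "10828004", "display": "Positive"},
          {"code": "260385009", "display": "Negative"},
          {"code": "52101004", "display": "Present"},
          {"code": "2667000", "display": "Absent"},
          {"code": "272519000", "display": "Absence findings"},
          {"code": "410594000", "display": "Definitely NOT present"},
          {"code": "260373001", "display": "Detected"},
          {"code": "260415000", "display": "Not detected"}
        ]
      }
    ]
  }
}
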