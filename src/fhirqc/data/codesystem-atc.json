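{
  "resourceType": "CodeSystem",
  "url": "http://fhir.de/CodeSystem/bfarm/atc",
  "version": "2023",
  "name": "ATC_DE_SyntheticSubset",
  "description": "Synthetic test subset of the German ATC classification; NOT the published code system.",
  "status": "active",
  "caseSensitive": true,
  "content": "fragment",
  "concept": [
    {"code": "B01AC06", "display": "Acetylsalicylic acid"},
    {"code": "C07AB02", "display": "Metoprolol"},
    {"code": "A10BA02", "display": "Metformin"},
    {"code": "N02BE01", "display": "Paracetamol"},
    {"code": "C10AA05", "display": "Atorvastatin"}
  ]
}
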