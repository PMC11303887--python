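{
  "resourceType": "CodeSystem",
  "url": "http://snomed.info/sct",
  "version": "http://snomed.info/sct/900000000000207008",
  "name": "SNOMED_SyntheticSubset",
  "description": "Tiny curated SNOMED CT fragment for tests (specimen subtree via part-of links, procedure category, qualitative result values); NOT the published code system.",
  "status": "active",
  "caseSensitive": true,
  "content": "fragment",
  "concept": [
    {"code": "123038009", "display": "Specimen"},
    {"code": "119361006", "display": "Plasma specimen",
     "property": [{"code": "parent", "valueCode": "123038009"}]},
    {"code": "119364003", "display": "Serum specimen",
     "property": [{"code": "parent", "valueCode": "123038009"}]},
    {"code": "119297000", "display": "Blood specimen",
     "property": [{"code": "parent", "valueCode": "123038009"}]},
    {"code": "122555007", "display": "Venous blood specimen",
     "property": [{"code": "parent", "valueCode": "119297000"}]},
    {"code": "258580003", "display": "Whole blood specimen",
     "property": [{"code": "parent", "valueCode": "119297000"}]},
    {"code": "122575003", "display": "Urine specimen",
     "property": [{"code": "parent", "valueCode": "123038009"}]},
    {"code": "119342007", "display": "Saliva specimen",
     "property": [{"code": "parent", "valueCode": "123038009"}]},
    {"code": "387713003", "display": "Surgical procedure"},
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
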