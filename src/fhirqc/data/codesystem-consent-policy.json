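{
  "resourceType": "CodeSystem",
  "url": "urn:oid:2.16.840.1.113883.3.1937.777.24.5.3",
  "version": "1.0",
  "name": "ConsentPolicy_SyntheticSubset",
  "description": "Synthetic stand-in for the national consent policy code system. Encompassing permissions are linked to the specific permissions they imply via the part-of relationship.",
  "status": "active",
  "caseSensitive": true,
  "content": "fragment",
  "concept": [
    {"code": "PATDAT_erheben_speichern_nutzen",
     "display": "Collect, store and use patient data (encompassing)"},
    {"code": "IDAT_erheben", "display": "Collect identifying data",
     "property": [{"code": "part-of", "valueCode": "PATDAT_erheben_speichern_nutzen"}]},
    {"code": "IDAT_speichern_verarbeiten", "display": "Store and process identifying data",
     "property": [{"code": "part-of", "valueCode": "PATDAT_erheben_speichern_nutzen"}]},
    {"code": "MDAT_erheben", "display": "Collect medical data",
     "property": [{"code": "part-of", "valueCode": "PATDAT_erheben_speichern_nutzen"}]},
    {"code": "MDAT_speichern_verarbeiten", "display": "Store and process medical data",
     "property": [{"code": "part-of", "valueCode": "PATDAT_erheben_speichern_nutzen"}]},
    {"code": "MDAT_wissenschaftlich_nutzen", "display": "Use medical data for research",
     "property": [{"code": "part-of", "valueCode": "PATDAT_erheben_speichern_nutzen"}]},
    {"code": "KKDAT_retrospektiv_uebertragen_speichern_nutzen",
     "display": "Transfer, store and use retrospective insurance data (encompassing)"},
    {"code": "KKDAT_5J_retro_uebertragen", "display": "Transfer 5y retrospective insurance data",
     "property": [{"code": "part-of", "valueCode": "KKDAT_retrospektiv_uebertragen_speichern_nutzen"}]},
    {"code": "KKDAT_5J_retro_speichern_verarbeiten", "display": "Store 5y retrospective insurance data",
     "property": [{"code": "part-of", "valueCode": "KKDAT_retrospektiv_uebertragen_speichern_nutzen"}]},
    {"code": "KKDAT_5J_retro_wissenschaftlich_nutzen", "display": "Use 5y retrospective insurance data for research",
     "property": [{"code": "part-of", "valueCode": "KKDAT_retrospektiv_uebertragen_speichern_nutzen"}]}
  ]
}
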