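alias,canonical
urn:oid:2.16.840.1.113883.6.1,http://loinc.org
urn:oid:2.16.840.1.113883.6.96,http://snomed.info/sct
urn:oid:2.16.840.1.113883.6.8,http://unitsofmeasure.org
http://fhir.de/CodeSystem/dimdi/icd-10-gm,http://fhir.de/CodeSystem/bfarm/icd-10-gm
http://fhir.de/CodeSystem/dimdi/ops,http://fhir.de/CodeSystem/bfarm/ops
http://fhir.de/CodeSystem/dimdi/atc,http://fhir.de/CodeSystem/bfarm/atc
http://unitsofmeasure.org/ucum.html,http://unitsofmeasure.org
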