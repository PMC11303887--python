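loinc,display,scale,ucum_unit,answer_vs,low,high
718-7,Hemoglobin [Mass/volume] in Blood,QUANTITATIVE,g/dL,,12,17
2345-7,Glucose [Mass/volume] in Serum or Plasma,QUANTITATIVE,mg/dL,,60,110
2160-0,Creatinine [Mass/volume] in Serum or Plasma,QUANTITATIVE,mg/dL,,0.5,1.2
2823-3,Potassium [Moles/volume] in Serum or Plasma,QUANTITATIVE,mmol/L,,3.5,5.1
2951-2,Sodium [Moles/volume] in Serum or Plasma,QUANTITATIVE,mmol/L,,135,145
1742-6,Alanine aminotransferase [Enzymatic activity/volume],QUANTITATIVE,U/L,,10,50
1920-8,Aspartate aminotransferase [Enzymatic activity/volume],QUANTITATIVE,U/L,,10,50
4548-4,Hemoglobin A1c/Hemoglobin.total in Blood,QUANTITATIVE,%,,4,6.5
777-3,Platelets [#/volume] in Blood,QUANTITATIVE,10*3/uL,,150,400
6690-2,Leukocytes [#/volume] in Blood,QUANTITATIVE,10*3/uL,,4,10
789-8,Erythrocytes [#/volume] in Blood,QUANTITATIVE,10*6/uL,,4,6
2885-2,Protein [Mass/volume] in Serum or Plasma,QUANTITATIVE,g/L,,60,80
1988-5,C reactive protein [Mass/volume] in Serum or Plasma,QUANTITATIVE,mg/L,,0,5
2276-4,Ferritin [Mass/volume] in Serum or Plasma,QUANTITATIVE,ng/mL,,30,400
8480-6,Systolic blood pressure,QUANTITATIVE,mm[Hg],,90,140
5802-4,Nitrite [Presence] in Urine by Test strip,QUALITATIVE,,https://fhirqc.example.org/fhir/ValueSet/answers-presence,,
20454-5,Protein [Presence] in Urine by Test strip,QUALITATIVE,,https://fhirqc.example.org/fhir/ValueSet/answers-presence,,
6463-4,Bacteria identified in Unspecified specimen by Culture,QUALITATIVE,,https://fhirqc.example.org/fhir/ValueSet/answers-detection,,
5778-6,Color of Urine,QUALITATIVE,,,,
664-3,Microscopic observation [Identifier] in Unspecified specimen by Gram stain,QUALITATIVE,,,,
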