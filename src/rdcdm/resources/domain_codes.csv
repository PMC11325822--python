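domain,kind,code,label,unit
endocrinology,loinc,3016-3,Thyrotropin [Units/volume] in Serum or Plasma,mU/L
endocrinology,loinc,3024-7,Thyroxine (T4) free [Mass/volume] in Serum or Plasma,ng/dL
endocrinology,loinc,3053-6,Triiodothyronine (T3) [Mass/volume] in Serum or Plasma,ng/dL
endocrinology,atc,H03AA01,levothyroxine sodium,
endocrinology,atc,H03BB01,carbimazole,
endocrinology,ops,3-820,Scintigraphy of the thyroid,
gastroenterology,loinc,1742-6,Alanine aminotransferase [Enzymatic activity/volume],U/L
gastroenterology,loinc,1920-8,Aspartate aminotransferase [Enzymatic activity/volume],U/L
gastroenterology,loinc,1975-2,Bilirubin total [Mass/volume] in Serum or Plasma,mg/dL
gastroenterology,loinc,2276-4,Ferritin [Mass/volume] in Serum or Plasma,ng/mL
gastroenterology,atc,J05AP01,ribavirin,
gastroenterology,atc,A07AA02,nystatin,
gastroenterology,ops,1-440,Endoscopic biopsy of upper digestive tract,
gastroenterology,ops,3-035,Sonography of the abdomen,
pneumonology,loinc,6690-2,Leukocytes [#/volume] in Blood,10*3/uL
pneumonology,loinc,1988-5,C reactive protein [Mass/volume] in Serum or Plasma,mg/L
pneumonology,loinc,2532-0,Lactate dehydrogenase [Enzymatic activity/volume],U/L
pneumonology,atc,J04AC01,isoniazid,
pneumonology,atc,J05AH02,oseltamivir,
pneumonology,ops,3-222,CT of the thorax with contrast medium,
pneumonology,ops,1-430,Endoscopic biopsy of respiratory organs,
hematology,loinc,6690-2,Leukocytes [#/volume] in Blood,10*3/uL
hematology,loinc,718-7,Hemoglobin [Mass/volume] in Blood,g/dL
hematology,loinc,777-3,Platelets [#/volume] in Blood,10*3/uL
hematology,atc,L01DB06,idarubicin,
hematology,atc,L01BC01,cytarabine,
hematology,ops,1-424,Bone marrow biopsy,
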