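rdcdm_module,omop_tables,default_table,vocabularies
Person,person;visit_occurrence,person,SNOMED;Gender
Diagnosis,condition_occurrence;procedure_occurrence;measurement;observation,condition_occurrence,SNOMED;ICD-10-GM;OrphaCode
Procedure,drug_exposure;procedure_occurrence;measurement;observation,procedure_occurrence,SNOMED;OPS
LaboratoryFindings,observation;measurement;procedure_occurrence,measurement,LOINC;UCUM
Medication,drug_exposure;observation,drug_exposure,RxNorm;ATC
Genotype,observation;measurement,measurement,OMOP Genomic
Phenotype,observation;measurement,observation,HPO;SNOMED;LOINC
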