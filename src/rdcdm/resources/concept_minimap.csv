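source_code,source_vocabulary,concept_id,concept_name,placeholder
female,Gender,8532,FEMALE,false
male,Gender,8507,MALE,false
other,Gender,8521,OTHER,false
unknown,Gender,8551,UNKNOWN,false
positive,Meas Value,9191,Positive,false
negative,Meas Value,9189,Negative,false
unknown,Meas Value,0,No matching concept,false
inpatient_full,Visit,9201,Inpatient Visit,false
inpatient_partial,Visit,9201,Inpatient Visit,false
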