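study_id,year,ethnicity,genotyping_method,control_source,nos_score,language,case_S,case_M,case_L,ctrl_S,ctrl_M,ctrl_L,case_typeI,case_typeII,ctrl_typeI,ctrl_typeII,less_typeI,less_typeII,more_typeI,more_typeII,n_cases,n_controls
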