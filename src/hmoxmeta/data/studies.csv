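study_id,year,ethnicity,genotyping_method,control_source,nos_score,language,case_S,case_M,case_L,ctrl_S,ctrl_M,ctrl_L,case_typeI,case_typeII,ctrl_typeI,ctrl_typeII,less_typeI,less_typeII,more_typeI,more_typeII,n_cases,n_controls
Budhi,2003,Asian,automated_sequencing,general_population,5,English,,,,,,,55,8,140,32,,,,,63,172
Du,2006,Asian,pcr_page,general_population,7,Chinese,42,56,30,54,46,12,26,38,12,44,,,,,64,56
Fu,2007,Asian,automated_sequencing,hospital,6,Chinese,233,195,84,243,240,49,72,184,45,221,,,,,256,266
Ma,2005,Asian,pcr_page,hospital,5,Chinese,29,49,22,31,26,3,20,30,3,27,,,,,50,30
Matokanovic,2012,Caucasian,automated_sequencing,general_population,7,English,107,140,13,70,108,12,12,118,11,84,,,,,130,95
Putra,2013,Asian,automated_sequencing,general_population,6,English,,,,,,,40,8,140,32,,,,,48,172
Yamada,2000,Asian,automated_sequencing,hospital,7,English,67,93,42,92,88,20,38,63,20,80,,,,,101,100
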