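patient_id,sex,race,smoking_status_on_file
P01,female,white,current
P02,male,african_american,unknown
P03,female,white,current
P04,male,other,unknown
P05,female,white,current
P06,male,white,current
P07,female,african_american,unknown
P08,male,white,current
P09,female,white,never
P10,male,other,former
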