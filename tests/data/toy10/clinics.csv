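clinic_id,name,go_live_date,alerts_implemented
C1,Oncology clinic 1,2024-01-01,screening|support
C2,Oncology clinic 2,2024-02-01,screening
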