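encounter_id,flowsheet_name,flowsheet_value,recorded_time
E01,Q1,within past 7 days,2024-01-10T09:12:10Z
E01,Q2,yes,2024-01-10T09:12:10Z
E01,Q3,advised to quit,2024-01-10T09:12:10Z
E06,Q1,within past 7 days,2024-05-20T09:05:00Z
E06,Q2,no,2024-05-20T09:05:00Z
E07,Q1,more than 30 days ago,2024-02-10T09:00:20Z
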