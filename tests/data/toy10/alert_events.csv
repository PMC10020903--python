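alert_id,alert_instance_id,alert_name,encounter_id,patient_id,firing_time,response_time,triggering_condition,subsequent_action,override_reason,signed_order
A1,A1-I1,screening,E01,P01,2024-01-10T09:01:00Z,2024-01-10T09:01:30Z,chart_open,acknowledge_override_warning,Defer,
A1,A1-I2,screening,E01,P01,2024-01-10T09:11:30Z,2024-01-10T09:12:10Z,timer_refire,acknowledge_override_warning,Documented in Flowsheet,
A2,A2-I1,support,E01,P01,2024-01-10T09:20:00Z,2024-01-10T09:20:20Z,chart_open,acknowledge_override_warning,Discussed - Ready to quit,REF-TOBACCO-CESSATION
A3,A3-I1,screening,E02,P02,2024-04-05T10:00:00Z,2024-04-05T10:00:15Z,noninterruptive_display,acknowledge_override_warning,Documented in Flowsheet,
A4,A4-I1,screening,E03,P03,2024-07-10T09:00:30Z,2024-07-10T09:01:30Z,chart_open,acknowledge_override_warning,Defer,
A4,A4-I2,screening,E03,P03,2024-07-10T09:11:30Z,,timer_refire,none,,
A5,A5-I1,screening,E04,P04,2024-10-15T11:00:00Z,2024-10-15T11:00:10Z,chart_open,acknowledge_override_warning,Not appropriate,
A6,A6-I1,screening,E05,P05,2024-02-01T09:30:00Z,,chart_open,none,,
A7,A7-I1,support,E06,P06,2024-05-20T09:10:00Z,2024-05-20T09:10:25Z,chart_open,acknowledge_override_warning,Defer,
A7,A7-I2,support,E06,P06,2024-05-20T09:15:00Z,2024-05-20T09:15:35Z,chart_reopen,acknowledge_override_warning,Discussed - Not ready to quit,
A8,A8-I1,screening,E07,P07,2024-02-10T09:00:00Z,2024-02-10T09:00:20Z,chart_open,acknowledge_override_warning,Documented in Flowsheet,
A9,A9-I1,screening,E08,P08,2024-06-01T09:00:00Z,2024-06-01T09:00:45Z,chart_open,acknowledge_override_warning,Defer,
A9,A9-I2,screening,E08,P08,2024-06-01T09:10:45Z,2024-06-01T09:11:40Z,timer_refire,acknowledge_override_warning,Defer,
A9,A9-I3,screening,E08,P08,2024-06-01T09:21:40Z,2024-06-01T09:22:30Z,timer_refire,acknowledge_override_warning,Documented in Flowsheet,
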