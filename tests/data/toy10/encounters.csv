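encounter_id,patient_id,clinic_id,encounter_type,start_time
E01,P01,C1,office_visit,2024-01-10T08:45:00Z
E02,P02,C1,office_visit,2024-04-05T09:45:00Z
E03,P03,C1,lab_visit,2024-07-10T08:50:00Z
E04,P04,C1,office_visit,2024-10-15T10:50:00Z
E05,P05,C1,office_visit,2024-02-01T09:15:00Z
E06,P06,C1,office_visit,2024-05-20T09:00:00Z
E07,P07,C2,office_visit,2024-02-10T08:50:00Z
E08,P08,C2,office_visit,2024-06-01T08:55:00Z
E09,P09,C2,lab_visit,2024-03-01T09:00:00Z
E10,P10,C2,office_visit,2024-08-01T09:00:00Z
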