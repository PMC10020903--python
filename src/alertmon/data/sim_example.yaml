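# Example simulator configuration: two clinics, one with both alerts and
# one screening-only, at the default behaviour probabilities (acknowledged
# completion 0.55, documentation given acknowledgement 0.58, support
# responded-without-postponing 0.87; lognormal handling times centred on
# 53/52 s screening and 50/67 s support). All fields not listed fall back
# to the documented defaults.
seed: 0
refire_interval_s: 600
max_defers: 20
clinics:
  - clinic_id: C1
    name: Oncology clinic 1
    go_live_date: 2024-01-01
    alerts_implemented: [screening, support]
    n_encounters: 2000
  - clinic_id: C2
    name: Oncology clinic 2
    go_live_date: 2024-02-01
    alerts_implemented: [screening]
    n_encounters: 1000
    p_ack_complete: 0.40
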