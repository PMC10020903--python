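# Canonical-action vocabulary: maps the raw override-reason button labels
# recorded in the alert event log to canonical actions, and names the
# screener-question flowsheet rows that constitute complete documentation.
# Button captions vary between deployments; edit the keys to match yours.
questions: [Q1, Q2, Q3]
actions:
  "Documented in Flowsheet": ack_complete_screening
  "Defer": defer
  "Not appropriate": not_appropriate
  "Discussed - Ready to quit": discussed_ready
  "Discussed - Not ready to quit": discussed_not_ready
  "Not discussed": not_discussed
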