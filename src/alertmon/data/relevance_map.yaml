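# Example physician-assigned encounter-relevance map: whether an encounter
# type is an appropriate occasion for routine tobacco-use screening.
# Institutional encounter-type lists differ; supply your own mapping.
office_visit: relevant
initial_consultation: relevant
lab_visit: less_relevant
radiation_treatment_visit: less_relevant
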