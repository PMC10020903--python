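# alertmon

EHR activity metrics for monitoring clinical decision support (CDS) alerts.

Quality-improvement programs increasingly lean on EHR-embedded alerts — in
Epic, Best Practice Advisories (BPAs) — to prompt clinicians at the point of
care. Whether those alerts are actually being completed, and at what cost in
interruptions, is usually assessed by surveys or workflow observation.
`alertmon` instead computes completion and burden metrics directly from the
alert activity records the EHR already logs, for the two-alert tobacco
cessation workflow used in cancer clinics: a **screening alert** reminding
staff to complete the smoking assessment (fires when the patient's recorded
smoking status is *current* or *unknown*), and a conditional **support
alert** prompting the provider to discuss cessation support and referral
(fires only after a positive, documented screen). Each alert is either
*interruptive* — pops up at chart open and, if postponed, refires after 10
minutes or at chart reopen — or sits passively in the BPA section.

It is written for implementation-science and clinical-informatics teams who
have event-log extracts (CSV/JSONL tables of alert firings and responses,
encounters, patients, flowsheet documentation, clinics) and want
reproducible, periodic monitoring numbers rather than one-off SQL.

## Metrics

With `E_fired` the encounters in which an alert fired and `E_done(def)`
those completing it under a definition `def`:

* **Completion rate** = `|E_done(def)| / |E_fired|`, per alert. Screening
  completion is measured both as *acknowledged* (staff pressed "Documented
  in Flowsheet") and as *documented* (all screener questions Q1–Q3 actually
  answered in the flowsheet) — the gap between the two exposes
  acknowledged-but-undocumented screening. Support completion is measured
  as *discussion* (readiness to quit assessed) and *referral* (signed
  order to the cessation clinic), plus the responded-without-postponing and
  ready-to-quit shares.
* **Firing rate** = total firings / completions over a period, on
  interruptive episodes: the average number of interruptions an alert
  costs per completion (≥ 1 whenever defined; undefined when nothing was
  completed — which is why it is computed over a period, not per encounter).
* **Handling time** = mean seconds of provider attention per encounter,
  separately over completing encounters (firing→response time of responding
  instances) and postponing encounters (defer instances), sets overlapping.

All rates can be stratified by clinic, 3-month window from each clinic's own
go-live, physician-assigned encounter relevance, and patient sex/race, with
a χ² two-proportion comparison for contrasts. Every output carries its
numerator and denominator.

An *episode* is all firings sharing one alert id within an encounter
(postpone → refire chains collapse into one episode); reconstruction of
episodes from instance-level rows is the core of the package, and a
synthetic generator (`alertmon.simulate`) emits realistic event logs with a
per-encounter ground-truth ledger so the whole pipeline is testable without
any real patient data.

## Worked example

Simulate two clinics (one with both alerts, one screening-only) and compute
the metrics:

```
alertmon simulate --config src/alertmon/data/sim_example.yaml --out demo
alertmon metrics demo --out demo_metrics
```

`demo_metrics/summary.json` then contains (abridged):

```json
"screening": {
  "fired_encounters": 581,
  "completion": {
    "ack":        {"numerator": 300, "denominator": 581, "rate_rounded": 0.52},
    "documented": {"numerator": 173, "denominator": 581, "rate_rounded": 0.30}
  },
  "firing_rate": {"overall": {"fired": 919, "completed": 258, "rate_rounded": 3.6}},
  "handling_time_s": {"mean_complete_s_rounded": 51, "mean_postpone_s_rounded": 84}
}
```

Read: the screening alert fired in 581 of 3000 encounters (the rest had a
documented non-smoking status); staff acknowledged completion in 52% of
fired encounters but fully documented the screener in only 30% — the
acknowledged-but-undocumented gap the generator deliberately produces. Each
interruptive completion cost 3.6 firings on average, and a completing
encounter took 51 s of alert handling versus 84 s summed across postpones in
postponing encounters. `demo_metrics/metrics.csv` holds the same numbers in
tidy per-metric rows and `trend.csv` the per-clinic 3-month windows;
`alertmon report demo_metrics --out demo_report` renders a monitoring
report flagging clinics whose windowed rate deviates from the pooled rate by
more than 0.15 (configurable).

All randomness is seeded: the same config and seed give byte-identical
datasets.

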