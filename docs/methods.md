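# Methods

## The measurement problem

Alert activity logs record one row per alert *instance*: a firing timestamp,
an optional response timestamp, the triggering condition, the subsequent
action ("acknowledge/override warning" or nothing), the override-reason
button label, and any signed order linked to the alert. An interruptive
alert that is postponed refires — after ten minutes, or when the chart is
reopened — under the same *alert id* with a new instance id. Meaningful
monitoring quantities therefore live at two aggregated levels that must be
reconstructed from instance rows:

* the **episode** (all instances of one alert id): did the provider ever
  complete this alert, how many times did it fire, was it interruptive;
* the **encounter** (all episodes plus flowsheet documentation): the unit
  at which completion rates, relevance and demographics are defined.

The pipeline is `read/validate → build_episodes → rollup_encounters →
metrics`, with every stage pure and deterministic.

## Reconstruction rules

* **Canonical actions.** Override-reason labels are mapped through a
  user-configurable vocabulary (exact string after trimming,
  case-sensitive, since they are fixed button captions that vary by
  deployment) onto {acknowledge-complete, defer, not-appropriate,
  discussed-ready, discussed-not-ready, not-discussed}; an instance with
  subsequent action "none" is *no_response*. An unmapped label is an error
  naming the token.
* **Episode ordering.** Instances sort by firing time, ties broken by
  instance id (determinism).
* **Final action precedence.** Any responding (non-defer) action outranks
  defer; among responders the last in time wins; defer-only episodes end as
  "defer", untouched ones as "no_response". Rationale: an encounter counts
  as completed if completion happened at all, whenever it happened.
* **Completion.** Screening episodes complete on acknowledge-complete;
  support episodes complete at the discussion level (either readiness
  answer). Referral is counted only from signed orders linked to the alert
  — deliberately reproducing the known undercount of referral activity that
  happens outside the alert — never from a chart-wide order search.
* **Modality.** An episode is interruptive if *any* instance was triggered
  by chart open/reopen or timer refire; a mixed episode counts as
  interruptive because any interruption contributes to interruptive burden.
* **Documentation.** An encounter is documented when every configured
  screener question (default Q1–Q3) has a non-empty flowsheet value,
  evaluated from the encounter's flowsheet rows regardless of which button
  was pressed. This is what makes the acknowledged-vs-documented gap
  measurable.
* **Handling time.** Per encounter, completion time is the sum of
  firing→response durations over responding instances and postponement time
  the sum over defer instances; the completing mean averages over
  encounters that completed (screening: acknowledged; support: discussed),
  the postponing mean over encounters with at least one defer. The two sets
  overlap by design. Because postponement time is a within-encounter *sum*,
  its mean exceeds the per-instance mean defer duration whenever defer
  chains are longer than one; an `aggregation="instance"` switch computes
  the per-instance alternative for comparison with reports that averaged at
  the instance level.
* **Windows.** Window *k* (k = 0–3) covers [go-live + 3k months, go-live +
  3(k+1) months), half-open, calendar-month arithmetic with day-of-month
  clamping, indexed from each clinic's own go-live date; the encounter's
  start time decides membership. Encounters at or beyond 12 months stay in
  the dataset but drop out of windowed outputs.
* **Firing rate** is fired/completed over the episodes of a scope (period
  or clinic), not per encounter — an encounter-level version divides by
  zero for non-completing encounters. Interruptive episodes only by
  default: refiring is the interruptive mechanism and the quantity measures
  interruption burden; `interruptive_only=False` includes passive
  displays for sensitivity analysis.
* **Support "responded without postponing"** means the episode has a
  responding action and no defer instance anywhere in the encounter. Whether
  a later defer should disqualify an earlier response is not observable in
  aggregate reports; the no-defer-anywhere reading is the stricter one and
  is applied uniformly.

Reporting conventions: completion rates to 2 decimals, percentage shares to
1 decimal, firing rates to 1 decimal, handling times to integer seconds;
all rounding is decimal half-up (`round_half_up`), so 2.05625 → 2.1.

## The two-proportion comparison

Relevance (and any other two-group) contrasts use the Pearson χ² on the
2×2 table, df 1, two-sided, without continuity correction — the standard
large-sample choice; a degenerate pooled margin returns statistic 0, p = 1.
Small-sample caveat: the asymptotic χ² p can differ materially from the
exact conditional (permutation/hypergeometric) p at tiny n — for
3/10 vs 7/10 they are 0.074 vs 0.179. The test suite therefore checks the
Monte-Carlo permutation oracle against exact enumeration, and checks the
χ²-vs-permutation agreement on the large reference table, where both are
far below 0.001. For small tables an exact test should be preferred; the
reference contrasts here are thousands of encounters, where the χ² is
accurate.

## Synthetic data

Two generators cover two distinct needs.

**The stochastic simulator** (`simulate`) emulates what the metrics
consume, not clinical reality in full. Per encounter it draws patient
demographics, a smoking status on file, and an encounter type; fires the
screening alert for current/unknown statuses; draws a behaviour path —
acknowledge-complete (`p_ack_complete`, default 0.55), not-appropriate
(`p_not_appropriate`, 0.05), or no final response — preceded by a geometric
number of postponements (stop probability `p_stop`, 0.6, capped at
`max_defers` = 20) for interruptive episodes (`p_interruptive`, 0.85).
Acknowledged screens are actually documented with `p_document_given_ack`
(0.58), reproducing the navigator-bypass mechanism behind the
acknowledged-but-undocumented gap. The support alert fires only for
current smokers with documented screener answers, in clinics that
implemented it: the provider responds without postponing
(`p_support_respond_no_postpone`, 0.87) or defers first; responders
discussed with `p_discussed`, discussions find a patient ready with
`p_ready_given_discussed` (0.20), and ready patients are referred with
`p_referral_given_ready` (0.17). Instance durations are lognormal with
configurable mean seconds (screening 53/52 s complete/postpone, support
50/67 s) or fixed when σ = 0. Refires come at exactly +600 s
(`refire_interval_s`) unless a simulated chart reopen lands sooner. The
defaults are the observed deployment-level rates where such rates exist and
field-plausible values elsewhere. Every drawn disposition is written to a
per-encounter **ground-truth ledger** at generation time; the pipeline's
metrics must equal ledger-derived metrics *exactly*, which is the
package's strongest correctness check (any reconstruction bug breaks the
equality). The same seed yields byte-identical output.

What the simulator does **not** model: provider identity and within-clinic
clustering, repeat visits by one patient (one patient per encounter),
status changes during an encounter, free-text documentation, order
workflows beyond the single alert-linked referral code, and any activity
outside the EHR. Passing tests therefore demonstrate that the pipeline
measures what the log contains, not that the log captures the clinic.

**The deterministic expander** (`expand_calibration`) realizes published
per-clinic aggregates as the minimal event log reproducing them exactly:
category counts become blocks of identically shaped encounters cycled
round-robin across the four windows (so window rates are stable by
construction), extra firings become defer→refire chains distributed
round-robin over the encounters allowed to defer — completing encounters
for the screening alert; only designated postponers for the support alert,
whose responded-without-postponing count must survive — and fixed
durations are placed so per-encounter sums hit the published means exactly
(first defer carries the whole postponement time, later defers 0 s).
Published reports give per-clinic firing *rates* to one decimal, not the
underlying integer pairs; the packaged calibration chooses pairs that match
every per-clinic rate and simultaneously the pooled rates and the
interruptive share of completions (the published modality shares sum to
100.1%; the expansion fixes the interruptive count at the value matching
84.7% exactly, leaving 15.3% passive). Inconsistent counts fail validation
with the violated sum named.

## Problem sizes in the test suite

Oracle-equivalence sweeps use 20 randomized configurations of 150–900
encounters; parameter recovery uses one clinic of 50,000 encounters with
every behaviour probability required to land within 3 binomial standard
errors of its estimate; the permutation oracle uses 10⁵ hypergeometric
draws. The calibration fixture expands to 6,195 encounters and 8,306 alert
events and is reconstructed in a few seconds on one CPU.

## Known limitations

* Timestamps are truncated to whole seconds; sub-second log precision, if
  present, is discarded, and durations are integer seconds.
* Relevance classification is a user-supplied encounter-type map; the
  shipped map is an example, not an institutional standard.
* The window assignment uses the encounter start time; an encounter
  straddling a window boundary is attributed wholly to its start.
* The χ² comparison is asymptotic (see above).
* Referral counting is deliberately alert-linked only and will undercount
  treatment reached through other routes.
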