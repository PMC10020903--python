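"""Reconstruct alert episodes from instance-level events and roll them up.

One *episode* is every firing (instance) of one alert id: an interruptive
alert that is postponed refires — after ten minutes or when the chart is
reopened — under the same alert id with a new instance id, so the episode is
the unit at which "did the provider ever complete this alert?" is a
well-posed question. The per-encounter roll-up then condenses each
encounter's screening and support episodes plus its flowsheet documentation
into the boolean/duration outcome record the metrics consume.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .event_model import (
    INTERRUPTIVE_TRIGGERS,
    NO_RESPONSE,
    RESPONDING_ACTIONS,
    Dataset,
    VocabularyError,
)

N_WINDOWS = 4
WINDOW_MONTHS = 3


@dataclass(frozen=True)
class AlertInstance:
    """One firing of an alert and the provider's (possibly absent) response."""

    instance_id: str
    firing_time: pd.Timestamp
    response_time: pd.Timestamp | None
    triggering_condition: str
    canonical_action: str  # canonical action or "no_response"
    duration_s: int | None
    referral_ordered: bool

    @property
    def responded(self) -> bool:
        return self.canonical_action in RESPONDING_ACTIONS

    @property
    def deferred(self) -> bool:
        return self.canonical_action == "defer"


@dataclass(frozen=True)
class AlertEpisode:
    """All instances of one alert id, time-ordered, with its disposition."""

    alert_id: str
    alert_kind: str  # "screening" | "support"
    encounter_id: str
    patient_id: str
    clinic_id: str
    instances: tuple[AlertInstance, ...]
    modality: str  # "interruptive" | "noninterruptive"
    final_action: str
    completed: bool
    deferred_any: bool
    referral_ordered: bool

    @property
    def n_firings(self) -> int:
        return len(self.instances)

    @property
    def complete_time_s(self) -> int | None:
        """Seconds summed over responding (non-defer) instances; None if none."""
        vals = [i.duration_s for i in self.instances if i.responded and i.duration_s is not None]
        return sum(vals) if vals else None

    @property
    def postpone_time_s(self) -> int | None:
        vals = [i.duration_s for i in self.instances if i.deferred and i.duration_s is not None]
        return sum(vals) if vals else None


@dataclass
class EncounterOutcome:
    """Per-encounter roll-up of screening/support dispositions."""

    encounter_id: str
    clinic_id: str
    window_index: int | None  # 0..3, None when outside the 12-month horizon
    encounter_type: str
    relevance: str | None  # "relevant" | "less_relevant"
    sex: str
    race: str
    screening_fired: bool = False
    screening_interruptive: bool = False
    screening_ack_completed: bool = False
    screening_documented: bool = False
    screening_deferred_any: bool = False
    screening_not_appropriate: bool = False
    support_fired: bool = False
    support_interruptive: bool = False
    support_responded: bool = False
    support_no_postpone: bool = False
    support_deferred_any: bool = False
    support_discussed: bool = False
    support_ready_to_quit: bool = False
    support_referral_ordered: bool = False
    screening_complete_time_s: int | None = None
    screening_postpone_time_s: int | None = None
    support_complete_time_s: int | None = None
    support_postpone_time_s: int | None = None


def determine_modality(instances: Sequence[AlertInstance]) -> str:
    """Interruptive iff any instance interrupted the provider.

    A mixed episode (a passive display plus a chart-open pop-up or timer
    refire) counts as interruptive: any interruption makes the episode part
    of the interruptive burden.
    """
    if not instances:
        raise ValueError("determine_modality requires at least one instance")
    if any(i.triggering_condition in INTERRUPTIVE_TRIGGERS for i in instances):
        return "interruptive"
    return "noninterruptive"


def _final_action(instances: Sequence[AlertInstance]) -> str:
    # Responding actions (completion, not-appropriate, discussion buttons)
    # outrank defer; among responders the last in time wins; a defer-only
    # episode ends as "defer", an untouched one as "no_response".
    responders = [i for i in instances if i.responded]
    if responders:
        return responders[-1].canonical_action
    if any(i.deferred for i in instances):
        return "defer"
    return NO_RESPONSE


def _completing_actions(kind: str) -> frozenset[str]:
    # Screening completion = acknowledged screening done; support completion
    # (level 1) = discussed treatment options and assessed readiness to quit.
    if kind == "screening":
        return frozenset({"ack_complete_screening"})
    return frozenset({"discussed_ready", "discussed_not_ready"})


def build_episodes(d: Dataset) -> list[AlertEpisode]:
    """Group alert events by alert id into time-ordered episodes.

    Instances are ordered by firing time, ties broken by ascending instance
    id. The number of instances across all episodes equals the event-table
    row count (conservation). Raises :class:`VocabularyError` on an
    override-reason token the vocabulary does not cover.
    """
    ev = d.alert_events
    enc_clinic = d.encounters.set_index("encounter_id")["clinic_id"]
    episodes: list[AlertEpisode] = []
    order = ev.sort_values("alert_id", kind="stable")
    for alert_id, group in order.groupby("alert_id", sort=True):
        group = group.sort_values(
            ["firing_time", "alert_instance_id"], kind="stable"
        )
        instances = []
        for _, row in group.iterrows():
            if row["subsequent_action"] == "none":
                action = NO_RESPONSE
            else:
                reason = row["override_reason"]
                if reason is None:
                    raise VocabularyError(
                        f"alert instance {row['alert_instance_id']!r} acknowledged "
                        "but has no override_reason"
                    )
                action = d.vocabulary.map_action(str(reason))
            resp = row["response_time"]
            resp = None if pd.isna(resp) else pd.Timestamp(resp)
            duration = None
            if resp is not None:
                duration = int((resp - row["firing_time"]).total_seconds())
            instances.append(
                AlertInstance(
                    instance_id=str(row["alert_instance_id"]),
                    firing_time=pd.Timestamp(row["firing_time"]),
                    response_time=resp,
                    triggering_condition=str(row["triggering_condition"]),
                    canonical_action=action,
                    duration_s=duration,
                    referral_ordered=row["signed_order"] is not None
                    and not pd.isna(row["signed_order"]),
                )
            )
        kind = str(group["alert_name"].iloc[0])
        encounter_id = str(group["encounter_id"].iloc[0])
        final = _final_action(instances)
        completing = _completing_actions(kind)
        episodes.append(
            AlertEpisode(
                alert_id=str(alert_id),
                alert_kind=kind,
                encounter_id=encounter_id,
                patient_id=str(group["patient_id"].iloc[0]),
                clinic_id=str(enc_clinic.get(encounter_id, "")),
                instances=tuple(instances),
                modality=determine_modality(instances),
                final_action=final,
                completed=any(i.canonical_action in completing for i in instances),
                deferred_any=any(i.deferred for i in instances),
                referral_ordered=any(i.referral_ordered for i in instances),
            )
        )
    return episodes


def documentation_complete(
    rows: pd.DataFrame | Iterable[Mapping], required_questions: Iterable[str]
) -> bool:
    """True iff every required screener question has a non-empty answer.

    ``rows`` are the flowsheet rows of one encounter; the empty string is
    the null token, so an empty answer does not count.
    """
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict(orient="records")
    else:
        records = list(rows)
    answered = {
        str(r["flowsheet_name"])
        for r in records
        if r.get("flowsheet_value") is not None and str(r["flowsheet_value"]) != ""
    }
    return all(q in answered for q in required_questions)


def add_months(day: dt.date, months: int) -> dt.date:
    """Calendar-month shift, clamping the day-of-month (Jan 31 + 1mo = Feb 28)."""
    month_index = day.month - 1 + months
    year = day.year + month_index // 12
    month = month_index % 12 + 1
    last = [31, 29 if _leap(year) else 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31][month - 1]
    return dt.date(year, month, min(day.day, last))


def _leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def window_index(event_time: pd.Timestamp, go_live: dt.date, n_windows: int = N_WINDOWS) -> int | None:
    """3-month window index from the clinic's own go-live; None if outside.

    Window k covers [go_live + 3k months, go_live + 3(k+1) months), half-open
    with calendar-month arithmetic; anything at or beyond 12 months (or
    before go-live) is out of window.
    """
    when = pd.Timestamp(event_time)
    for k in range(n_windows):
        lo = pd.Timestamp(add_months(go_live, WINDOW_MONTHS * k), tz="UTC")
        hi = pd.Timestamp(add_months(go_live, WINDOW_MONTHS * (k + 1)), tz="UTC")
        if lo <= when < hi:
            return k
    return None


def rollup_encounters(
    episodes: Sequence[AlertEpisode],
    d: Dataset,
    relevance_map: Mapping[str, str],
) -> list[EncounterOutcome]:
    """One outcome per encounter in which at least one studied alert fired.

    ``relevance_map`` must cover every encounter type present among fired
    encounters (physician-assigned relevant / less_relevant labels);
    a missing type raises ``KeyError`` naming it.

    Documentation status is evaluated from the encounter's flowsheet rows
    regardless of which alert button was pressed — this is what exposes the
    acknowledged-but-undocumented gap. Handling-time fields are per-encounter
    sums over the corresponding instance durations (responding instances for
    completion time, defer instances for postponement time).
    """
    enc = d.encounters.set_index("encounter_id")
    pat = d.patients.set_index("patient_id")
    go_live = d.clinics.set_index("clinic_id")["go_live_date"].to_dict()
    fs_by_enc = dict(tuple(d.flowsheet.groupby("encounter_id", sort=False)))
    empty_fs = d.flowsheet.iloc[0:0]

    by_encounter: dict[str, list[AlertEpisode]] = {}
    for ep in episodes:
        by_encounter.setdefault(ep.encounter_id, []).append(ep)

    outcomes: list[EncounterOutcome] = []
    for encounter_id in sorted(by_encounter):
        eps = by_encounter[encounter_id]
        erow = enc.loc[encounter_id]
        prow = pat.loc[str(erow["patient_id"])]
        etype = str(erow["encounter_type"])
        if etype not in relevance_map:
            raise KeyError(
                f"encounter_type {etype!r} missing from the relevance map"
            )
        clinic_id = str(erow["clinic_id"])
        out = EncounterOutcome(
            encounter_id=encounter_id,
            clinic_id=clinic_id,
            window_index=window_index(erow["start_time"], go_live[clinic_id]),
            encounter_type=etype,
            relevance=str(relevance_map[etype]),
            sex=str(prow["sex"]),
            race=str(prow["race"]),
        )
        rows = fs_by_enc.get(encounter_id, empty_fs)
        documented = documentation_complete(rows, d.vocabulary.questions)
        for ep in eps:
            if ep.alert_kind == "screening":
                out.screening_fired = True
                out.screening_interruptive |= ep.modality == "interruptive"
                out.screening_ack_completed |= ep.completed
                out.screening_deferred_any |= ep.deferred_any
                out.screening_not_appropriate |= any(
                    i.canonical_action == "not_appropriate" for i in ep.instances
                )
                out.screening_complete_time_s = _merge(out.screening_complete_time_s, ep.complete_time_s)
                out.screening_postpone_time_s = _merge(out.screening_postpone_time_s, ep.postpone_time_s)
            else:
                out.support_fired = True
                out.support_interruptive |= ep.modality == "interruptive"
                responded = any(i.responded for i in ep.instances)
                out.support_responded |= responded
                out.support_deferred_any |= ep.deferred_any
                out.support_discussed |= ep.completed
                out.support_ready_to_quit |= any(
                    i.canonical_action == "discussed_ready" for i in ep.instances
                )
                out.support_referral_ordered |= ep.referral_ordered
                out.support_complete_time_s = _merge(out.support_complete_time_s, ep.complete_time_s)
                out.support_postpone_time_s = _merge(out.support_postpone_time_s, ep.postpone_time_s)
        out.screening_documented = out.screening_fired and documented
        # responded and never postponed ("acted upon")
        out.support_no_postpone = out.support_responded and not out.support_deferred_any
        outcomes.append(out)
    return outcomes


def _merge(current: int | None, extra: int | None) -> int | None:
    if extra is None:
        return current
    return extra if current is None else current + extra


OUTCOME_COLUMNS = [
    "encounter_id",
    "clinic_id",
    "window_index",
    "encounter_type",
    "relevance",
    "sex",
    "race",
    "screening_fired",
    "screening_interruptive",
    "screening_ack_completed",
    "screening_documented",
    "screening_deferred_any",
    "screening_not_appropriate",
    "support_fired",
    "support_interruptive",
    "support_responded",
    "support_no_postpone",
    "support_deferred_any",
    "support_discussed",
    "support_ready_to_quit",
    "support_referral_ordered",
    "screening_complete_time_s",
    "screening_postpone_time_s",
    "support_complete_time_s",
    "support_postpone_time_s",
]


def outcomes_to_frame(outcomes: Sequence[EncounterOutcome]) -> pd.DataFrame:
    """Tabular view of the roll-up, one row per encounter."""
    frame = pd.DataFrame(
        [{col: getattr(o, col) for col in OUTCOME_COLUMNS} for o in outcomes],
        columns=OUTCOME_COLUMNS,
    )
    return frame
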