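"""Stochastic event-log simulator with a per-encounter ground-truth ledger.

The generator emulates the firing logic of the two tobacco-cessation
decision-support alerts and the provider behaviours the metrics measure:

* the **screening alert** fires for encounters of patients whose recorded
  smoking status is *current* or *unknown*; staff acknowledge completion,
  judge the patient not appropriate, postpone (an interruptive alert then
  refires after ``refire_interval_s`` — ten minutes — or a simulated chart
  reopen), or ignore it;
* acknowledged screenings are actually documented in the flowsheet (the
  three screener questions) only with probability ``p_document_given_ack``,
  generating the acknowledged-but-undocumented gap that makes the two
  screening completion definitions diverge;
* the **support alert** fires only when the screening result is positive
  (current smoker with a positive first screener answer) and the screener
  answers are documented, and only in clinics that implemented it;
  providers respond without postponing, postpone-then-respond, or leave it.

Every sampled disposition is recorded in a :class:`GroundTruth` ledger (one
row per encounter) at generation time, so the reconstruction pipeline can be
checked against the truth exactly. The same seed yields a byte-identical
dataset.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .episodes import window_index
from .event_model import ActionVocabulary, Dataset, _finalize_table

POSITIVE_Q1_VALUES = ("within past 7 days", "within past 30 days")
_Q1_NEGATIVE = ("more than 30 days ago", "never")
_Q2_VALUES = ("yes", "no")
_Q3_VALUES = ("advised to quit", "counseling materials given")
REFERRAL_ORDER_CODE = "REF-TOBACCO-CESSATION"


class DurationModel(BaseModel):
    """Seconds spent on one alert instance; lognormal, or fixed if sigma=0."""

    mean_s: float = Field(gt=0)
    sigma: float = Field(default=0.5, ge=0)

    def draw(self, rng: np.random.Generator) -> int:
        if self.sigma == 0:
            return int(round(self.mean_s))
        mu = math.log(self.mean_s) - self.sigma**2 / 2.0
        return max(1, int(round(rng.lognormal(mu, self.sigma))))


class EncounterTypeMix(BaseModel):
    name: str
    relevance: str  # "relevant" | "less_relevant"
    p: float = Field(ge=0, le=1)

    @field_validator("relevance")
    @classmethod
    def _rel(cls, v: str) -> str:
        if v not in {"relevant", "less_relevant"}:
            raise ValueError(f"relevance must be relevant/less_relevant, got {v!r}")
        return v


def _default_type_mix() -> list[EncounterTypeMix]:
    return [
        EncounterTypeMix(name="office_visit", relevance="relevant", p=0.55),
        EncounterTypeMix(name="initial_consultation", relevance="relevant", p=0.30),
        EncounterTypeMix(name="lab_visit", relevance="less_relevant", p=0.10),
        EncounterTypeMix(name="radiation_treatment_visit", relevance="less_relevant", p=0.05),
    ]


class ClinicSimConfig(BaseModel):
    """Per-clinic cohort size, patient mix and provider-behaviour probabilities."""

    clinic_id: str
    name: str = ""
    go_live_date: dt.date = dt.date(2024, 1, 1)
    alerts_implemented: list[str] = Field(default_factory=lambda: ["screening", "support"])
    n_encounters: int = Field(default=1000, ge=0)
    encounter_type_mix: list[EncounterTypeMix] = Field(default_factory=_default_type_mix)
    # population on file: screening fires for current/unknown
    smoking_status_dist: dict[str, float] = Field(
        default_factory=lambda: {"current": 0.13, "former": 0.25, "never": 0.55, "unknown": 0.07}
    )
    sex_dist: dict[str, float] = Field(default_factory=lambda: {"female": 0.55, "male": 0.45})
    race_dist: dict[str, float] = Field(
        default_factory=lambda: {"white": 0.77, "african_american": 0.18, "other": 0.05}
    )
    p_interruptive: float = Field(default=0.85, ge=0, le=1)
    # screening behaviour
    p_ack_complete: float = Field(default=0.55, ge=0, le=1)
    p_not_appropriate: float = Field(default=0.05, ge=0, le=1)
    p_document_given_ack: float = Field(default=0.58, ge=0, le=1)
    #: geometric stopping probability of the postpone chain; the number of
    #: defers before the final disposition is Geometric(p_stop) - 1 (capped)
    p_stop: float = Field(default=0.6, gt=0, le=1)
    # support behaviour
    p_support_respond_no_postpone: float = Field(default=0.87, ge=0, le=1)
    p_respond_after_defer: float = Field(default=0.5, ge=0, le=1)
    p_discussed: float = Field(default=0.68, ge=0, le=1)
    p_ready_given_discussed: float = Field(default=0.20, ge=0, le=1)
    p_referral_given_ready: float = Field(default=0.17, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "ClinicSimConfig":
        if self.p_ack_complete + self.p_not_appropriate > 1.0 + 1e-9:
            raise ValueError("p_ack_complete + p_not_appropriate exceeds 1")
        for name in ("smoking_status_dist", "sex_dist", "race_dist"):
            dist = getattr(self, name)
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} must sum to 1, sums to {total}")
        total = sum(m.p for m in self.encounter_type_mix)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"encounter_type_mix must sum to 1, sums to {total}")
        bad = set(self.alerts_implemented) - {"screening", "support"}
        if bad:
            raise ValueError(f"unknown alerts {sorted(bad)}")
        return self


def _default_durations() -> dict[str, DurationModel]:
    return {
        "screening_complete": DurationModel(mean_s=53.0),
        "screening_postpone": DurationModel(mean_s=52.0),
        "support_complete": DurationModel(mean_s=50.0),
        "support_postpone": DurationModel(mean_s=67.0),
    }


class SimConfig(BaseModel):
    """Full generator configuration: clinics plus alert mechanics."""

    clinics: list[ClinicSimConfig]
    refire_interval_s: int = Field(default=600, gt=0)
    max_defers: int = Field(default=20, ge=0)
    p_reopen_instead_of_timer: float = Field(default=0.3, ge=0, le=1)
    durations: dict[str, DurationModel] = Field(default_factory=_default_durations)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        missing = set(_default_durations()) - set(self.durations)
        if missing:
            raise ValueError(f"durations missing {sorted(missing)}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def relevance_map(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for clinic in self.clinics:
            for mix in clinic.encounter_type_mix:
                out[mix.name] = mix.relevance
        return out


GROUND_TRUTH_COLUMNS = [
    "encounter_id",
    "clinic_id",
    "window_index",
    "encounter_type",
    "relevance",
    "sex",
    "race",
    "smoking_status",
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
    "screening_n_firings",
    "support_n_firings",
]


@dataclass
class GroundTruth:
    """The generator's per-encounter ledger of true dispositions and times."""

    ledger: pd.DataFrame  # one row per simulated encounter (fired or not)

    def fired(self, kind: str) -> pd.DataFrame:
        return self.ledger[self.ledger[f"{kind}_fired"]]


class _Emitter:
    """Accumulates table rows and hands out sequential identifiers."""

    def __init__(self) -> None:
        self.patients: list[dict] = []
        self.encounters: list[dict] = []
        self.clinics: list[dict] = []
        self.events: list[dict] = []
        self.flowsheet: list[dict] = []
        self.truth: list[dict] = []
        self._alert_seq = 0

    def next_alert_id(self, clinic_id: str) -> str:
        self._alert_seq += 1
        return f"{clinic_id}-A{self._alert_seq:06d}"


def _categorical(rng: np.random.Generator, dist: dict[str, float]) -> str:
    names = list(dist.keys())
    probs = np.array([dist[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _n_defers(rng: np.random.Generator, p_stop: float, cap: int) -> int:
    # number of failures before the first success: Geometric(p_stop) - 1
    return min(int(rng.geometric(p_stop)) - 1, cap)


def _emit_chain(
    em: _Emitter,
    *,
    alert_name: str,
    encounter_id: str,
    patient_id: str,
    clinic_id: str,
    t0: pd.Timestamp,
    interruptive: bool,
    n_defers: int,
    final_action: str | None,  # vocabulary raw token, or None for no response
    postpone_s: list[int],
    complete_s: int | None,
    refire_interval_s: int,
    reopen_gaps: list[int],  # per-defer: 0 => timer refire at +interval, else reopen after gap
    signed_order: str | None = None,
) -> tuple[int, int | None, int | None]:
    """Emit one episode's instances; returns (n_firings, complete_sum, postpone_sum)."""
    alert_id = em.next_alert_id(clinic_id)
    t = t0
    seq = 0
    postpone_sum: int | None = None
    complete_sum: int | None = None

    def emit(trigger: str, action_token: str | None, duration: int | None, order: str | None) -> None:
        nonlocal seq
        seq += 1
        responded = action_token is not None
        em.events.append(
            {
                "alert_id": alert_id,
                "alert_instance_id": f"{alert_id}-I{seq:02d}",
                "alert_name": alert_name,
                "encounter_id": encounter_id,
                "patient_id": patient_id,
                "firing_time": t,
                "response_time": (t + pd.Timedelta(seconds=duration)) if responded else None,
                "triggering_condition": trigger,
                "subsequent_action": "acknowledge_override_warning" if responded else "none",
                "override_reason": action_token,
                "signed_order": order,
            }
        )

    first_trigger = "chart_open" if interruptive else "noninterruptive_display"
    for k in range(n_defers):
        trigger = first_trigger if k == 0 else ("chart_reopen" if reopen_gaps[k - 1] else "timer_refire")
        emit(trigger, "Defer", postpone_s[k], None)
        postpone_sum = (postpone_sum or 0) + postpone_s[k]
        gap = reopen_gaps[k] if reopen_gaps[k] else refire_interval_s
        t = t + pd.Timedelta(seconds=postpone_s[k] + gap)
    trigger = first_trigger if n_defers == 0 else (
        "chart_reopen" if reopen_gaps[n_defers - 1] else "timer_refire"
    )
    if final_action is not None:
        emit(trigger, final_action, complete_s, signed_order)
        complete_sum = complete_s
    else:
        emit(trigger, None, None, None)
    return n_defers + 1, complete_sum, postpone_sum


def simulate(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Generate an event-log dataset plus its ground-truth ledger.

    Deterministic under ``config.seed``; encounter times are uniform over
    each clinic's first 12 months post go-live.
    """
    rng = np.random.default_rng(config.seed)
    em = _Emitter()

    for clinic in config.clinics:
        em.clinics.append(
            {
                "clinic_id": clinic.clinic_id,
                "name": clinic.name or clinic.clinic_id,
                "go_live_date": clinic.go_live_date,
                "alerts_implemented": "|".join(sorted(clinic.alerts_implemented)),
            }
        )
        go_live = pd.Timestamp(clinic.go_live_date, tz="UTC")
        type_names = [m.name for m in clinic.encounter_type_mix]
        type_probs = np.array([m.p for m in clinic.encounter_type_mix], dtype=float)
        type_probs /= type_probs.sum()
        relevance_of = {m.name: m.relevance for m in clinic.encounter_type_mix}

        for i in range(clinic.n_encounters):
            patient_id = f"{clinic.clinic_id}-P{i + 1:06d}"
            encounter_id = f"{clinic.clinic_id}-E{i + 1:06d}"
            sex = _categorical(rng, clinic.sex_dist)
            race = _categorical(rng, clinic.race_dist)
            smoking = _categorical(rng, clinic.smoking_status_dist)
            etype = type_names[int(rng.choice(len(type_names), p=type_probs))]
            # uniform over ~12 months, business hours
            day = int(rng.integers(0, 360))
            second = int(rng.integers(8 * 3600, 17 * 3600))
            start = go_live + pd.Timedelta(days=day, seconds=second)

            em.patients.append(
                {"patient_id": patient_id, "sex": sex, "race": race, "smoking_status_on_file": smoking}
            )
            em.encounters.append(
                {
                    "encounter_id": encounter_id,
                    "patient_id": patient_id,
                    "clinic_id": clinic.clinic_id,
                    "encounter_type": etype,
                    "start_time": start,
                }
            )
            truth = {c: None for c in GROUND_TRUTH_COLUMNS}
            truth.update(
                encounter_id=encounter_id,
                clinic_id=clinic.clinic_id,
                window_index=window_index(start, clinic.go_live_date),
                encounter_type=etype,
                relevance=relevance_of[etype],
                sex=sex,
                race=race,
                smoking_status=smoking,
                screening_fired=False,
                support_fired=False,
                screening_n_firings=0,
                support_n_firings=0,
            )
            for flag in (
                "screening_interruptive screening_ack_completed screening_documented "
                "screening_deferred_any screening_not_appropriate support_interruptive "
                "support_responded support_no_postpone support_deferred_any support_discussed "
                "support_ready_to_quit support_referral_ordered"
            ).split():
                truth[flag] = False

            screening_on = "screening" in clinic.alerts_implemented
            fires = screening_on and smoking in {"current", "unknown"}
            documented_time: pd.Timestamp | None = None
            if fires:
                truth["screening_fired"] = True
                interruptive = bool(rng.random() < clinic.p_interruptive)
                truth["screening_interruptive"] = interruptive
                u = rng.random()
                if u < clinic.p_ack_complete:
                    final = "Documented in Flowsheet"
                elif u < clinic.p_ack_complete + clinic.p_not_appropriate:
                    final = "Not appropriate"
                else:
                    final = None
                n_def = _n_defers(rng, clinic.p_stop, config.max_defers) if interruptive else 0
                if final is None and n_def == 0 and interruptive and rng.random() < 0.5:
                    n_def = 1  # ignored after one postponement
                postpone_s = [config.durations["screening_postpone"].draw(rng) for _ in range(n_def)]
                reopen_gaps = [
                    int(rng.integers(60, config.refire_interval_s))
                    if rng.random() < config.p_reopen_instead_of_timer
                    else 0
                    for _ in range(n_def)
                ]
                complete = (
                    config.durations["screening_complete"].draw(rng) if final is not None else None
                )
                t0 = start + pd.Timedelta(seconds=60)
                n_fired, csum, psum = _emit_chain(
                    em,
                    alert_name="screening",
                    encounter_id=encounter_id,
                    patient_id=patient_id,
                    clinic_id=clinic.clinic_id,
                    t0=t0,
                    interruptive=interruptive,
                    n_defers=n_def,
                    final_action=final,
                    postpone_s=postpone_s,
                    complete_s=complete,
                    refire_interval_s=config.refire_interval_s,
                    reopen_gaps=reopen_gaps,
                )
                truth["screening_n_firings"] = n_fired
                truth["screening_complete_time_s"] = csum
                truth["screening_postpone_time_s"] = psum
                truth["screening_deferred_any"] = n_def > 0
                truth["screening_ack_completed"] = final == "Documented in Flowsheet"
                truth["screening_not_appropriate"] = final == "Not appropriate"

                if final == "Documented in Flowsheet" and rng.random() < clinic.p_document_given_ack:
                    documented_time = t0 + pd.Timedelta(
                        seconds=sum(postpone_s) + sum(g or config.refire_interval_s for g in reopen_gaps) + (complete or 0)
                    )
                    positive = smoking == "current"
                    q1 = (
                        POSITIVE_Q1_VALUES[int(rng.integers(0, len(POSITIVE_Q1_VALUES)))]
                        if positive
                        else _Q1_NEGATIVE[int(rng.integers(0, len(_Q1_NEGATIVE)))]
                    )
                    answers = [
                        ("Q1", q1),
                        ("Q2", _Q2_VALUES[int(rng.integers(0, 2))]),
                        ("Q3", _Q3_VALUES[int(rng.integers(0, 2))]),
                    ]
                    for q, value in answers:
                        em.flowsheet.append(
                            {
                                "encounter_id": encounter_id,
                                "flowsheet_name": q,
                                "flowsheet_value": value,
                                "recorded_time": documented_time,
                            }
                        )
                    truth["screening_documented"] = True

            support_on = "support" in clinic.alerts_implemented
            # conditional sequential design: positive screen + documented answers
            if support_on and smoking == "current" and truth["screening_documented"]:
                truth["support_fired"] = True
                interruptive = bool(rng.random() < clinic.p_interruptive)
                truth["support_interruptive"] = interruptive
                no_postpone = bool(rng.random() < clinic.p_support_respond_no_postpone)
                if no_postpone or not interruptive:
                    n_def, responds = 0, True
                else:
                    n_def = max(1, _n_defers(rng, clinic.p_stop, config.max_defers))
                    responds = bool(rng.random() < clinic.p_respond_after_defer)
                final = None
                if responds:
                    if rng.random() < clinic.p_discussed:
                        ready = rng.random() < clinic.p_ready_given_discussed
                        final = "Discussed - Ready to quit" if ready else "Discussed - Not ready to quit"
                    else:
                        final = "Not discussed"
                referral = final == "Discussed - Ready to quit" and rng.random() < clinic.p_referral_given_ready
                postpone_s = [config.durations["support_postpone"].draw(rng) for _ in range(n_def)]
                reopen_gaps = [
                    int(rng.integers(60, config.refire_interval_s))
                    if rng.random() < config.p_reopen_instead_of_timer
                    else 0
                    for _ in range(n_def)
                ]
                complete = config.durations["support_complete"].draw(rng) if final else None
                t0 = documented_time + pd.Timedelta(seconds=60)
                n_fired, csum, psum = _emit_chain(
                    em,
                    alert_name="support",
                    encounter_id=encounter_id,
                    patient_id=patient_id,
                    clinic_id=clinic.clinic_id,
                    t0=t0,
                    interruptive=interruptive,
                    n_defers=n_def,
                    final_action=final,
                    postpone_s=postpone_s,
                    complete_s=complete,
                    refire_interval_s=config.refire_interval_s,
                    reopen_gaps=reopen_gaps,
                    signed_order=REFERRAL_ORDER_CODE if referral else None,
                )
                truth["support_n_firings"] = n_fired
                truth["support_complete_time_s"] = csum
                truth["support_postpone_time_s"] = psum
                truth["support_deferred_any"] = n_def > 0
                truth["support_responded"] = responds
                truth["support_no_postpone"] = responds and n_def == 0
                truth["support_discussed"] = final in {
                    "Discussed - Ready to quit",
                    "Discussed - Not ready to quit",
                }
                truth["support_ready_to_quit"] = final == "Discussed - Ready to quit"
                truth["support_referral_ordered"] = referral

            em.truth.append(truth)

    dataset = _assemble(em)
    ledger = pd.DataFrame(em.truth, columns=GROUND_TRUTH_COLUMNS)
    return dataset, GroundTruth(ledger=ledger)


def _assemble(em: _Emitter, vocabulary: ActionVocabulary | None = None) -> Dataset:
    from .event_model import TABLE_COLUMNS

    frames = {
        "patients": pd.DataFrame(em.patients, columns=TABLE_COLUMNS["patients"]),
        "encounters": pd.DataFrame(em.encounters, columns=TABLE_COLUMNS["encounters"]),
        "clinics": pd.DataFrame(em.clinics, columns=TABLE_COLUMNS["clinics"]),
        "alert_events": pd.DataFrame(em.events, columns=TABLE_COLUMNS["alert_events"]),
        "flowsheet": pd.DataFrame(em.flowsheet, columns=TABLE_COLUMNS["flowsheet"]),
    }
    for name, frame in frames.items():
        frames[name] = _finalize_table(frame, name)
    return Dataset(vocabulary=vocabulary or ActionVocabulary(), **frames)


def conditional_firing_check(
    d: Dataset,
    positive_q1_values: tuple[str, ...] = POSITIVE_Q1_VALUES,
    required_questions: tuple[str, str] = ("Q1", "Q2"),
) -> list[str]:
    """Verify the conditional sequential design on a dataset.

    The support alert may only fire in an encounter whose screening result
    is positive — the patient is a current smoker and the first screener
    answer indicates recent smoking — with both screener answers documented
    before the support alert's first firing. Returns one message per
    violating support alert id (empty list if the logic holds).
    """
    violations: list[str] = []
    ev = d.alert_events
    support = ev[ev["alert_name"] == "support"]
    if len(support) == 0:
        return violations
    status = d.patients.set_index("patient_id")["smoking_status_on_file"]
    fs_by_enc = dict(tuple(d.flowsheet.groupby("encounter_id", sort=False)))
    for alert_id, group in support.groupby("alert_id", sort=True):
        first_fire = group["firing_time"].min()
        encounter_id = str(group["encounter_id"].iloc[0])
        patient_id = str(group["patient_id"].iloc[0])
        if status.get(patient_id) != "current":
            violations.append(
                f"support alert {alert_id}: patient {patient_id} is not a current smoker"
            )
            continue
        rows = fs_by_enc.get(encounter_id)
        answered: dict[str, str] = {}
        if rows is not None:
            prior = rows[rows["recorded_time"] <= first_fire]
            for _, row in prior.iterrows():
                value = row["flowsheet_value"]
                if value is not None and str(value) != "":
                    answered[str(row["flowsheet_name"])] = str(value)
        missing = [q for q in required_questions if q not in answered]
        if missing:
            violations.append(
                f"support alert {alert_id}: screener question(s) {missing} not documented "
                "before the alert fired"
            )
            continue
        if answered[required_questions[0]] not in positive_q1_values:
            violations.append(
                f"support alert {alert_id}: screening result not positive "
                f"(Q1={answered[required_questions[0]]!r})"
            )
    return violations
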