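"""Deterministic expansion of aggregate counts into an event-level fixture.

Monitoring reports publish aggregates — encounters fired, completions by
definition, total firings, per-encounter mean handling times — not event
logs. ``expand_calibration`` realizes such per-clinic counts as the minimal
event log whose pipeline reconstruction reproduces every input count
exactly: category counts become blocks of identically shaped encounters,
extra firings beyond one per encounter become defer→refire chains
distributed round-robin, and handling times are met exactly by giving each
encounter's first defer the full fixed postponement duration (later defers
in the chain take zero seconds, so the per-encounter sum is the configured
constant).

There is no randomness anywhere: re-expanding the same counts yields a
byte-identical dataset.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .episodes import N_WINDOWS, WINDOW_MONTHS, add_months
from .event_model import ActionVocabulary, Dataset
from .simulate import POSITIVE_Q1_VALUES, REFERRAL_ORDER_CODE, _Emitter, _assemble

_SEXES = ("female", "male")
_RACES = ("white", "white", "white", "african_american", "other")


class ConsistencyError(ValueError):
    """Calibration counts violate an internal sum or capacity constraint."""


class ScreeningCounts(BaseModel):
    """Per-clinic screening-alert aggregates (encounter counts)."""

    interruptive_ack_completed: int = Field(default=0, ge=0)
    interruptive_not_appropriate: int = Field(default=0, ge=0)
    interruptive_defer_only: int = Field(default=0, ge=0)
    interruptive_no_response: int = Field(default=0, ge=0)
    noninterruptive_ack_completed: int = Field(default=0, ge=0)
    noninterruptive_no_response: int = Field(default=0, ge=0)
    #: total firings of interruptive episodes (>= interruptive episodes)
    total_interruptive_firings: int = Field(default=0, ge=0)
    #: encounters with complete screener documentation (subset of ack-completed)
    documented: int = Field(default=0, ge=0)
    #: ack-completed encounters whose type is less relevant to routine screening
    ack_less_relevant: int = Field(default=0, ge=0)
    #: all fired encounters whose type is less relevant
    less_relevant_fired: int = Field(default=0, ge=0)

    @property
    def interruptive_encounters(self) -> int:
        return (
            self.interruptive_ack_completed
            + self.interruptive_not_appropriate
            + self.interruptive_defer_only
            + self.interruptive_no_response
        )

    @property
    def fired_encounters(self) -> int:
        return (
            self.interruptive_encounters
            + self.noninterruptive_ack_completed
            + self.noninterruptive_no_response
        )

    @property
    def ack_completed(self) -> int:
        return self.interruptive_ack_completed + self.noninterruptive_ack_completed


class SupportCounts(BaseModel):
    """Per-clinic support-alert aggregates; all support episodes interruptive."""

    np_discussed_ready: int = Field(default=0, ge=0)
    np_discussed_not_ready: int = Field(default=0, ge=0)
    np_not_discussed: int = Field(default=0, ge=0)
    defer_discussed_ready: int = Field(default=0, ge=0)
    defer_discussed_not_ready: int = Field(default=0, ge=0)
    defer_not_discussed: int = Field(default=0, ge=0)
    defer_only: int = Field(default=0, ge=0)
    no_response: int = Field(default=0, ge=0)
    referrals: int = Field(default=0, ge=0)
    total_firings: int = Field(default=0, ge=0)

    @property
    def fired_encounters(self) -> int:
        return (
            self.np_discussed_ready
            + self.np_discussed_not_ready
            + self.np_not_discussed
            + self.defer_discussed_ready
            + self.defer_discussed_not_ready
            + self.defer_not_discussed
            + self.defer_only
            + self.no_response
        )

    @property
    def deferring_encounters(self) -> int:
        return (
            self.defer_discussed_ready
            + self.defer_discussed_not_ready
            + self.defer_not_discussed
            + self.defer_only
        )

    @property
    def ready(self) -> int:
        return self.np_discussed_ready + self.defer_discussed_ready


class ClinicCalibration(BaseModel):
    clinic_id: str
    name: str = ""
    go_live_date: dt.date
    alerts_implemented: list[str]
    screening: ScreeningCounts | None = None
    support: SupportCounts | None = None


class CalibrationCounts(BaseModel):
    """Aggregate counts per clinic plus fixed per-action durations."""

    clinics: list[ClinicCalibration]
    screening_complete_s: int = Field(default=53, ge=0)
    screening_postpone_s: int = Field(default=52, ge=0)
    support_complete_s: int = Field(default=50, ge=0)
    support_postpone_s: int = Field(default=67, ge=0)
    refire_interval_s: int = Field(default=600, gt=0)
    max_defers_per_encounter: int = Field(default=20, ge=1)
    relevant_type: str = "office_visit"
    less_relevant_type: str = "lab_visit"

    @model_validator(mode="after")
    def _consistent(self) -> "CalibrationCounts":
        for clinic in self.clinics:
            s = clinic.screening
            if s is not None:
                cid = clinic.clinic_id
                if s.documented > s.ack_completed:
                    raise ConsistencyError(
                        f"{cid}: documented ({s.documented}) exceeds ack-completed "
                        f"({s.ack_completed})"
                    )
                if s.ack_less_relevant > min(s.ack_completed, s.less_relevant_fired):
                    raise ConsistencyError(
                        f"{cid}: ack_less_relevant ({s.ack_less_relevant}) exceeds "
                        f"ack_completed or less_relevant_fired"
                    )
                non_ack = s.fired_encounters - s.ack_completed
                if s.less_relevant_fired - s.ack_less_relevant > non_ack:
                    raise ConsistencyError(
                        f"{cid}: less_relevant_fired ({s.less_relevant_fired}) cannot be "
                        f"covered by non-completing encounters ({non_ack})"
                    )
                if s.interruptive_encounters > 0:
                    floor = s.interruptive_encounters + s.interruptive_defer_only
                    if s.total_interruptive_firings < floor:
                        raise ConsistencyError(
                            f"{cid}: total_interruptive_firings "
                            f"({s.total_interruptive_firings}) below minimum {floor} "
                            "(one per episode plus one refire per defer-only encounter)"
                        )
                    extra = s.total_interruptive_firings - floor
                    if extra > 0 and s.interruptive_ack_completed == 0:
                        raise ConsistencyError(
                            f"{cid}: {extra} extra firings but no completing encounters "
                            "to carry defer chains"
                        )
                    if s.interruptive_ack_completed:
                        per = -(-extra // s.interruptive_ack_completed)
                        if per + 1 > self.max_defers_per_encounter:
                            raise ConsistencyError(
                                f"{cid}: defer chains would exceed the "
                                f"{self.max_defers_per_encounter}-defer cap"
                            )
            p = clinic.support
            if p is not None:
                cid = clinic.clinic_id
                if p.referrals > p.ready:
                    raise ConsistencyError(
                        f"{cid}: referrals ({p.referrals}) exceed ready-to-quit "
                        f"encounters ({p.ready})"
                    )
                floor = p.fired_encounters + p.deferring_encounters
                if p.fired_encounters and p.total_firings < floor:
                    raise ConsistencyError(
                        f"{cid}: total_firings ({p.total_firings}) below minimum {floor}"
                    )
                extra = p.total_firings - floor
                if extra > 0 and p.deferring_encounters == 0:
                    raise ConsistencyError(
                        f"{cid}: {extra} extra support firings but no postponing encounters"
                    )
                if p.deferring_encounters:
                    per = -(-extra // p.deferring_encounters)
                    if per + 1 > self.max_defers_per_encounter:
                        raise ConsistencyError(
                            f"{cid}: support defer chains would exceed the cap"
                        )
        return self

    @classmethod
    def from_yaml(cls, path) -> "CalibrationCounts":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def relevance_map(self) -> dict[str, str]:
        return {self.relevant_type: "relevant", self.less_relevant_type: "less_relevant"}


def _round_robin(total: int, n_bins: int) -> list[int]:
    if n_bins == 0:
        return []
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


class _ClinicExpander:
    """Emits one clinic's encounters; windows cycle 0,1,2,3,0,… so every
    3-month window carries a near-equal share of each behaviour category."""

    def __init__(self, em: _Emitter, clinic: ClinicCalibration, cal: CalibrationCounts):
        self.em = em
        self.clinic = clinic
        self.cal = cal
        self.seq = 0
        self.go_live = clinic.go_live_date

    def new_encounter(self, etype: str, smoking: str) -> tuple[str, str, pd.Timestamp]:
        self.seq += 1
        i = self.seq
        cid = self.clinic.clinic_id
        patient_id = f"{cid}-P{i:06d}"
        encounter_id = f"{cid}-E{i:06d}"
        window = (i - 1) % N_WINDOWS
        day_offset = ((i - 1) // N_WINDOWS) % 85
        start = pd.Timestamp(
            add_months(self.go_live, WINDOW_MONTHS * window), tz="UTC"
        ) + pd.Timedelta(days=day_offset, hours=9)
        self.em.patients.append(
            {
                "patient_id": patient_id,
                "sex": _SEXES[i % 2],
                "race": _RACES[i % len(_RACES)],
                "smoking_status_on_file": smoking,
            }
        )
        self.em.encounters.append(
            {
                "encounter_id": encounter_id,
                "patient_id": patient_id,
                "clinic_id": cid,
                "encounter_type": etype,
                "start_time": start,
            }
        )
        return encounter_id, patient_id, start

    def emit_episode(
        self,
        *,
        alert_name: str,
        encounter_id: str,
        patient_id: str,
        start: pd.Timestamp,
        interruptive: bool,
        n_defers: int,
        final_token: str | None,
        complete_s: int,
        postpone_s: int,
        signed_order: str | None = None,
        t_offset_s: int = 60,
    ) -> None:
        from .simulate import _emit_chain

        # first defer carries the whole fixed postponement time, later defers 0 s
        postpone = [postpone_s if k == 0 else 0 for k in range(n_defers)]
        _emit_chain(
            self.em,
            alert_name=alert_name,
            encounter_id=encounter_id,
            patient_id=patient_id,
            clinic_id=self.clinic.clinic_id,
            t0=start + pd.Timedelta(seconds=t_offset_s),
            interruptive=interruptive,
            n_defers=n_defers,
            final_action=final_token,
            postpone_s=postpone,
            complete_s=complete_s if final_token is not None else None,
            refire_interval_s=self.cal.refire_interval_s,
            reopen_gaps=[0] * n_defers,
            signed_order=signed_order,
        )

    def document(self, encounter_id: str, when: pd.Timestamp, questions=("Q1", "Q2", "Q3")) -> None:
        values = {"Q1": POSITIVE_Q1_VALUES[0], "Q2": "yes", "Q3": "advised to quit"}
        for q in questions:
            self.em.flowsheet.append(
                {
                    "encounter_id": encounter_id,
                    "flowsheet_name": q,
                    "flowsheet_value": values[q],
                    "recorded_time": when,
                }
            )


def expand_calibration(counts: CalibrationCounts) -> Dataset:
    """Expand aggregate counts into the minimal consistent event log.

    Raises :class:`ConsistencyError` (at model validation) when the counts
    violate an internal sum; the expansion itself is total on validated
    counts and involves no randomness.
    """
    em = _Emitter()
    for clinic in counts.clinics:
        em.clinics.append(
            {
                "clinic_id": clinic.clinic_id,
                "name": clinic.name or clinic.clinic_id,
                "go_live_date": clinic.go_live_date,
                "alerts_implemented": "|".join(sorted(clinic.alerts_implemented)),
            }
        )
        ex = _ClinicExpander(em, clinic, counts)
        if clinic.screening is not None:
            _expand_screening(ex, clinic.screening, counts)
        if clinic.support is not None:
            _expand_support(ex, clinic.support, counts)
    return _assemble(em)


def _expand_screening(ex: _ClinicExpander, s: ScreeningCounts, cal: CalibrationCounts) -> None:
    extra = s.total_interruptive_firings - s.interruptive_encounters - s.interruptive_defer_only
    ack_defers = _round_robin(extra, s.interruptive_ack_completed)
    # relevance labels: the last ack_less_relevant completing encounters and the
    # first (less_relevant_fired - ack_less_relevant) non-completing ones are
    # less-relevant types; everything else is relevant.
    ack_total = s.ack_completed
    nonack_less = s.less_relevant_fired - s.ack_less_relevant
    ack_rank = 0
    nonack_rank = 0

    def ack_type() -> str:
        nonlocal ack_rank
        ack_rank += 1
        return cal.less_relevant_type if ack_rank > ack_total - s.ack_less_relevant else cal.relevant_type

    def nonack_type() -> str:
        nonlocal nonack_rank
        nonack_rank += 1
        return cal.less_relevant_type if nonack_rank <= nonack_less else cal.relevant_type

    doc_left = s.documented
    smoking = ("current", "unknown")

    for j in range(s.interruptive_ack_completed):
        enc, pat, start = ex.new_encounter(ack_type(), smoking[j % 2])
        n_def = ack_defers[j]
        ex.emit_episode(
            alert_name="screening",
            encounter_id=enc,
            patient_id=pat,
            start=start,
            interruptive=True,
            n_defers=n_def,
            final_token="Documented in Flowsheet",
            complete_s=cal.screening_complete_s,
            postpone_s=cal.screening_postpone_s,
        )
        if doc_left > 0:
            doc_left -= 1
            response = start + pd.Timedelta(
                seconds=60
                + (cal.screening_postpone_s if n_def else 0)
                + n_def * cal.refire_interval_s
                + cal.screening_complete_s
            )
            ex.document(enc, response)
    for j in range(s.noninterruptive_ack_completed):
        enc, pat, start = ex.new_encounter(ack_type(), smoking[j % 2])
        ex.emit_episode(
            alert_name="screening",
            encounter_id=enc,
            patient_id=pat,
            start=start,
            interruptive=False,
            n_defers=0,
            final_token="Documented in Flowsheet",
            complete_s=cal.screening_complete_s,
            postpone_s=cal.screening_postpone_s,
        )
        if doc_left > 0:
            doc_left -= 1
            ex.document(enc, start + pd.Timedelta(seconds=60 + cal.screening_complete_s))
    for j in range(s.interruptive_not_appropriate):
        enc, pat, start = ex.new_encounter(nonack_type(), smoking[j % 2])
        ex.emit_episode(
            alert_name="screening",
            encounter_id=enc,
            patient_id=pat,
            start=start,
            interruptive=True,
            n_defers=0,
            final_token="Not appropriate",
            complete_s=cal.screening_complete_s,
            postpone_s=cal.screening_postpone_s,
        )
    for j in range(s.interruptive_defer_only):
        enc, pat, start = ex.new_encounter(nonack_type(), smoking[j % 2])
        ex.emit_episode(
            alert_name="screening",
            encounter_id=enc,
            patient_id=pat,
            start=start,
            interruptive=True,
            n_defers=1,
            final_token=None,
            complete_s=cal.screening_complete_s,
            postpone_s=cal.screening_postpone_s,
        )
    for j in range(s.interruptive_no_response):
        enc, pat, start = ex.new_encounter(nonack_type(), smoking[j % 2])
        ex.emit_episode(
            alert_name="screening",
            encounter_id=enc,
            patient_id=pat,
            start=start,
            interruptive=True,
            n_defers=0,
            final_token=None,
            complete_s=cal.screening_complete_s,
            postpone_s=cal.screening_postpone_s,
        )
    for j in range(s.noninterruptive_no_response):
        enc, pat, start = ex.new_encounter(nonack_type(), smoking[j % 2])
        ex.emit_episode(
            alert_name="screening",
            encounter_id=enc,
            patient_id=pat,
            start=start,
            interruptive=False,
            n_defers=0,
            final_token=None,
            complete_s=cal.screening_complete_s,
            postpone_s=cal.screening_postpone_s,
        )


def _expand_support(ex: _ClinicExpander, p: SupportCounts, cal: CalibrationCounts) -> None:
    extra = p.total_firings - p.fired_encounters - p.deferring_encounters
    defer_extra = _round_robin(extra, p.deferring_encounters)
    referrals_left = p.referrals
    categories: list[tuple[int, bool, str | None]] = [
        # (count, deferring, final raw token)
        (p.np_discussed_ready, False, "Discussed - Ready to quit"),
        (p.defer_discussed_ready, True, "Discussed - Ready to quit"),
        (p.np_discussed_not_ready, False, "Discussed - Not ready to quit"),
        (p.np_not_discussed, False, "Not discussed"),
        (p.defer_discussed_not_ready, True, "Discussed - Not ready to quit"),
        (p.defer_not_discussed, True, "Not discussed"),
        (p.defer_only, True, None),
        (p.no_response, False, None),
    ]
    defer_idx = 0
    for count, deferring, token in categories:
        for _ in range(count):
            enc, pat, start = ex.new_encounter(cal.relevant_type, "current")
            # screener answers documented before the support alert fires
            ex.document(enc, start + pd.Timedelta(seconds=60), questions=("Q1", "Q2"))
            n_def = 0
            if deferring:
                n_def = 1 + defer_extra[defer_idx]
                defer_idx += 1
            order = None
            if token == "Discussed - Ready to quit" and referrals_left > 0:
                referrals_left -= 1
                order = REFERRAL_ORDER_CODE
            ex.emit_episode(
                alert_name="support",
                encounter_id=enc,
                patient_id=pat,
                start=start,
                interruptive=True,
                n_defers=n_def,
                final_token=token,
                complete_s=cal.support_complete_s,
                postpone_s=cal.support_postpone_s,
                signed_order=order,
                t_offset_s=120,
            )
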