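"""Event-log data model: tables, vocabulary, I/O and integrity validation.

The atomic record is one firing (instance) of one clinical decision support
alert. A dataset bundles five tables — patients, encounters, clinics, alert
events, flowsheet rows — plus the action vocabulary that maps the raw
override-reason button labels recorded by the EHR to canonical actions.

All timestamps are UTC at one-second resolution (ISO-8601 on disk, with a
trailing ``Z``); durations derived from them are integer seconds. CSV files
are comma-separated UTF-8 with a mandatory header row; the empty string is
the null token for optional fields. The same schemas are accepted as JSONL
(one JSON object per line).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Enumerations (kept as plain frozensets: the tables are pandas DataFrames and
# values are validated, not coerced into Python enum objects)

SEX_VALUES = frozenset({"female", "male", "unknown"})
RACE_VALUES = frozenset({"african_american", "white", "other", "unknown"})
SMOKING_VALUES = frozenset({"current", "former", "never", "unknown"})
ALERT_NAMES = frozenset({"screening", "support"})
TRIGGER_VALUES = frozenset(
    {"chart_open", "chart_reopen", "timer_refire", "noninterruptive_display"}
)
INTERRUPTIVE_TRIGGERS = frozenset({"chart_open", "chart_reopen", "timer_refire"})
SUBSEQUENT_ACTIONS = frozenset({"acknowledge_override_warning", "none"})

CANONICAL_ACTIONS = frozenset(
    {
        "ack_complete_screening",
        "defer",
        "not_appropriate",
        "discussed_ready",
        "discussed_not_ready",
        "not_discussed",
    }
)
#: Responding (non-defer) actions; ``no_response`` is assigned when the
#: provider took no action on an instance.
RESPONDING_ACTIONS = frozenset(CANONICAL_ACTIONS - {"defer"})
NO_RESPONSE = "no_response"

DEFAULT_ACTION_MAP = {
    "Documented in Flowsheet": "ack_complete_screening",
    "Defer": "defer",
    "Not appropriate": "not_appropriate",
    "Discussed - Ready to quit": "discussed_ready",
    "Discussed - Not ready to quit": "discussed_not_ready",
    "Not discussed": "not_discussed",
}
DEFAULT_QUESTIONS = ("Q1", "Q2", "Q3")

TABLE_COLUMNS = {
    "patients": ["patient_id", "sex", "race", "smoking_status_on_file"],
    "encounters": ["encounter_id", "patient_id", "clinic_id", "encounter_type", "start_time"],
    "clinics": ["clinic_id", "name", "go_live_date", "alerts_implemented"],
    "alert_events": [
        "alert_id",
        "alert_instance_id",
        "alert_name",
        "encounter_id",
        "patient_id",
        "firing_time",
        "response_time",
        "triggering_condition",
        "subsequent_action",
        "override_reason",
        "signed_order",
    ],
    "flowsheet": ["encounter_id", "flowsheet_name", "flowsheet_value", "recorded_time"],
}
_TIMESTAMP_COLUMNS = {
    "encounters": ["start_time"],
    "alert_events": ["firing_time", "response_time"],
    "flowsheet": ["recorded_time"],
}
_DATE_COLUMNS = {"clinics": ["go_live_date"]}
_OPTIONAL_COLUMNS = {"alert_events": {"response_time", "override_reason", "signed_order"}}


class SchemaError(ValueError):
    """A table or column is missing, or a field cannot be parsed."""


class VocabularyError(ValueError):
    """An override-reason token has no canonical-action mapping."""


@dataclass(frozen=True)
class ActionVocabulary:
    """Mapping from raw override-reason button labels to canonical actions.

    Matching is exact-string after trimming surrounding whitespace and
    case-sensitive: the labels are fixed button captions in the EHR, but
    their wording varies between deployments, so the mapping is
    user-configurable (``vocabulary.yaml``).
    """

    actions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ACTION_MAP))
    questions: tuple[str, ...] = DEFAULT_QUESTIONS

    def __post_init__(self) -> None:
        bad = {a for a in self.actions.values() if a not in CANONICAL_ACTIONS}
        if bad:
            raise VocabularyError(f"unknown canonical action(s): {sorted(bad)}")

    def map_action(self, raw: str) -> str:
        token = raw.strip()
        if token not in self.actions:
            raise VocabularyError(f"unmapped override_reason token: {raw!r}")
        return self.actions[token]

    def covers(self, raw: str) -> bool:
        return raw.strip() in self.actions

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ActionVocabulary":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            actions=dict(doc.get("actions", DEFAULT_ACTION_MAP)),
            questions=tuple(doc.get("questions", DEFAULT_QUESTIONS)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {"questions": list(self.questions), "actions": dict(self.actions)},
                fh,
                sort_keys=False,
            )


@dataclass
class Dataset:
    """The five event-log tables plus the action vocabulary.

    Tables are pandas DataFrames with the documented column sets; timestamp
    columns are tz-aware UTC ``datetime64[s]``-compatible series, optional
    fields hold ``pd.NaT`` / ``None`` when absent.
    """

    patients: pd.DataFrame
    encounters: pd.DataFrame
    clinics: pd.DataFrame
    alert_events: pd.DataFrame
    flowsheet: pd.DataFrame
    vocabulary: ActionVocabulary = field(default_factory=ActionVocabulary)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "Dataset":
        return replace(
            self,
            **{name: self.table(name).copy() for name in TABLE_COLUMNS},
        )

    def counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLE_COLUMNS}

    @classmethod
    def empty(cls, vocabulary: ActionVocabulary | None = None) -> "Dataset":
        tables = {
            name: _finalize_table(pd.DataFrame(columns=cols), name)
            for name, cols in TABLE_COLUMNS.items()
        }
        return cls(vocabulary=vocabulary or ActionVocabulary(), **tables)


@dataclass(frozen=True)
class Violation:
    """One integrity-rule violation: rule id, row locator, message."""

    rule: str
    table: str
    locator: str
    message: str


# ---------------------------------------------------------------------------
# Parsing helpers


def _parse_timestamps(frame: pd.DataFrame, table: str, col: str, path: str) -> pd.Series:
    raw = frame[col]
    mask = raw.notna() & (raw.astype(str).str.len() > 0)
    parsed = pd.Series(pd.NaT, index=frame.index, dtype="datetime64[ns, UTC]")
    if mask.any():
        try:
            vals = pd.to_datetime(raw[mask], utc=True, format="ISO8601")
        except (ValueError, TypeError):
            # locate the offending row for the error message
            for idx, value in raw[mask].items():
                try:
                    pd.to_datetime(value, utc=True, format="ISO8601")
                except (ValueError, TypeError):
                    raise SchemaError(
                        f"{path}: unparseable timestamp {value!r} in column "
                        f"{col!r} at row {idx + 2} (1-based, counting header)"
                    ) from None
            raise
        parsed.loc[mask] = vals.dt.floor("s")
    return parsed


def _finalize_table(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    frame = frame.copy()
    for col in _TIMESTAMP_COLUMNS.get(name, []):
        if len(frame) == 0:
            frame[col] = pd.Series(dtype="datetime64[ns, UTC]")
    for col in frame.columns:
        if frame[col].dtype == object:
            frame[col] = frame[col].where(frame[col].notna(), None)
    return frame.reset_index(drop=True)


def _read_table(root: Path, name: str) -> tuple[pd.DataFrame, str]:
    csv_path = root / f"{name}.csv"
    jsonl_path = root / f"{name}.jsonl"
    if csv_path.exists():
        frame = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
        frame = frame.replace({"": None})
        path = str(csv_path)
    elif jsonl_path.exists():
        records = []
        with open(jsonl_path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{jsonl_path}: invalid JSON at line {lineno}: {exc}")
        frame = pd.DataFrame(records, columns=TABLE_COLUMNS[name] if not records else None)
        if len(frame):
            frame = frame.replace({"": None})
        path = str(jsonl_path)
    else:
        raise SchemaError(f"missing table {name!r}: expected {csv_path} or {jsonl_path}")

    missing = [c for c in TABLE_COLUMNS[name] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: table {name!r} missing column(s) {missing}")
    frame = frame[TABLE_COLUMNS[name]]
    for col in _TIMESTAMP_COLUMNS.get(name, []):
        frame[col] = _parse_timestamps(frame, name, col, path)
    for col in _DATE_COLUMNS.get(name, []):
        try:
            frame[col] = pd.to_datetime(frame[col], format="%Y-%m-%d").dt.date
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: unparseable date in column {col!r}: {exc}")
    return _finalize_table(frame, name), path


def read_dataset(root_path: str | Path, vocab_path: str | Path | None = None) -> Dataset:
    """Read the five tables (CSV or JSONL) under ``root_path`` into a Dataset.

    Parameters
    ----------
    root_path:
        Directory holding ``patients``, ``encounters``, ``clinics``,
        ``alert_events`` and ``flowsheet`` tables as ``.csv`` or ``.jsonl``.
    vocab_path:
        Optional ``vocabulary.yaml``; defaults to ``root_path/vocabulary.yaml``
        when present, else the built-in default vocabulary.

    Raises
    ------
    SchemaError
        On a missing table or column (naming it) or an unparseable
        timestamp (naming the row).
    """
    root = Path(root_path)
    if vocab_path is None:
        candidate = root / "vocabulary.yaml"
        vocab = ActionVocabulary.from_yaml(candidate) if candidate.exists() else ActionVocabulary()
    else:
        vocab = ActionVocabulary.from_yaml(vocab_path)
    tables = {}
    for name in TABLE_COLUMNS:
        tables[name], _ = _read_table(root, name)
    return Dataset(vocabulary=vocab, **tables)


def _format_timestamp(value) -> str:
    if value is None or pd.isna(value):
        return ""
    return pd.Timestamp(value).strftime("%Y-%m-%dT%H:%M:%SZ")


def _serial_frame(d: Dataset, name: str) -> pd.DataFrame:
    frame = d.table(name).copy()
    for col in _TIMESTAMP_COLUMNS.get(name, []):
        frame[col] = frame[col].map(_format_timestamp)
    for col in _DATE_COLUMNS.get(name, []):
        frame[col] = frame[col].map(lambda v: "" if v is None or pd.isna(v) else v.isoformat())
    for col in frame.columns:
        frame[col] = frame[col].map(lambda v: "" if v is None or (isinstance(v, float) and pd.isna(v)) else str(v))
    return frame[TABLE_COLUMNS[name]]


def write_dataset(d: Dataset, root_path: str | Path, fmt: str = "csv") -> list[Path]:
    """Write all tables plus ``vocabulary.yaml`` under ``root_path``.

    ``read_dataset(write_dataset(d))`` is the identity on valid datasets:
    one fixed CSV dialect (UTF-8, comma, header row, ``""`` as null, ``\\n``
    line terminator) keeps round-trips byte-stable.
    """
    if fmt not in {"csv", "jsonl"}:
        raise ValueError(f"unknown format {fmt!r}")
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in TABLE_COLUMNS:
        frame = _serial_frame(d, name)
        path = root / f"{name}.{fmt}"
        if fmt == "csv":
            frame.to_csv(path, index=False, lineterminator="\n")
        else:
            with open(path, "w", encoding="utf-8") as fh:
                for record in frame.to_dict(orient="records"):
                    fh.write(json.dumps(record, sort_keys=False) + "\n")
        written.append(path)
    vocab_path = root / "vocabulary.yaml"
    d.vocabulary.to_yaml(vocab_path)
    written.append(vocab_path)
    return written


# ---------------------------------------------------------------------------
# Validation


def _dups(series: pd.Series) -> list:
    return sorted(series[series.duplicated()].unique().tolist())


def validate_dataset(d: Dataset) -> list[Violation]:
    """Check every referential, temporal and enum invariant; pure function.

    Returns the (possibly empty) list of violations and never mutates or
    raises on content problems — callers decide whether violations are fatal.
    """
    v: list[Violation] = []
    pat, enc, cli = d.patients, d.encounters, d.clinics
    ev, fs = d.alert_events, d.flowsheet

    # --- primary keys
    for table, col in [
        ("patients", "patient_id"),
        ("encounters", "encounter_id"),
        ("clinics", "clinic_id"),
        ("alert_events", "alert_instance_id"),
    ]:
        for key in _dups(d.table(table)[col]):
            v.append(Violation("duplicate-key", table, str(key), f"duplicate {col} {key!r}"))

    # --- enum domains
    enum_checks = [
        ("patients", "sex", SEX_VALUES, "patient_id"),
        ("patients", "race", RACE_VALUES, "patient_id"),
        ("patients", "smoking_status_on_file", SMOKING_VALUES, "patient_id"),
        ("alert_events", "alert_name", ALERT_NAMES, "alert_instance_id"),
        ("alert_events", "triggering_condition", TRIGGER_VALUES, "alert_instance_id"),
        ("alert_events", "subsequent_action", SUBSEQUENT_ACTIONS, "alert_instance_id"),
    ]
    for table, col, domain, key in enum_checks:
        frame = d.table(table)
        bad = frame[~frame[col].isin(domain)]
        for _, row in bad.iterrows():
            v.append(
                Violation(
                    "enum-domain", table, str(row[key]), f"{col}={row[col]!r} not in {sorted(domain)}"
                )
            )

    # --- referential integrity
    patient_ids = set(pat["patient_id"])
    encounter_ids = set(enc["encounter_id"])
    clinic_ids = set(cli["clinic_id"])
    refs = [
        ("encounters", "patient_id", patient_ids, "encounter_id"),
        ("encounters", "clinic_id", clinic_ids, "encounter_id"),
        ("alert_events", "encounter_id", encounter_ids, "alert_instance_id"),
        ("alert_events", "patient_id", patient_ids, "alert_instance_id"),
        ("flowsheet", "encounter_id", encounter_ids, "flowsheet_name"),
    ]
    for table, col, universe, key in refs:
        frame = d.table(table)
        bad = frame[~frame[col].isin(universe)]
        for _, row in bad.iterrows():
            v.append(
                Violation(
                    "dangling-reference",
                    table,
                    str(row[key]),
                    f"{col}={row[col]!r} does not resolve",
                )
            )

    # --- temporal: response not before firing
    if len(ev):
        has_resp = ev["response_time"].notna()
        bad = ev[has_resp & (ev["response_time"] < ev["firing_time"])]
    else:
        bad = ev
    for _, row in bad.iterrows():
        v.append(
            Violation(
                "response-before-firing",
                "alert_events",
                str(row["alert_instance_id"]),
                f"response_time {row['response_time']} precedes firing_time {row['firing_time']}",
            )
        )

    # --- temporal: clinic go-live precedes its alert events
    if len(ev) and len(cli):
        enc_clinic = enc.set_index("encounter_id")["clinic_id"]
        ev_clinic = ev["encounter_id"].map(enc_clinic)
        go_live = cli.set_index("clinic_id")["go_live_date"].map(
            lambda day: pd.Timestamp(day, tz="UTC")
            if day is not None and not pd.isna(day)
            else pd.NaT
        )
        ev_golive = pd.to_datetime(ev_clinic.map(go_live), utc=True)
        bad = ev[ev_golive.notna() & (ev["firing_time"] < ev_golive)]
    else:
        bad = ev
    for _, row in bad.iterrows():
        v.append(
            Violation(
                "fired-before-go-live",
                "alert_events",
                str(row["alert_instance_id"]),
                f"alert fired {row['firing_time']} before clinic go-live",
            )
        )

    # --- one alert id, one encounter/patient/kind
    for col in ("encounter_id", "patient_id", "alert_name"):
        spread = ev.groupby("alert_id")[col].nunique()
        for alert_id in spread[spread > 1].index:
            v.append(
                Violation(
                    "episode-shared-identity",
                    "alert_events",
                    str(alert_id),
                    f"instances of alert_id {alert_id!r} disagree on {col}",
                )
            )

    # --- signed orders only on support alerts
    bad = ev[ev["signed_order"].notna() & (ev["alert_name"] != "support")]
    for _, row in bad.iterrows():
        v.append(
            Violation(
                "order-on-nonsupport",
                "alert_events",
                str(row["alert_instance_id"]),
                "signed_order present on a non-support alert event",
            )
        )

    # --- no-response consistency: override reason only with an acknowledgement
    bad = ev[(ev["subsequent_action"] == "none") & ev["override_reason"].notna()]
    for _, row in bad.iterrows():
        v.append(
            Violation(
                "reason-without-action",
                "alert_events",
                str(row["alert_instance_id"]),
                "override_reason recorded but subsequent_action is 'none'",
            )
        )

    # --- vocabulary coverage
    acted = ev[(ev["subsequent_action"] == "acknowledge_override_warning")]
    for _, row in acted.iterrows():
        reason = row["override_reason"]
        if reason is None or not d.vocabulary.covers(str(reason)):
            v.append(
                Violation(
                    "unmapped-override-reason",
                    "alert_events",
                    str(row["alert_instance_id"]),
                    f"override_reason {reason!r} not covered by the vocabulary",
                )
            )

    # --- flowsheet names restricted to the configured screener questions
    bad = fs[~fs["flowsheet_name"].isin(set(d.vocabulary.questions))]
    for _, row in bad.iterrows():
        v.append(
            Violation(
                "unknown-flowsheet-name",
                "flowsheet",
                str(row["flowsheet_name"]),
                f"flowsheet_name {row['flowsheet_name']!r} not in configured questions "
                f"{list(d.vocabulary.questions)}",
            )
        )

    return v
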