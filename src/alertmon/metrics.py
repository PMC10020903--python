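"""Completion, firing-rate and handling-time metrics with stratification.

Three metric families:

* **Completion rate** — encounters in which the alert-prompted action was
  completed over encounters in which the alert fired. Screening completion
  is measured two ways (staff acknowledged completion; EHR documentation of
  the screener answers actually present), support completion likewise
  (discussed treatment options / referral ordered), plus the
  responded-without-postponing and ready-to-quit shares.
* **Firing rate** — total firings over completions in a period: the average
  number of times an alert had to fire per completion. Computed over
  episodes (an encounter-level version is undefined for encounters that
  never complete). Interruptive episodes only by default, since refiring is
  the interruptive mechanism and the quantity measures interruption burden.
* **Handling time** — mean seconds of provider attention per encounter,
  separately over encounters that completed the alert and encounters that
  postponed it at least once (the two sets may overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .episodes import N_WINDOWS, AlertEpisode

#: completion definition -> (numerator flag, denominator flag)
DEFINITIONS: dict[str, tuple[str, str]] = {
    "ack": ("screening_ack_completed", "screening_fired"),
    "documented": ("screening_documented", "screening_fired"),
    "discussion": ("support_discussed", "support_fired"),
    "referral": ("support_referral_ordered", "support_fired"),
    "no_postpone": ("support_no_postpone", "support_fired"),
    "ready_to_quit": ("support_ready_to_quit", "support_fired"),
}

SCREENING_DEFINITIONS = ("ack", "documented")
SUPPORT_DEFINITIONS = ("no_postpone", "discussion", "ready_to_quit", "referral")

#: completion flag used as the handling-time "completed" denominator
COMPLETION_FLAG = {"screening": "screening_ack_completed", "support": "support_discussed"}


class UndefinedRateError(ZeroDivisionError):
    """Requested a rate whose denominator is empty."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.55 stays 0.55, 2.05 -> 2.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateResult:
    definition: str
    numerator: int
    denominator: int
    filter_description: str = "all"

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator

    @property
    def pct(self) -> float:
        return 100.0 * self.rate

    def rounded(self) -> float:
        """Completion rate at the reporting convention (2 decimals)."""
        return round_half_up(self.rate, 2)

    def pct_rounded(self) -> float:
        return round_half_up(self.pct, 1)


@dataclass(frozen=True)
class FiringRateResult:
    fired: int
    completed: int
    scope: str = "overall"

    @property
    def undefined(self) -> bool:
        return self.completed == 0

    @property
    def rate(self) -> float | None:
        return None if self.undefined else self.fired / self.completed

    def rounded(self) -> float | None:
        """Firing rate at the reporting convention (1 decimal)."""
        return None if self.undefined else round_half_up(self.rate, 1)


@dataclass(frozen=True)
class HandlingTimeResult:
    mean_complete_s: float | None
    n_complete_encounters: int
    mean_postpone_s: float | None
    n_postpone_encounters: int

    def rounded(self) -> tuple[int | None, int | None]:
        """(complete, postpone) means at integer seconds."""
        c = None if self.mean_complete_s is None else int(round_half_up(self.mean_complete_s, 0))
        p = None if self.mean_postpone_s is None else int(round_half_up(self.mean_postpone_s, 0))
        return c, p


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int = 1


@dataclass
class TrendTable:
    """Per-(clinic, window) completion rates plus pooled ALL rows."""

    definition: str
    rows: list[tuple[str, int, RateResult]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "clinic_id": clinic,
                "window_index": window,
                "definition": r.definition,
                "numerator": r.numerator,
                "denominator": r.denominator,
                "rate": r.rate,
            }
            for clinic, window, r in self.rows
        ]
        return pd.DataFrame(
            records,
            columns=["clinic_id", "window_index", "definition", "numerator", "denominator", "rate"],
        )


def _apply_filter(
    outcomes: pd.DataFrame, where: Callable[[pd.DataFrame], pd.Series] | pd.Series | None
) -> pd.DataFrame:
    if where is None:
        return outcomes
    mask = where(outcomes) if callable(where) else where
    return outcomes[mask]


def completion_rate(
    outcomes: pd.DataFrame,
    definition: str,
    where: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
    filter_description: str = "all",
) -> RateResult:
    """Encounter-level completion rate under one definition.

    ``outcomes`` is the roll-up frame (``outcomes_to_frame``); ``where`` is
    an optional boolean mask or predicate restricting the encounter set
    (clinic, window, stratum). Raises :class:`UndefinedRateError` when no
    encounter in scope had the relevant alert fire.
    """
    num_flag, den_flag = DEFINITIONS[definition]
    sub = _apply_filter(outcomes, where)
    den = int(sub[den_flag].sum())
    if den == 0:
        raise UndefinedRateError(
            f"completion rate {definition!r} undefined: no fired encounters in scope "
            f"({filter_description})"
        )
    num = int((sub[num_flag] & sub[den_flag]).sum())
    return RateResult(definition, num, den, filter_description)


def completion_trend(
    outcomes: pd.DataFrame,
    definition: str = "ack",
    n_windows: int = N_WINDOWS,
) -> TrendTable:
    """Completion rate per clinic per 3-month window, plus pooled ALL rows.

    Windows are indexed from each clinic's own go-live (already resolved
    into ``window_index`` during roll-up); empty (clinic, window) cells are
    omitted. Window denominators per clinic sum to that clinic's in-horizon
    denominator.
    """
    table = TrendTable(definition=definition)
    _, den_flag = DEFINITIONS[definition]
    fired = outcomes[outcomes[den_flag] & outcomes["window_index"].notna()]
    scopes: list[tuple[str, pd.DataFrame]] = [("ALL", fired)]
    scopes += [(str(c), g) for c, g in fired.groupby("clinic_id", sort=True)]
    for clinic, group in scopes:
        for window in range(n_windows):
            sub = group[group["window_index"] == window]
            if len(sub) == 0:
                continue
            table.rows.append(
                (
                    clinic,
                    window,
                    completion_rate(sub, definition, filter_description=f"{clinic}/window{window}"),
                )
            )
    return table


def firing_rate(
    episodes: Sequence[AlertEpisode],
    kind: str,
    clinic_id: str | None = None,
    interruptive_only: bool = True,
) -> FiringRateResult:
    """Total firings over completed episodes for one alert kind.

    ``interruptive_only`` (default) restricts to interruptive episodes, the
    ones whose refiring constitutes the interruption burden; pass False to
    include passively displayed episodes as well.
    """
    scope = "overall" if clinic_id is None else clinic_id
    eps = [e for e in episodes if e.alert_kind == kind]
    if clinic_id is not None:
        eps = [e for e in eps if e.clinic_id == clinic_id]
    if interruptive_only:
        eps = [e for e in eps if e.modality == "interruptive"]
    fired = sum(e.n_firings for e in eps)
    completed = sum(1 for e in eps if e.completed)
    return FiringRateResult(fired=fired, completed=completed, scope=scope)


def handling_time(
    outcomes: pd.DataFrame,
    kind: str,
    aggregation: str = "encounter_sum",
    episodes: Sequence[AlertEpisode] | None = None,
) -> HandlingTimeResult:
    """Mean seconds spent completing / postponing the alert per encounter.

    The completing mean averages over encounters where the alert was
    completed (screening: acknowledged; support: discussed); the postponing
    mean over encounters where it was postponed at least once. The sets may
    overlap: an alert deferred twice and then completed contributes to both.

    ``aggregation='encounter_sum'`` (default) sums a provider's seconds
    within the encounter before averaging; ``'instance'`` instead averages
    raw per-instance durations (responding instances for the completing
    mean, defer instances for the postponing mean) and needs ``episodes``.
    """
    if aggregation == "instance":
        if episodes is None:
            raise ValueError("aggregation='instance' requires the episode list")
        eps = [e for e in episodes if e.alert_kind == kind]
        complete = [
            i.duration_s
            for e in eps
            if e.completed
            for i in e.instances
            if i.responded and i.duration_s is not None
        ]
        postpone = [
            i.duration_s
            for e in eps
            for i in e.instances
            if i.deferred and i.duration_s is not None
        ]
        return HandlingTimeResult(
            mean_complete_s=float(np.mean(complete)) if complete else None,
            n_complete_encounters=len(complete),
            mean_postpone_s=float(np.mean(postpone)) if postpone else None,
            n_postpone_encounters=len(postpone),
        )
    if aggregation != "encounter_sum":
        raise ValueError(f"unknown aggregation {aggregation!r}")

    flag = COMPLETION_FLAG[kind]
    time_col = f"{kind}_complete_time_s"
    postpone_col = f"{kind}_postpone_time_s"
    defer_flag = f"{kind}_deferred_any"
    completing = outcomes[outcomes[flag] & outcomes[time_col].notna()]
    postponing = outcomes[outcomes[defer_flag] & outcomes[postpone_col].notna()]
    return HandlingTimeResult(
        mean_complete_s=float(completing[time_col].mean()) if len(completing) else None,
        n_complete_encounters=int(len(completing)),
        mean_postpone_s=float(postponing[postpone_col].mean()) if len(postponing) else None,
        n_postpone_encounters=int(len(postponing)),
    )


def stratify_completion(
    outcomes: pd.DataFrame,
    definition: str,
    keys: Sequence[str],
) -> pd.DataFrame:
    """Completion rate per observed combination of stratification keys.

    ``keys`` is a non-empty subset of {sex, race, relevance, clinic_id}.
    Stratum numerators and denominators partition the overall counts.
    """
    if not keys:
        raise ValueError("stratify_completion requires at least one key")
    allowed = {"sex", "race", "relevance", "clinic_id"}
    bad = set(keys) - allowed
    if bad:
        raise ValueError(f"unknown stratification key(s) {sorted(bad)}; allowed: {sorted(allowed)}")
    _, den_flag = DEFINITIONS[definition]
    fired = outcomes[outcomes[den_flag]]
    records = []
    for values, group in fired.groupby(list(keys), sort=True):
        if not isinstance(values, tuple):
            values = (values,)
        r = completion_rate(group, definition, filter_description="×".join(map(str, values)))
        rec = dict(zip(keys, map(str, values)))
        rec.update(
            definition=definition,
            numerator=r.numerator,
            denominator=r.denominator,
            rate=r.rate,
        )
        records.append(rec)
    return pd.DataFrame(records, columns=[*keys, "definition", "numerator", "denominator", "rate"])


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pearson chi-square (df 1, no continuity correction) on a 2x2 table.

    Two-sided p. A degenerate pooled margin (all successes or all failures)
    yields statistic 0 and p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError(f"invalid proportion counts x={x}, n={n}")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
    if (table.sum(axis=0) == 0).any():
        return TestResult(statistic=0.0, p_value=1.0)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p))


def fired_encounters(outcomes: pd.DataFrame, kind: str) -> int:
    return int(outcomes[f"{kind}_fired"].sum())


def modality_share(outcomes: pd.DataFrame, definition: str = "ack") -> tuple[RateResult, RateResult]:
    """Among completions, the interruptive and noninterruptive shares.

    Completion-episode modality is taken from the encounter's screening (or
    support) interruptive flag; returns (interruptive, noninterruptive)
    rate results with the completion count as denominator.
    """
    num_flag, _ = DEFINITIONS[definition]
    kind = "screening" if definition in SCREENING_DEFINITIONS else "support"
    completed = outcomes[outcomes[num_flag]]
    n = len(completed)
    if n == 0:
        raise UndefinedRateError(f"no completed encounters for {definition!r}")
    inter = int(completed[f"{kind}_interruptive"].sum())
    return (
        RateResult("modality_interruptive", inter, n, definition),
        RateResult("modality_noninterruptive", n - inter, n, definition),
    )


def metrics_frame(results: Iterable[Mapping]) -> pd.DataFrame:
    """Tidy one-row-per-metric frame with numerator/denominator provenance."""
    return pd.DataFrame(
        list(results),
        columns=["metric", "scope", "window_index", "stratum", "numerator", "denominator", "value"],
    )
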