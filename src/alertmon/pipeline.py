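"""End-to-end orchestration: dataset -> episodes -> outcomes -> summary.

``run_pipeline`` performs the reconstruction; ``summarize`` computes every
metric family into one nested, JSON-serializable summary with full
numerator/denominator provenance. ``summarize_ground_truth`` computes the
same summary straight from a simulator ground-truth ledger, bypassing event
reconstruction entirely — the two must agree exactly on simulator output,
which is the pipeline's core correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .episodes import AlertEpisode, EncounterOutcome, build_episodes, outcomes_to_frame, rollup_encounters
from .event_model import Dataset
from .metrics import (
    SCREENING_DEFINITIONS,
    SUPPORT_DEFINITIONS,
    FiringRateResult,
    UndefinedRateError,
    completion_rate,
    completion_trend,
    firing_rate,
    handling_time,
    modality_share,
    round_half_up,
    stratify_completion,
    two_proportion_test,
)


@dataclass
class PipelineResult:
    episodes: list[AlertEpisode]
    outcomes: list[EncounterOutcome]
    frame: pd.DataFrame


def load_relevance_map(path) -> dict[str, str]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    bad = {k: v for k, v in doc.items() if v not in {"relevant", "less_relevant"}}
    if bad:
        raise ValueError(f"relevance map values must be relevant/less_relevant: {bad}")
    return {str(k): str(v) for k, v in doc.items()}


def run_pipeline(d: Dataset, relevance_map: Mapping[str, str]) -> PipelineResult:
    episodes = build_episodes(d)
    outcomes = rollup_encounters(episodes, d, relevance_map)
    return PipelineResult(episodes=episodes, outcomes=outcomes, frame=outcomes_to_frame(outcomes))


def _rate_entry(r) -> dict:
    return {
        "numerator": r.numerator,
        "denominator": r.denominator,
        "rate": r.rate,
        "rate_rounded": r.rounded(),
        "pct_rounded": r.pct_rounded(),
    }


def _firing_entry(fr: FiringRateResult) -> dict:
    return {
        "fired": fr.fired,
        "completed": fr.completed,
        "undefined": fr.undefined,
        "rate": fr.rate,
        "rate_rounded": fr.rounded(),
    }


def _clinic_firing_rates(
    episodes: Sequence[AlertEpisode], kind: str, interruptive_only: bool
) -> dict[str, dict]:
    clinics = sorted({e.clinic_id for e in episodes if e.alert_kind == kind})
    return {
        c: _firing_entry(firing_rate(episodes, kind, clinic_id=c, interruptive_only=interruptive_only))
        for c in clinics
    }


def summarize(
    frame: pd.DataFrame,
    episodes: Sequence[AlertEpisode] | None = None,
    interruptive_only: bool = True,
) -> dict:
    """Nested metric summary from the outcome frame (and episodes, if
    firing rates are wanted). Omits a whole alert block when that alert
    never fired; rounded values follow the reporting conventions
    (completion rates 2 dp, percentages 1 dp, firing rates 1 dp,
    handling times integer seconds)."""
    out: dict = {}
    if frame["screening_fired"].any():
        block: dict = {"fired_encounters": int(frame["screening_fired"].sum())}
        block["completion"] = {
            d: _rate_entry(completion_rate(frame, d)) for d in SCREENING_DEFINITIONS
        }
        try:
            inter, noninter = modality_share(frame, "ack")
            block["modality_share_of_ack"] = {
                "interruptive": _rate_entry(inter),
                "noninterruptive": _rate_entry(noninter),
            }
        except UndefinedRateError:
            pass  # no completions anywhere: no modality split to report
        ht = handling_time(frame, "screening")
        c, p = ht.rounded()
        block["handling_time_s"] = {
            "mean_complete_s": ht.mean_complete_s,
            "mean_complete_s_rounded": c,
            "n_complete_encounters": ht.n_complete_encounters,
            "mean_postpone_s": ht.mean_postpone_s,
            "mean_postpone_s_rounded": p,
            "n_postpone_encounters": ht.n_postpone_encounters,
        }
        if episodes is not None:
            block["firing_rate"] = {
                "overall": _firing_entry(
                    firing_rate(episodes, "screening", interruptive_only=interruptive_only)
                ),
                "by_clinic": _clinic_firing_rates(episodes, "screening", interruptive_only),
            }
        out["screening"] = block

    if frame["support_fired"].any():
        block = {"fired_encounters": int(frame["support_fired"].sum())}
        block["completion"] = {
            d: _rate_entry(completion_rate(frame, d)) for d in SUPPORT_DEFINITIONS
        }
        ht = handling_time(frame, "support")
        c, p = ht.rounded()
        block["handling_time_s"] = {
            "mean_complete_s": ht.mean_complete_s,
            "mean_complete_s_rounded": c,
            "mean_postpone_s": ht.mean_postpone_s,
            "mean_postpone_s_rounded": p,
            "n_complete_encounters": ht.n_complete_encounters,
            "n_postpone_encounters": ht.n_postpone_encounters,
        }
        if episodes is not None:
            block["firing_rate"] = {
                "overall": _firing_entry(
                    firing_rate(episodes, "support", interruptive_only=interruptive_only)
                ),
                "by_clinic": _clinic_firing_rates(episodes, "support", interruptive_only),
            }
        out["support"] = block

    if frame["screening_fired"].any() and frame["relevance"].notna().any():
        strata = stratify_completion(frame, "ack", ["relevance"]).set_index("relevance")
        rel_block: dict = {}
        for label in ("relevant", "less_relevant"):
            if label in strata.index:
                row = strata.loc[label]
                rel_block[label] = {
                    "numerator": int(row["numerator"]),
                    "denominator": int(row["denominator"]),
                    "rate": float(row["rate"]),
                    "pct_rounded": round_half_up(100 * float(row["rate"]), 1),
                }
        if "relevant" in rel_block:
            total = int(frame["screening_fired"].sum())
            rel_block["share_relevant_pct"] = round_half_up(
                100.0 * rel_block["relevant"]["denominator"] / total, 1
            )
        if {"relevant", "less_relevant"} <= rel_block.keys():
            t = two_proportion_test(
                rel_block["relevant"]["numerator"],
                rel_block["relevant"]["denominator"],
                rel_block["less_relevant"]["numerator"],
                rel_block["less_relevant"]["denominator"],
            )
            rel_block["test"] = {"chi2": t.statistic, "df": t.df, "p_value": t.p_value}
        out["relevance"] = rel_block
    return out


def summarize_ground_truth(ledger: pd.DataFrame, interruptive_only: bool = True) -> dict:
    """The same summary computed directly from a simulator's truth ledger.

    Episode-level quantities (firing rates) come from the ledger's own
    per-encounter firing counts; nothing here touches the emitted events.
    """
    out = summarize(ledger, episodes=None)
    for kind in ("screening", "support"):
        if kind not in out:
            continue
        sub = ledger[ledger[f"{kind}_fired"]]
        if interruptive_only:
            sub = sub[sub[f"{kind}_interruptive"]]
        completed_flag = "screening_ack_completed" if kind == "screening" else "support_discussed"
        overall = FiringRateResult(
            fired=int(sub[f"{kind}_n_firings"].sum()), completed=int(sub[completed_flag].sum())
        )
        by_clinic = {}
        for clinic, group in sub.groupby("clinic_id", sort=True):
            by_clinic[str(clinic)] = _firing_entry(
                FiringRateResult(
                    fired=int(group[f"{kind}_n_firings"].sum()),
                    completed=int(group[completed_flag].sum()),
                    scope=str(clinic),
                )
            )
        out[kind]["firing_rate"] = {"overall": _firing_entry(overall), "by_clinic": by_clinic}
    return out


def tidy_metrics(frame: pd.DataFrame, episodes: Sequence[AlertEpisode]) -> pd.DataFrame:
    """One-row-per-metric tidy table with provenance columns."""
    rows: list[dict] = []

    def add(metric, scope, window, stratum, num, den, value):
        rows.append(
            {
                "metric": metric,
                "scope": scope,
                "window_index": window,
                "stratum": stratum,
                "numerator": num,
                "denominator": den,
                "value": value,
            }
        )

    for kind, defs in (("screening", SCREENING_DEFINITIONS), ("support", SUPPORT_DEFINITIONS)):
        if not frame[f"{kind}_fired"].any():
            continue
        for d in defs:
            r = completion_rate(frame, d)
            add(f"completion_{d}", "ALL", None, None, r.numerator, r.denominator, r.rate)
            trend = completion_trend(frame, d)
            for clinic, window, rr in trend.rows:
                add(f"completion_{d}", clinic, window, None, rr.numerator, rr.denominator, rr.rate)
        fr = firing_rate(episodes, kind)
        add(f"firing_rate_{kind}", "ALL", None, None, fr.fired, fr.completed, fr.rate)
        for clinic, entry in _clinic_firing_rates(episodes, kind, True).items():
            add(
                f"firing_rate_{kind}",
                clinic,
                None,
                None,
                entry["fired"],
                entry["completed"],
                entry["rate"],
            )
        ht = handling_time(frame, kind)
        add(
            f"handling_complete_{kind}_s",
            "ALL",
            None,
            None,
            None,
            ht.n_complete_encounters,
            ht.mean_complete_s,
        )
        add(
            f"handling_postpone_{kind}_s",
            "ALL",
            None,
            None,
            None,
            ht.n_postpone_encounters,
            ht.mean_postpone_s,
        )
    if frame["screening_fired"].any():
        for keys in (["relevance"], ["sex"], ["race"], ["sex", "race"]):
            try:
                table = stratify_completion(frame, "ack", keys)
            except UndefinedRateError:
                continue
            for _, row in table.iterrows():
                stratum = "×".join(f"{k}={row[k]}" for k in keys)
                add(
                    "completion_ack",
                    "ALL",
                    None,
                    stratum,
                    int(row["numerator"]),
                    int(row["denominator"]),
                    float(row["rate"]),
                )
    return pd.DataFrame(
        rows, columns=["metric", "scope", "window_index", "stratum", "numerator", "denominator", "value"]
    )
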