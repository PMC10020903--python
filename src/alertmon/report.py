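"""Monitoring report: per-clinic trend tables with deviation flags.

A clinic is flagged in a window when its completion rate deviates from the
pooled all-clinic rate of that window by more than an absolute threshold
(default 0.15) — a screen for sites whose alert adoption has drifted and
may need local adaptation, not a formal test.
"""

from __future__ import annotations

import pandas as pd

DEFAULT_DEVIATION_THRESHOLD = 0.15


def deviation_flags(trend: pd.DataFrame, threshold: float = DEFAULT_DEVIATION_THRESHOLD) -> pd.DataFrame:
    """Rows of (clinic, window, clinic rate, pooled rate, deviation) flagged.

    ``trend`` is a trend table frame (clinic_id / window_index / definition /
    numerator / denominator / rate) containing pooled ``ALL`` rows.
    """
    pooled = (
        trend[trend["clinic_id"] == "ALL"]
        .set_index(["definition", "window_index"])["rate"]
        .to_dict()
    )
    rows = []
    clinics = trend[trend["clinic_id"] != "ALL"]
    for _, row in clinics.iterrows():
        key = (row["definition"], row["window_index"])
        if key not in pooled:
            continue
        deviation = float(row["rate"]) - float(pooled[key])
        if abs(deviation) > threshold:
            rows.append(
                {
                    "clinic_id": row["clinic_id"],
                    "window_index": row["window_index"],
                    "definition": row["definition"],
                    "clinic_rate": float(row["rate"]),
                    "pooled_rate": float(pooled[key]),
                    "deviation": deviation,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["clinic_id", "window_index", "definition", "clinic_rate", "pooled_rate", "deviation"],
    )


def render_report(trend: pd.DataFrame, flags: pd.DataFrame, threshold: float) -> str:
    lines = ["# Alert completion monitoring report", ""]
    for definition, group in trend.groupby("definition", sort=True):
        lines.append(f"## Completion ({definition}) by clinic and 3-month window")
        pivot = group.pivot_table(
            index="clinic_id", columns="window_index", values="rate", aggfunc="first"
        )
        lines.append(pivot.round(3).to_string())
        lines.append("")
    lines.append(f"## Deviation flags (|clinic - pooled| > {threshold:g})")
    if len(flags) == 0:
        lines.append("none")
    else:
        for _, f in flags.iterrows():
            lines.append(
                f"- {f['clinic_id']} window {int(f['window_index'])} ({f['definition']}): "
                f"clinic {f['clinic_rate']:.3f} vs pooled {f['pooled_rate']:.3f} "
                f"({f['deviation']:+.3f})"
            )
    lines.append("")
    return "\n".join(lines)
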