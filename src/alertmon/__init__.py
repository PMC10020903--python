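"""EHR activity metrics for monitoring clinical decision support alerts.

Reconstructs alert episodes from EHR event logs of two tobacco-cessation
decision-support alerts (a screening alert and a conditional support
alert), computes completion and burden metrics — completion rate under
several definitions, firing rate, handling time — with temporal, clinic,
relevance and demographic stratification, and ships a synthetic event-log
generator so the whole pipeline is testable without real EHR data.
"""

from importlib import resources

from .calibration import CalibrationCounts, ConsistencyError, expand_calibration
from .episodes import (
    AlertEpisode,
    AlertInstance,
    EncounterOutcome,
    build_episodes,
    determine_modality,
    documentation_complete,
    outcomes_to_frame,
    rollup_encounters,
    window_index,
)
from .event_model import (
    ActionVocabulary,
    Dataset,
    SchemaError,
    Violation,
    VocabularyError,
    read_dataset,
    validate_dataset,
    write_dataset,
)
from .metrics import (
    FiringRateResult,
    HandlingTimeResult,
    RateResult,
    TestResult,
    TrendTable,
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
from .pipeline import (
    load_relevance_map,
    run_pipeline,
    summarize,
    summarize_ground_truth,
    tidy_metrics,
)
from .report import deviation_flags, render_report
from .simulate import (
    ClinicSimConfig,
    DurationModel,
    GroundTruth,
    SimConfig,
    conditional_firing_check,
    simulate,
)

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path-like handle to a packaged config file (e.g. ``calibration.yaml``)."""
    return resources.files("alertmon.data").joinpath(name)


__all__ = [
    "ActionVocabulary",
    "AlertEpisode",
    "AlertInstance",
    "CalibrationCounts",
    "ClinicSimConfig",
    "ConsistencyError",
    "Dataset",
    "DurationModel",
    "EncounterOutcome",
    "FiringRateResult",
    "GroundTruth",
    "HandlingTimeResult",
    "RateResult",
    "SchemaError",
    "SimConfig",
    "TestResult",
    "TrendTable",
    "UndefinedRateError",
    "Violation",
    "VocabularyError",
    "build_episodes",
    "completion_rate",
    "completion_trend",
    "conditional_firing_check",
    "determine_modality",
    "deviation_flags",
    "documentation_complete",
    "expand_calibration",
    "firing_rate",
    "handling_time",
    "load_relevance_map",
    "modality_share",
    "outcomes_to_frame",
    "packaged_data",
    "read_dataset",
    "render_report",
    "rollup_encounters",
    "round_half_up",
    "run_pipeline",
    "simulate",
    "stratify_completion",
    "summarize",
    "summarize_ground_truth",
    "tidy_metrics",
    "two_proportion_test",
    "validate_dataset",
    "window_index",
    "write_dataset",
]
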