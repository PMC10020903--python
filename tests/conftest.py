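from pathlib import Path

import numpy as np
import pytest

from alertmon import (
    CalibrationCounts,
    ClinicSimConfig,
    SimConfig,
    expand_calibration,
    packaged_data,
    read_dataset,
    run_pipeline,
    simulate,
    summarize,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy10():
    """Hand-authored fixture: 10 encounters, 14 alert events, 6 flowsheet rows."""
    return read_dataset(DATA_DIR / "toy10")


@pytest.fixture(scope="session")
def toy10_result(toy10):
    relevance = {"office_visit": "relevant", "lab_visit": "less_relevant"}
    return run_pipeline(toy10, relevance)


@pytest.fixture(scope="session")
def calibration_counts():
    return CalibrationCounts.from_yaml(packaged_data("calibration.yaml"))


@pytest.fixture(scope="session")
def calibration_dataset(calibration_counts):
    return expand_calibration(calibration_counts)


@pytest.fixture(scope="session")
def calibration_summary(calibration_counts, calibration_dataset):
    result = run_pipeline(calibration_dataset, calibration_counts.relevance_map())
    return result, summarize(result.frame, result.episodes)


def small_sim_config(seed: int, n_encounters: int = 400, **overrides) -> SimConfig:
    clinic = ClinicSimConfig(
        clinic_id="C1",
        go_live_date="2024-01-01",
        n_encounters=n_encounters,
        **overrides,
    )
    return SimConfig(clinics=[clinic], seed=seed)


def random_sim_config(seed: int) -> SimConfig:
    """A randomized, non-degenerate simulator configuration."""
    rng = np.random.default_rng(seed)
    clinics = []
    for c in range(int(rng.integers(1, 3))):
        p_ack = float(rng.uniform(0.25, 0.85))
        clinics.append(
            ClinicSimConfig(
                clinic_id=f"C{c + 1}",
                go_live_date="2024-01-01",
                n_encounters=int(rng.integers(150, 450)),
                alerts_implemented=["screening", "support"] if c == 0 else ["screening"],
                p_ack_complete=p_ack,
                p_not_appropriate=float(rng.uniform(0.0, min(0.15, 0.95 - p_ack))),
                p_document_given_ack=float(rng.uniform(0.3, 0.95)),
                p_interruptive=float(rng.uniform(0.5, 0.95)),
                p_stop=float(rng.uniform(0.35, 0.9)),
                p_support_respond_no_postpone=float(rng.uniform(0.6, 0.95)),
                p_discussed=float(rng.uniform(0.4, 0.9)),
                p_ready_given_discussed=float(rng.uniform(0.1, 0.4)),
                p_referral_given_ready=float(rng.uniform(0.1, 0.5)),
            )
        )
    return SimConfig(clinics=clinics, seed=int(rng.integers(0, 2**31 - 1)))


@pytest.fixture(scope="session")
def sim_medium():
    """One simulated dataset with both alerts, reused across tests."""
    config = small_sim_config(seed=11, n_encounters=1500)
    dataset, truth = simulate(config)
    return config, dataset, truth
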