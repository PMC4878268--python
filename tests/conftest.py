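import numpy as np
import pytest
from hypothesis import settings

from calclust import (
    Epoch,
    Protocol,
    TraceDataset,
    default_protocol,
    extract_features,
    generate_dataset,
    paperlike_preset,
    qc_filter,
)
from calclust.preprocess import apply_qc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def toy_protocol() -> Protocol:
    """Minute-resolution miniature of the glucose/KCl protocol."""
    return Protocol(
        epochs=(
            Epoch("low_glucose", 0, 4),
            Epoch("high_glucose", 4, 10),
            Epoch("low_glucose", 10, 13),
            Epoch("kcl", 13, 16),
            Epoch("low_glucose", 16, 18),
        )
    )


@pytest.fixture
def toy_times() -> np.ndarray:
    return np.arange(18.0)


@pytest.fixture
def toy_trace() -> np.ndarray:
    """Hand-computable cell: baseline 1, square-wave high-glucose, KCl 3.

    Baseline median 1, N = 2; high-glucose median 1.5, MAD 0.5; peaks at
    t = 5, 7, 9; second-low minimum 1.0.
    """
    return np.array(
        [1, 1, 1, 1, 1, 2, 1, 2, 1, 2, 1.2, 1.0, 1.1, 3, 3, 3, 1, 1], dtype=float
    )


def make_dataset(values, times, field_ids=None) -> TraceDataset:
    values = np.atleast_2d(np.asarray(values, float))
    n = values.shape[0]
    return TraceDataset(
        cell_ids=[f"c{i + 1}" for i in range(n)],
        field_ids=field_ids or ["f1"] * n,
        times=np.asarray(times, float),
        values=values,
    )


@pytest.fixture(scope="session")
def preset_run():
    """One paperlike simulated run taken through QC and feature extraction."""
    protocol = default_protocol()
    dataset, labels = generate_dataset(paperlike_preset(), seed=1)
    report = qc_filter(dataset, protocol)
    kept = apply_qc(dataset, report)
    kept_set = set(report.kept_ids)
    features = extract_features(kept, protocol)
    truth = [l for c, l in zip(dataset.cell_ids, labels) if c in kept_set]
    return {
        "protocol": protocol,
        "dataset": dataset,
        "labels": labels,
        "report": report,
        "kept": kept,
        "features": features,
        "truth_kept": np.array(truth),
    }
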