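"""Per-cell Ca2+ response features.

Nine features summarise each cell's response to the glucose/KCl protocol.
All magnitudes are differences from the cell's baseline (median signal in
the first low-glucose epoch) normalised by that cell's median KCl response
above baseline, N = median(KCl epoch) - baseline.  Because N also sets the
peak-detection threshold (N/3), every feature is invariant under an affine
rescaling of the trace (a*x + b with a > 0) — per-cell dye loading and gain
differences cancel.

The features, in the fixed column order used throughout:

=============================  =============================================
``high_glucose_response``      (median high-glucose signal - baseline) / N
``high_glucose_oscillation``   MAD of high-glucose samples / N
``low_glucose_oscillation_pre``   MAD of the first low-glucose epoch / N
``low_glucose_oscillation_post``  MAD of the second low-glucose epoch / N
``response_speed``             1 / (time to first high-glucose peak), 1/min
``counted_peaks``              number of qualifying high-glucose local maxima
``oscillation_frequency``      1 / mean inter-peak interval, 1/min
``return_to_baseline``         (min of second low-glucose epoch - baseline)/N
``kcl_response``               (max KCl signal - baseline) / N  (>= 1)
=============================  =============================================

MAD is the raw median absolute deviation from the epoch median (no
normal-consistency constant).  A local maximum qualifies as a counted peak
when it rises at least N/3 above its surroundings (topographic prominence
within the epoch, the default) or, in the alternative height modes, when it
sits at least N/3 above the cell's baseline or the epoch median.  Plateaus
of tied samples contribute a single peak at their first sample, and an
epoch endpoint counts when it exceeds its single interior neighbour.
Degenerate cases never produce NaN: with no peaks, ``response_speed`` and
``oscillation_frequency`` are 0; with a single peak, the frequency is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HIGH_GLUCOSE, KCL, LOW_GLUCOSE, Protocol, TraceDataset
from .preprocess import baseline_stat, correct_dataset

FEATURE_NAMES = (
    "high_glucose_response",
    "high_glucose_oscillation",
    "low_glucose_oscillation_pre",
    "low_glucose_oscillation_post",
    "response_speed",
    "counted_peaks",
    "oscillation_frequency",
    "return_to_baseline",
    "kcl_response",
)


@dataclass(frozen=True)
class PeakSet:
    """Qualifying local maxima of one epoch of one trace."""

    peak_times: np.ndarray  # minutes, strictly increasing
    peak_heights: np.ndarray  # ratio units above the height reference
    threshold: float  # minimum qualifying height

    def __len__(self) -> int:
        return len(self.peak_times)


def _epoch_samples(
    trace: np.ndarray, times: np.ndarray, protocol: Protocol, label: str, occurrence: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    epoch = protocol.find(label, occurrence)
    mask = epoch.contains(np.asarray(times, float))
    if not mask.any():
        raise ValueError(f"no samples in epoch {label!r} (occurrence {occurrence})")
    return np.asarray(times, float)[mask], np.asarray(trace, float)[mask]


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def kcl_norm(trace: np.ndarray, times: np.ndarray, protocol: Protocol) -> float:
    """Median KCl signal above baseline, N — the per-cell normaliser.

    Raises if N <= 0: such a cell does not respond to depolarization and
    should have been removed by QC before feature extraction.
    """
    b = baseline_stat(trace, times, protocol)
    _, kcl = _epoch_samples(trace, times, protocol, KCL)
    n = float(np.median(kcl) - b)
    if n <= 0:
        raise ValueError(
            f"median KCl response above baseline is {n:.4g} <= 0; cell fails QC"
        )
    return n


def high_glucose_response(trace: np.ndarray, times: np.ndarray, protocol: Protocol) -> float:
    """Median high-glucose signal above baseline, as a fraction of N."""
    b = baseline_stat(trace, times, protocol)
    n = kcl_norm(trace, times, protocol)
    _, hg = _epoch_samples(trace, times, protocol, HIGH_GLUCOSE)
    return float((np.median(hg) - b) / n)


def oscillation_magnitude(
    trace: np.ndarray,
    times: np.ndarray,
    protocol: Protocol,
    epoch_label: str = HIGH_GLUCOSE,
    occurrence: int = 1,
) -> float:
    """MAD of the epoch's samples as a fraction of N."""
    n = kcl_norm(trace, times, protocol)
    _, seg = _epoch_samples(trace, times, protocol, epoch_label, occurrence)
    return float(_mad(seg) / n)


def _local_maxima_runs(x: np.ndarray) -> list[int]:
    """Indices of local maxima, one per plateau (first sample of the run).

    A run of tied samples is a maximum when it exceeds both neighbouring
    runs; a boundary run qualifies by exceeding its single neighbour.  A
    constant segment (single run) has no maxima.
    """
    run_starts = [0]
    for i in range(1, len(x)):
        if x[i] != x[run_starts[-1]]:
            run_starts.append(i)
    if len(run_starts) == 1:
        return []
    vals = [x[s] for s in run_starts]
    out = []
    for k, s in enumerate(run_starts):
        left_ok = k == 0 or vals[k] > vals[k - 1]
        right_ok = k == len(run_starts) - 1 or vals[k] > vals[k + 1]
        if left_ok and right_ok:
            out.append(s)
    return out


def _prominence(seg: np.ndarray, i: int) -> float:
    """Topographic prominence of a local maximum within the segment.

    Walk outwards from the peak on each side until a strictly higher sample
    (or the segment edge) is met; the base on that side is the lowest sample
    encountered.  The prominence is the peak value minus the higher base.
    """
    v = seg[i]
    bases = []
    for step in (-1, 1):
        j = i + step
        base = None
        while 0 <= j < len(seg) and seg[j] <= v:
            base = seg[j] if base is None else min(base, seg[j])
            j += step
        if base is not None:
            bases.append(base)
    return float(v - max(bases)) if bases else 0.0


def detect_peaks(
    trace: np.ndarray,
    times: np.ndarray,
    protocol: Protocol,
    epoch_label: str = HIGH_GLUCOSE,
    occurrence: int = 1,
    qualification: str = "prominence",
) -> PeakSet:
    """Qualifying local maxima within one epoch.

    A candidate local maximum is a true peak when it clears one third of the
    KCl-to-baseline signal difference, N/3.  With the default
    ``qualification="prominence"`` the peak's topographic prominence within
    the epoch must reach N/3, which rejects measurement-noise jitter riding
    on an elevated plateau; ``"above_baseline"`` and ``"above_epoch_median"``
    instead require the peak to sit N/3 above the cell's baseline or the
    epoch median respectively.
    """
    if qualification not in {"prominence", "above_baseline", "above_epoch_median"}:
        raise ValueError(f"unknown qualification {qualification!r}")
    b = baseline_stat(trace, times, protocol)
    n = kcl_norm(trace, times, protocol)
    t_seg, seg = _epoch_samples(trace, times, protocol, epoch_label, occurrence)
    threshold = n / 3.0
    candidates = _local_maxima_runs(seg)
    if qualification == "prominence":
        heights = {i: _prominence(seg, i) for i in candidates}
    else:
        ref = b if qualification == "above_baseline" else float(np.median(seg))
        heights = {i: float(seg[i] - ref) for i in candidates}
    idx = [i for i in candidates if heights[i] >= threshold]
    return PeakSet(
        peak_times=t_seg[idx],
        peak_heights=np.array([heights[i] for i in idx]),
        threshold=threshold,
    )


def counted_peaks(
    trace: np.ndarray, times: np.ndarray, protocol: Protocol, qualification: str = "prominence"
) -> int:
    """Number of qualifying local maxima during high-glucose exposure."""
    return len(detect_peaks(trace, times, protocol, qualification=qualification))


def _median_dt(times: np.ndarray) -> float:
    return float(np.median(np.diff(np.asarray(times, float))))


def response_speed(
    trace: np.ndarray, times: np.ndarray, protocol: Protocol, qualification: str = "prominence"
) -> float:
    """Inverse time (1/min) from high-glucose onset to the first peak.

    0 when no peak is detected; when the very first epoch sample is itself
    the peak, the latency is taken as one median sampling interval so the
    speed stays finite.
    """
    peaks = detect_peaks(trace, times, protocol, qualification=qualification)
    if len(peaks) == 0:
        return 0.0
    start = protocol.find(HIGH_GLUCOSE, 1).start
    dt = float(peaks.peak_times[0]) - start
    if dt <= 0:
        dt = _median_dt(times)
    return float(1.0 / dt)


def oscillation_frequency(
    trace: np.ndarray, times: np.ndarray, protocol: Protocol, qualification: str = "prominence"
) -> float:
    """Mean oscillation frequency (1/min) from high-glucose peak periodicity.

    The reciprocal of the mean inter-peak interval; 0 with fewer than two
    peaks.
    """
    peaks = detect_peaks(trace, times, protocol, qualification=qualification)
    if len(peaks) < 2:
        return 0.0
    return float(1.0 / np.mean(np.diff(peaks.peak_times)))


def return_to_baseline(trace: np.ndarray, times: np.ndarray, protocol: Protocol) -> float:
    """Minimum of the second low-glucose epoch above baseline, over N.

    Negative values are allowed (undershoot below baseline).
    """
    b = baseline_stat(trace, times, protocol)
    n = kcl_norm(trace, times, protocol)
    _, seg = _epoch_samples(trace, times, protocol, LOW_GLUCOSE, occurrence=2)
    return float((np.min(seg) - b) / n)


def kcl_response_feature(trace: np.ndarray, times: np.ndarray, protocol: Protocol) -> float:
    """Maximum KCl signal above baseline over N; >= 1 since max >= median."""
    b = baseline_stat(trace, times, protocol)
    n = kcl_norm(trace, times, protocol)
    _, seg = _epoch_samples(trace, times, protocol, KCL)
    return float((np.max(seg) - b) / n)


def extract_cell_features(
    trace: np.ndarray,
    times: np.ndarray,
    protocol: Protocol,
    qualification: str = "prominence",
) -> dict[str, float]:
    """All nine features of one (QC-passing, already corrected) trace."""
    return {
        "high_glucose_response": high_glucose_response(trace, times, protocol),
        "high_glucose_oscillation": oscillation_magnitude(trace, times, protocol, HIGH_GLUCOSE),
        "low_glucose_oscillation_pre": oscillation_magnitude(
            trace, times, protocol, LOW_GLUCOSE, occurrence=1
        ),
        "low_glucose_oscillation_post": oscillation_magnitude(
            trace, times, protocol, LOW_GLUCOSE, occurrence=2
        ),
        "response_speed": response_speed(trace, times, protocol, qualification=qualification),
        "counted_peaks": float(counted_peaks(trace, times, protocol, qualification=qualification)),
        "oscillation_frequency": oscillation_frequency(trace, times, protocol, qualification=qualification),
        "return_to_baseline": return_to_baseline(trace, times, protocol),
        "kcl_response": kcl_response_feature(trace, times, protocol),
    }


def extract_features(
    dataset: TraceDataset,
    protocol: Protocol,
    drift_correct: bool = True,
    qualification: str = "prominence",
) -> pd.DataFrame:
    """Feature table for every cell of a QC-filtered dataset.

    Returns a DataFrame with columns ``cell_id``, ``field_id`` and the nine
    features in fixed order.  Traces are drift-corrected first unless
    ``drift_correct=False`` (raw-data mode).  Per-cell failures are
    re-raised with the offending cell id attached.
    """
    work = dataset
    if drift_correct:
        work, _ = correct_dataset(dataset, protocol)
    rows = []
    for i, cid in enumerate(work.cell_ids):
        try:
            feats = extract_cell_features(work.values[i], work.times, protocol, qualification=qualification)
        except ValueError as exc:
            raise ValueError(f"cell {cid!r}: {exc}") from exc
        rows.append({"cell_id": cid, "field_id": work.field_ids[i], **feats})
    df = pd.DataFrame(rows, columns=["cell_id", "field_id", *FEATURE_NAMES])
    df["counted_peaks"] = df["counted_peaks"].astype(int)
    return df


__all__ = [
    "FEATURE_NAMES",
    "PeakSet",
    "kcl_norm",
    "high_glucose_response",
    "oscillation_magnitude",
    "detect_peaks",
    "counted_peaks",
    "response_speed",
    "oscillation_frequency",
    "return_to_baseline",
    "kcl_response_feature",
    "extract_cell_features",
    "extract_features",
]
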