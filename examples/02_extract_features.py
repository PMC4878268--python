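"""Extract the nine Ca2+ response features and inspect them by sub-type.

Each cell is summarised by nine dimensionless numbers: its median
high-glucose elevation, oscillation magnitudes (MAD) in three epochs, the
speed to its first glucose-driven peak, peak count and oscillation
frequency, how completely it returns to baseline, and its peak KCl
response.  All magnitudes are normalised by the cell's own KCl step, so
dye loading and detector gain cancel.
"""

import numpy as np

from calclust import (
    default_protocol,
    extract_features,
    generate_dataset,
    paperlike_preset,
    qc_filter,
)
from calclust.preprocess import apply_qc

protocol = default_protocol()
dataset, truth = generate_dataset(paperlike_preset(), seed=1)
report = qc_filter(dataset, protocol)
kept = apply_qc(dataset, report)
table = extract_features(kept, protocol)

kept_truth = np.array(
    [l for c, l in zip(dataset.cell_ids, truth) if c in set(report.kept_ids)]
)
cols = [
    "high_glucose_response",
    "high_glucose_oscillation",
    "counted_peaks",
    "oscillation_frequency",
    "response_speed",
]
print(f"feature table: {table.shape[0]} cells x {len(table.columns) - 2} features")
print(table.groupby(kept_truth)[cols].mean().round(3))
print()
print("Oscillators show ~0.29/min oscillations at ~0.18 MAD/KCl magnitude;")
print("non-oscillating responders rise higher and faster but barely oscillate;")
print("non-responders sit near zero on every glucose-driven feature.")
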