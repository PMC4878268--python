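"""Reading, validating and writing trace tables and perturbation protocols.

Trace tables hold one fluorescence-ratio time series per cell (Fura-2
340/380 ratio, dimensionless) plus per-cell metadata (cell id, imaging
field, optional x/y position).  Two delimited-text dialects are supported:

``wide``
    one row per cell; columns ``cell_id``, ``field_id`` (optional ``x``,
    ``y``) followed by one column per timepoint, the header of those columns
    being the timestamp in minutes.  Wide is the canonical output dialect.
``long``
    triplets ``cell_id, time, value`` with metadata either in extra columns
    (repeated per row) or supplied separately.

A :class:`Protocol` is an ordered list of condition epochs (low glucose,
high glucose, KCl depolarization) with start/end times in minutes.  Epoch
intervals are half-open ``[start, end)`` so every boundary sample belongs to
exactly one epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

LOW_GLUCOSE = "low_glucose"
HIGH_GLUCOSE = "high_glucose"
KCL = "kcl"
EPOCH_LABELS = (LOW_GLUCOSE, HIGH_GLUCOSE, KCL)

_META_COLUMNS = ("cell_id", "field_id", "x", "y")


@dataclass(frozen=True)
class Epoch:
    """A contiguous experimental condition window, half-open in minutes."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}; expected one of {EPOCH_LABELS}")
        if not self.end > self.start:
            raise ValueError(f"epoch {self.label!r}: end ({self.end}) must exceed start ({self.start})")

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of timestamps falling in [start, end)."""
        return (times >= self.start) & (times < self.end)


@dataclass(frozen=True)
class Protocol:
    """Ordered condition epochs defining baseline / stimulation / KCl windows.

    Invariants enforced at construction: epochs are ordered by start and
    non-overlapping (gaps are allowed; samples in a gap belong to no epoch);
    there is exactly one KCl epoch; and at least one low-glucose epoch
    precedes the first high-glucose epoch (that low-glucose epoch is the
    default baseline).
    """

    epochs: tuple[Epoch, ...]
    baseline_label: str = LOW_GLUCOSE

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        starts = [e.start for e in self.epochs]
        if starts != sorted(starts):
            raise ValueError("epochs must be ordered by start time")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start < a.end:
                raise ValueError(f"epochs {a.label!r} and {b.label!r} overlap ({a.end} > {b.start})")
        n_kcl = sum(e.label == KCL for e in self.epochs)
        if n_kcl != 1:
            raise ValueError(f"protocol must contain exactly one kcl epoch, found {n_kcl}")
        highs = [e.start for e in self.epochs if e.label == HIGH_GLUCOSE]
        lows = [e.start for e in self.epochs if e.label == LOW_GLUCOSE]
        if highs and not any(lo < highs[0] for lo in lows):
            raise ValueError("a low_glucose epoch must precede the high_glucose epoch")
        if self.baseline_label not in {e.label for e in self.epochs}:
            raise ValueError(f"baseline label {self.baseline_label!r} not present in epochs")

    def find(self, label: str, occurrence: int = 1) -> Epoch:
        """Return the ``occurrence``-th (1-based) epoch carrying ``label``."""
        matches = [e for e in self.epochs if e.label == label]
        if not matches:
            raise KeyError(f"no epoch labelled {label!r}")
        if not 1 <= occurrence <= len(matches):
            raise IndexError(
                f"occurrence {occurrence} out of range for label {label!r} ({len(matches)} present)"
            )
        return matches[occurrence - 1]

    @property
    def baseline(self) -> Epoch:
        """The baseline epoch: first epoch carrying ``baseline_label``."""
        return self.find(self.baseline_label, 1)

    @property
    def span(self) -> tuple[float, float]:
        return self.epochs[0].start, self.epochs[-1].end


def default_protocol() -> Protocol:
    """The built-in glucose/KCl perfusion preset.

    20 min low (3 mM) glucose, 30 min high (20 mM) glucose, 15 min low
    glucose, 10 min KCl (30 mM) depolarization, 5 min low glucose —
    80 minutes in total.
    """
    return Protocol(
        epochs=(
            Epoch(LOW_GLUCOSE, 0.0, 20.0),
            Epoch(HIGH_GLUCOSE, 20.0, 50.0),
            Epoch(LOW_GLUCOSE, 50.0, 65.0),
            Epoch(KCL, 65.0, 75.0),
            Epoch(LOW_GLUCOSE, 75.0, 80.0),
        )
    )


_PROTOCOL_PRESETS = {"glucose_kcl_80min": default_protocol}


@dataclass
class TraceDataset:
    """Matrix of per-cell fluorescence-ratio time series with metadata.

    Attributes
    ----------
    cell_ids : list of str
        Unique per-cell identifiers, one per row of ``values``.
    field_ids : list of str
        Imaging-field label per cell.
    times : ndarray, shape (T,)
        Strictly increasing timestamps in minutes, shared by all cells.
    values : ndarray, shape (n_cells, T)
        Ratio values (dimensionless); all finite.
    positions : ndarray, shape (n_cells, 2), optional
        Per-cell (x, y) stage coordinates.
    """

    cell_ids: list[str]
    field_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.field_ids = [str(f) for f in self.field_ids]
        n, t = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} trace rows")
        if len(self.field_ids) != n:
            raise ValueError(f"{len(self.field_ids)} field ids for {n} cells")
        if len(set(self.cell_ids)) != n:
            seen: set[str] = set()
            dup = next(c for c in self.cell_ids if c in seen or seen.add(c))
            raise ValueError(f"duplicate cell_id {dup!r}")
        if self.times.ndim != 1 or len(self.times) != t:
            raise ValueError(f"{len(self.times)} timestamps for {t} trace columns")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("timestamps contain non-finite entries")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite trace value for cell {self.cell_ids[i]!r} at t={self.times[j]:g} min"
            )
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (n, 2):
                raise ValueError(f"positions must have shape ({n}, 2)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def sampling_interval(self) -> float:
        """Median sampling interval in minutes (times need not be uniform)."""
        if len(self.times) < 2:
            raise ValueError("need at least two timepoints for a sampling interval")
        return float(np.median(np.diff(self.times)))

    def trace(self, cell_id: str) -> np.ndarray:
        return self.values[self.cell_ids.index(str(cell_id))]

    def subset(self, cell_ids: Sequence[str]) -> "TraceDataset":
        """Row subset preserving the requested order."""
        wanted = [str(c) for c in cell_ids]
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in wanted if c not in index]
        if missing:
            raise KeyError(f"unknown cell ids: {missing}")
        rows = [index[c] for c in wanted]
        return TraceDataset(
            cell_ids=wanted,
            field_ids=[self.field_ids[i] for i in rows],
            times=self.times.copy(),
            values=self.values[rows].copy(),
            positions=None if self.positions is None else self.positions[rows].copy(),
        )


def epoch_slice(
    dataset: TraceDataset, protocol: Protocol, label: str, occurrence: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Samples of every trace falling in the requested epoch.

    Returns ``(times, values)`` where ``values`` has shape
    ``(n_cells, n_samples_in_epoch)``.  The epoch interval is half-open on
    the right: a sample at exactly the epoch end belongs to the next epoch.
    """
    epoch = protocol.find(label, occurrence)
    mask = epoch.contains(dataset.times)
    return dataset.times[mask], dataset.values[:, mask]


def _mask_for(trace_times: np.ndarray, epoch: Epoch, what: str) -> np.ndarray:
    mask = epoch.contains(trace_times)
    if not mask.any():
        raise ValueError(f"no samples fall in the {what} epoch [{epoch.start}, {epoch.end})")
    return mask


def validate_protocol_against(dataset: TraceDataset, protocol: Protocol) -> None:
    """Check every epoch holds at least two samples of ``dataset``."""
    for e in protocol.epochs:
        if int(e.contains(dataset.times).sum()) < 2:
            raise ValueError(
                f"epoch {e.label!r} [{e.start}, {e.end}) contains fewer than 2 samples"
            )


# ---------------------------------------------------------------------------
# file input / output
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_trace_table(
    path: str | Path,
    dialect: str = "wide",
    field_ids: Sequence[str] | None = None,
    sep: str | None = None,
) -> TraceDataset:
    """Read a delimited trace table into a validated :class:`TraceDataset`.

    Parameters
    ----------
    path : path to a CSV/TSV file
    dialect : ``"wide"`` or ``"long"``
        Wide: metadata columns then one column per timestamp.  Long:
        ``cell_id, time, value`` triplets (optional ``field_id`` column).
    field_ids : optional
        Per-cell field labels if the file carries none; cells are then all
        assigned in file order.

    Row order of the file is preserved.  Non-numeric values, duplicate cell
    ids and non-increasing timestamps are hard errors naming the offender.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "field_id": str})
        meta_cols = [c for c in df.columns if c in _META_COLUMNS]
        time_cols = [c for c in df.columns if c not in _META_COLUMNS]
        if "cell_id" not in meta_cols:
            raise ValueError(f"{path}: wide trace table needs a cell_id column")
        try:
            times = np.array([float(c) for c in time_cols])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric timestamp column header: {exc}") from exc
        values = df[time_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: non-numeric or missing value at row {i} (cell "
                f"{df['cell_id'].iloc[i]!r}), column {time_cols[j]!r}"
            )
        cells = df["cell_id"].tolist()
        fields = (
            df["field_id"].tolist()
            if "field_id" in df.columns
            else list(field_ids) if field_ids is not None else ["field_1"] * len(cells)
        )
        positions = df[["x", "y"]].to_numpy() if {"x", "y"} <= set(df.columns) else None
        return TraceDataset(cells, fields, times, values.astype(float), positions)
    if dialect == "long":
        df = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "field_id": str})
        for col in ("cell_id", "time", "value"):
            if col not in df.columns:
                raise ValueError(f"{path}: long trace table needs a {col!r} column")
        for col in ("time", "value"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = int(coerced.index[coerced.isna()][0])
                raise ValueError(f"{path}: non-numeric {col!r} at row {row}")
            df[col] = coerced
        cells = list(dict.fromkeys(df["cell_id"]))  # preserve first-appearance order
        wide = df.pivot(index="cell_id", columns="time", values="value").reindex(cells)
        if wide.isna().any().any():
            cell = wide.index[wide.isna().any(axis=1)][0]
            raise ValueError(f"{path}: cell {cell!r} is missing one or more timepoints")
        if "field_id" in df.columns:
            fields = df.drop_duplicates("cell_id").set_index("cell_id")["field_id"].reindex(cells).tolist()
        else:
            fields = list(field_ids) if field_ids is not None else ["field_1"] * len(cells)
        return TraceDataset(cells, fields, wide.columns.to_numpy(float), wide.to_numpy(float))
    raise ValueError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def write_trace_table(dataset: TraceDataset, path: str | Path, sep: str | None = None) -> None:
    """Write a dataset in the canonical wide dialect."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.DataFrame(dataset.values, columns=[f"{t:g}" for t in dataset.times])
    df.insert(0, "field_id", dataset.field_ids)
    df.insert(0, "cell_id", dataset.cell_ids)
    if dataset.positions is not None:
        df.insert(2, "x", dataset.positions[:, 0])
        df.insert(3, "y", dataset.positions[:, 1])
    df.to_csv(path, sep=sep, index=False)


def read_protocol(source: str | Path) -> Protocol:
    """Read a protocol from a YAML config or resolve a named preset.

    The config lists epochs as mappings with ``label``, ``start`` and ``end``
    (minutes), e.g.::

        epochs:
          - {label: low_glucose, start: 0, end: 20}
          - {label: high_glucose, start: 20, end: 50}
          ...
        baseline_label: low_glucose   # optional

    Overlapping epochs, zero or multiple KCl epochs are hard errors (raised
    by :class:`Protocol`).  Gaps between epochs are accepted; samples in a
    gap are excluded from every epoch statistic.
    """
    if isinstance(source, str) and source in _PROTOCOL_PRESETS:
        return _PROTOCOL_PRESETS[source]()
    path = Path(source)
    if not path.exists() and str(source) in _PROTOCOL_PRESETS:  # pragma: no cover
        return _PROTOCOL_PRESETS[str(source)]()
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "epochs" not in spec:
        raise ValueError(f"{path}: protocol config must be a mapping with an 'epochs' list")
    epochs = tuple(
        Epoch(str(e["label"]), float(e["start"]), float(e["end"])) for e in spec["epochs"]
    )
    return Protocol(epochs=epochs, baseline_label=str(spec.get("baseline_label", LOW_GLUCOSE)))


def write_protocol(protocol: Protocol, path: str | Path) -> None:
    payload = {
        "epochs": [{"label": e.label, "start": e.start, "end": e.end} for e in protocol.epochs],
        "baseline_label": protocol.baseline_label,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


__all__ = [
    "Epoch",
    "Protocol",
    "TraceDataset",
    "LOW_GLUCOSE",
    "HIGH_GLUCOSE",
    "KCL",
    "default_protocol",
    "epoch_slice",
    "validate_protocol_against",
    "read_trace_table",
    "write_trace_table",
    "read_protocol",
    "write_protocol",
]
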