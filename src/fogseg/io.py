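"""Motion-capture trial I/O and the displacement feature representation.

A trial is a ``[T, N, 3]`` array of marker positions (millimetres, as stored
in C3D files) sampled at a fixed rate (100 Hz for the supported protocol),
with a per-sample binary label: 0 = functional gait (FG), 1 = freezing of
gait (FOG).  The network input is the per-sample marker displacement
``positions[t+1] - positions[t]``, so a trial of ``T`` samples yields
``T - 1`` feature samples; the displacement over ``[t, t+1)`` inherits the
label of sample ``t``, preserving the annotated FOG onset index.

Two interchange formats are supported: C3D (via :mod:`fogseg._c3d`) and a
wide CSV (columns ``time, <marker>_X, <marker>_Y, <marker>_Z, ..., label``).
FOG annotations may be given per sample or as half-open ``(onset, offset)``
sample intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._c3d import C3DFormatError, read_c3d, write_c3d  # noqa: F401  (re-export)
from .graph import DEFAULT_NODE_NAMES

__all__ = [
    "MarkerTrial", "FeatureSequence",
    "load_c3d", "save_c3d", "load_csv", "save_csv", "read_annotations",
    "select_markers", "displacement_features", "events_to_labels",
    "MissingMarkerError", "LabelAlignmentError", "DegenerateTrialError",
    "DEFAULT_MARKERS",
]

#: The canonical 9-marker configuration (matches the default skeleton graph).
DEFAULT_MARKERS = tuple(DEFAULT_NODE_NAMES)

FG, FOG = 0, 1


class MissingMarkerError(KeyError):
    """A requested marker name is not present in the trial/file."""


class LabelAlignmentError(ValueError):
    """Label sequence length does not match the trial frame count."""


class DegenerateTrialError(ValueError):
    """Trial too short for the requested operation."""


@dataclass
class MarkerTrial:
    """One MoCap trial: marker trajectories plus per-sample labels."""

    subject_id: str
    trial_id: str
    rate_hz: float
    marker_names: tuple
    positions: np.ndarray     # [T, N, 3] mm
    labels: np.ndarray        # [T] int, 0=FG 1=FOG

    def __post_init__(self):
        self.marker_names = tuple(self.marker_names)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        T, N = self.num_samples, len(self.marker_names)
        if self.positions.ndim != 3 or self.positions.shape != (T, N, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{N} markers / labels of length {T}")
        if T < 2:
            raise DegenerateTrialError("a trial needs at least 2 samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if np.isnan(self.positions).any():
            raise ValueError(
                "positions contain gaps (NaN); load with gap_fill or clean first")

    @property
    def num_samples(self) -> int:
        return len(self.labels)

    @property
    def num_markers(self) -> int:
        return len(self.marker_names)

    @property
    def duration_s(self) -> float:
        return self.num_samples / self.rate_hz


@dataclass
class FeatureSequence:
    """Displacement features derived from a :class:`MarkerTrial`."""

    features: np.ndarray      # [T-1, N, 3] mm/sample
    labels: np.ndarray        # [T-1]
    provenance: MarkerTrial | None = field(default=None, repr=False)

    def __post_init__(self):
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.features) != len(self.labels):
            raise LabelAlignmentError("features/labels length mismatch")


def events_to_labels(n_samples: int, events) -> np.ndarray:
    """Expand half-open ``(onset, offset)`` sample pairs to per-sample labels."""
    labels = np.zeros(n_samples, dtype=np.int64)
    for onset, offset in events:
        if not (0 <= onset < offset <= n_samples):
            raise LabelAlignmentError(
                f"episode ({onset}, {offset}) outside trial of {n_samples} samples")
        labels[onset:offset] = FOG
    return labels


def _resolve_labels(n_samples: int, label_source) -> np.ndarray:
    if label_source is None:
        return np.zeros(n_samples, dtype=np.int64)
    arr = np.asarray(label_source)
    if arr.ndim == 1 and len(arr) != n_samples:
        raise LabelAlignmentError(
            f"label length {len(arr)} != frame count {n_samples}")
    if arr.ndim == 2:  # event pairs
        return events_to_labels(n_samples, arr)
    return arr.astype(np.int64)


def _gap_fill(positions: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate marker gaps of at most ``max_gap`` samples."""
    out = positions.copy()
    T = len(out)
    t = np.arange(T)
    for n in range(out.shape[1]):
        bad = np.isnan(out[:, n, 0])
        if not bad.any():
            continue
        # reject long gaps and gaps touching either end
        runs = np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0]))
        for s, e in zip(runs[::2], runs[1::2]):
            if e - s > max_gap or s == 0 or e == T:
                raise ValueError(
                    f"marker gap of {e - s} samples at [{s}, {e}) exceeds "
                    f"max_gap={max_gap} or touches the trial boundary")
        good = ~bad
        for ax in range(3):
            out[bad, n, ax] = np.interp(t[bad], t[good], out[good, n, ax])
    return out


def load_c3d(path, label_source=None, markers=None, subject_id="", trial_id="",
             gap_fill: bool = False, max_gap: int = 10) -> MarkerTrial:
    """Load a C3D file into a :class:`MarkerTrial`.

    ``label_source`` is either a length-T per-sample label array or an
    iterable of half-open ``(onset, offset)`` FOG episode sample pairs (or
    None for an all-FG trial).  If ``markers`` is given, that subset is
    selected (in the given order).  Marker gaps are rejected unless
    ``gap_fill`` is set, in which case gaps of at most ``max_gap`` samples
    are linearly interpolated.
    """
    positions, names, rate = read_c3d(path)
    if gap_fill and np.isnan(positions).any():
        positions = _gap_fill(positions, max_gap)
    labels = _resolve_labels(len(positions), label_source)
    trial = MarkerTrial(subject_id=subject_id, trial_id=trial_id or str(path),
                        rate_hz=rate, marker_names=names,
                        positions=positions, labels=labels)
    if markers is not None:
        trial = select_markers(trial, markers)
    return trial


def save_c3d(path, trial: MarkerTrial) -> None:
    """Write the trial's point data as a minimal C3D file (labels not stored)."""
    write_c3d(path, trial.positions, list(trial.marker_names), trial.rate_hz)


def select_markers(trial: MarkerTrial, markers=DEFAULT_MARKERS) -> MarkerTrial:
    """Reduce/reorder the marker axis to ``markers`` (order defines graph indices)."""
    index = {m: i for i, m in enumerate(trial.marker_names)}
    missing = [m for m in markers if m not in index]
    if missing:
        raise MissingMarkerError(
            f"markers {missing} not present in trial {trial.trial_id!r} "
            f"(available: {list(trial.marker_names)})")
    cols = [index[m] for m in markers]
    return MarkerTrial(subject_id=trial.subject_id, trial_id=trial.trial_id,
                       rate_hz=trial.rate_hz, marker_names=tuple(markers),
                       positions=trial.positions[:, cols], labels=trial.labels)


def displacement_features(trial: MarkerTrial) -> FeatureSequence:
    """Per-sample marker displacement ``positions[t+1] - positions[t]``.

    The output has ``T - 1`` samples; sample ``t`` carries the label of the
    interval's first source sample.
    """
    if trial.num_samples < 2:
        raise DegenerateTrialError("displacement needs at least 2 samples")
    feats = np.diff(trial.positions, axis=0)
    return FeatureSequence(features=feats, labels=trial.labels[:-1],
                           provenance=trial)


# -- tabular interchange ---------------------------------------------------


def save_csv(path, trial: MarkerTrial) -> None:
    """Write the wide-CSV interchange format (time, <m>_{X,Y,Z}..., label)."""
    cols = {"time": np.arange(trial.num_samples) / trial.rate_hz}
    for i, m in enumerate(trial.marker_names):
        for ax, a in enumerate("XYZ"):
            cols[f"{m}_{a}"] = trial.positions[:, i, ax]
    cols["label"] = trial.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def load_csv(path, subject_id="", trial_id="", rate_hz=None) -> MarkerTrial:
    """Read the wide-CSV interchange format written by :func:`save_csv`."""
    df = pd.read_csv(path)
    marker_names = []
    for c in df.columns:
        if c.endswith("_X"):
            marker_names.append(c[:-2])
    if not marker_names:
        raise ValueError(f"{path}: no '<marker>_X' columns found")
    T = len(df)
    positions = np.empty((T, len(marker_names), 3))
    for i, m in enumerate(marker_names):
        for ax, a in enumerate("XYZ"):
            positions[:, i, ax] = df[f"{m}_{a}"].to_numpy()
    if rate_hz is None:
        t = df["time"].to_numpy()
        rate_hz = 1.0 / np.median(np.diff(t))
    labels = df["label"].to_numpy() if "label" in df else np.zeros(T, int)
    return MarkerTrial(subject_id=subject_id, trial_id=trial_id or str(path),
                       rate_hz=float(rate_hz), marker_names=marker_names,
                       positions=positions, labels=labels)


def read_annotations(path) -> dict:
    """Read an annotation sidecar CSV of (trial_id, onset_sample, offset_sample).

    Intervals are half-open and 0-based.  Returns ``{trial_id: [(on, off)...]}``.
    """
    df = pd.read_csv(path)
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["trial_id"]), []).append(
            (int(row["onset_sample"]), int(row["offset_sample"])))
    return out
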