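"""Gaze-recording container and CSV / timebase plumbing.

A recording is a single horizontal gaze channel (degrees of visual angle)
with millisecond timestamps and a small-integer event label per sample
(1 = fixation, 2 = saccade, 3 = post-saccadic oscillation, 0 = other/noise).
The analysis pipeline operates on a canonical 250 Hz timebase, i.e. a
4 ms inter-sample interval (ISI); recordings from faster trackers are
brought there by interpolation and/or plain decimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_OTHER = 0
LABEL_FIXATION = 1
LABEL_SACCADE = 2
LABEL_PSO = 3

#: Canonical inter-sample interval of the analysis timebase, in ms.
CANONICAL_ISI_MS = 4.0

_CSV_COLUMNS = ("t_ms", "x_deg", "label")


class GazeFormatError(ValueError):
    """Malformed gaze CSV (missing columns, unparseable header)."""


class GazeDataError(ValueError):
    """Structurally valid file but inconsistent data (e.g. non-monotone time)."""


@dataclass
class GazeRecording:
    """Uniformly or irregularly sampled horizontal gaze trace.

    Attributes
    ----------
    timestamps : ndarray of float, ms, strictly increasing
    x : ndarray of float, degrees of visual angle (NaN marks missing samples)
    labels : ndarray of int, per-sample event code
    sample_rate_hz : nominal sampling rate
    dataset_id : free-text tag naming the source dataset
    """

    timestamps: np.ndarray
    x: np.ndarray
    labels: np.ndarray
    sample_rate_hz: float = 250.0
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.timestamps) == len(self.x) == len(self.labels)):
            raise GazeDataError(
                "timestamps, x and labels must have equal length "
                f"(got {len(self.timestamps)}, {len(self.x)}, {len(self.labels)})"
            )
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise GazeDataError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def is_canonical(self) -> bool:
        """True when the trace sits exactly on the 4 ms grid."""
        if len(self) < 2:
            return True
        return bool(np.allclose(np.diff(self.timestamps), CANONICAL_ISI_MS))

    def equals(self, other: "GazeRecording") -> bool:
        return (
            np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.x, other.x, equal_nan=True)
            and np.array_equal(self.labels, other.labels)
            and self.sample_rate_hz == other.sample_rate_hz
            and self.dataset_id == other.dataset_id
        )


def read_gaze_csv(path, dataset_id: str = "", sample_rate_hz: float = 250.0) -> GazeRecording:
    """Read a gaze CSV with columns ``t_ms,x_deg,label``.

    Non-numeric position entries are preserved as NaN sentinels and their
    count logged; non-monotone timestamps raise :class:`GazeDataError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"{path}: missing required column(s) {missing}")
    t = pd.to_numeric(df["t_ms"], errors="raise").to_numpy(dtype=float)
    x = pd.to_numeric(df["x_deg"], errors="coerce").to_numpy(dtype=float)
    n_bad = int(np.isnan(x).sum() - df["x_deg"].isna().sum())
    if n_bad:
        logger.warning("%s: %d non-numeric x_deg values kept as missing", path, n_bad)
    labels = pd.to_numeric(df["label"], errors="raise").astype(int).to_numpy()
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise GazeDataError(f"{path}: timestamps are not strictly increasing")
    return GazeRecording(t, x, labels, sample_rate_hz=sample_rate_hz, dataset_id=dataset_id)


def write_gaze_csv(rec: GazeRecording, path) -> None:
    """Write ``t_ms,x_deg,label`` at full float precision (repr round-trip)."""
    df = pd.DataFrame(
        {"t_ms": rec.timestamps, "x_deg": rec.x, "label": rec.labels}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def interpolate_to_isi(rec: GazeRecording, isi_ms: float = CANONICAL_ISI_MS) -> GazeRecording:
    """Resample onto an arithmetic timestamp grid with step ``isi_ms``.

    Position is linearly interpolated; labels are taken from the nearest
    original sample (ties resolved toward the earlier sample).  Missing
    position values are first bridged by linear interpolation across gaps
    of at most 3 samples; longer gaps stay NaN.
    """
    if len(rec) < 2:
        raise GazeDataError("interpolation needs at least 2 samples")
    t, x, labels = rec.timestamps, _bridge_short_gaps(rec.x), rec.labels
    n_out = int(np.floor((t[-1] - t[0]) / isi_ms)) + 1
    t_new = t[0] + isi_ms * np.arange(n_out)
    x_new = np.interp(t_new, t[~np.isnan(x)], x[~np.isnan(x)]) if np.isnan(x).any() else np.interp(t_new, t, x)
    if np.isnan(x).any():
        # re-poison regions that were inside an unbridged gap
        nan_spans = _nan_spans(x)
        for i0, i1 in nan_spans:
            lo = t[i0 - 1] if i0 > 0 else -np.inf
            hi = t[i1] if i1 < len(t) else np.inf
            x_new[(t_new > lo) & (t_new < hi)] = np.nan
    # nearest label, ties -> earlier sample
    idx = np.searchsorted(t, t_new)
    idx = np.clip(idx, 1, len(t) - 1)
    left_closer = (t_new - t[idx - 1]) <= (t[idx] - t_new)
    nearest = np.where(left_closer, idx - 1, idx)
    labels_new = labels[nearest]
    return GazeRecording(
        t_new, x_new, labels_new,
        sample_rate_hz=1000.0 / isi_ms, dataset_id=rec.dataset_id,
    )


def _bridge_short_gaps(x: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap with interior support."""
    x = x.astype(float).copy()
    for i0, i1 in _nan_spans(x):
        if i1 - i0 <= max_gap and i0 > 0 and i1 < len(x):
            x[i0:i1] = np.interp(np.arange(i0, i1), [i0 - 1, i1], [x[i0 - 1], x[i1]])
    return x


def _nan_spans(x: np.ndarray) -> list[tuple[int, int]]:
    isnan = np.isnan(x)
    spans = []
    i = 0
    while i < len(x):
        if isnan[i]:
            j = i
            while j < len(x) and isnan[j]:
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def downsample(rec: GazeRecording, factor: int) -> GazeRecording:
    """Keep every ``factor``-th sample starting at index 0 (plain decimation).

    No anti-alias filter is applied: the downstream analysis depends on
    preserving high-frequency content (ocular microtremor) that a low-pass
    filter would remove.
    """
    if factor < 1:
        raise ValueError(f"decimation factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(rec)
    return GazeRecording(
        rec.timestamps[::factor],
        rec.x[::factor],
        rec.labels[::factor],
        sample_rate_hz=rec.sample_rate_hz / factor,
        dataset_id=rec.dataset_id,
    )
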