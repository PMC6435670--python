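"""Detection and morphometry of the named BCG waves.

A displacement BCG beat carries (at most) the classical H, I, J, K sequence:
a small peak (H), a valley (I), the main peak (J) and a valley (K).  The
acceleration channel carries the corresponding I (valley), J (peak), K
(valley), L (peak) sequence — to first order the flipped displacement beat,
since double differentiation of a band-limited oscillation adds a near-180
degree phase lead.

Detection operates on a single zero-mean steady-state beat: all local extrema
with prominence of at least 5% of the beat's peak-to-peak excursion are listed,
the main peak J is the global maximum, and the remaining labels are assigned by
adjacency.  Individual wave amplitudes are measured from the zero-mean
baseline; wave-to-wave amplitudes are differences of extreme values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FiducialSet",
    "MorphometryTable",
    "detect_displacement_waves",
    "detect_acceleration_waves",
    "intervals_amplitudes",
    "summarize_cohort",
    "write_fiducial_csv",
]

#: Minimum extremum prominence as a fraction of the beat peak-to-peak range.
PROMINENCE_FRACTION = 0.05


class NoWavesError(ValueError):
    """Beat has too few prominent extrema to label."""


class MissingWaveError(KeyError):
    """A requested wave label is absent from the fiducial set."""


@dataclass(frozen=True)
class FiducialSet:
    """Labeled wave extrema of one beat, ordered by time."""

    channel: str
    waves: tuple  # of (label, time_s, value)
    beat_window: float  # s

    def __post_init__(self) -> None:
        times = [t for _, t, _ in self.waves]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("wave times must be strictly increasing")

    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.waves)

    def __contains__(self, label: str) -> bool:
        return label in self.labels()

    def time(self, label: str) -> float:
        return self._get(label)[1]

    def value(self, label: str) -> float:
        return self._get(label)[2]

    def amplitude(self, label: str) -> float:
        """Individual wave amplitude: |value| from the zero-mean baseline."""
        return abs(self.value(label))

    def _get(self, label: str):
        for wave in self.waves:
            if wave[0] == label:
                return wave
        raise MissingWaveError(f"wave {label!r} absent from channel {self.channel}")


def _extrema(values: np.ndarray):
    """Indices of prominent maxima/minima on a periodically extended beat.

    The beat is tiled three times so extrema at the window edges get correct
    prominences; only extrema of the middle copy are kept.
    """
    n = len(values)
    tiled = np.tile(values, 3)
    floor = PROMINENCE_FRACTION * np.ptp(values)
    if floor == 0:
        raise NoWavesError("flat beat has no waves")
    maxima, _ = find_peaks(tiled, prominence=floor)
    minima, _ = find_peaks(-tiled, prominence=floor)
    maxima = maxima[(maxima >= n) & (maxima < 2 * n)] - n
    minima = minima[(minima >= n) & (minima < 2 * n)] - n
    if len(maxima) + len(minima) < 2:
        raise NoWavesError("fewer than two prominent extrema in the beat")
    return np.sort(maxima), np.sort(minima)


def _check_beat(time: np.ndarray, values: np.ndarray) -> None:
    if time.shape != values.shape or time.ndim != 1:
        raise ValueError("time and values must be 1-D arrays of equal length")
    if abs(np.mean(values)) > 1e-8 * max(np.ptp(values), 1e-300):
        raise ValueError("beat must be zero-mean (remove the mean first)")


def _refine(values: np.ndarray, idx: int) -> tuple[float, float]:
    """Sub-sample extremum location by a parabola through three samples.

    Returns (fractional index offset in (-0.5, 0.5), refined value); removes
    the sample-grid quantization of extremum times.  Neighbors wrap
    periodically, matching the beat's periodic extension.
    """
    n = len(values)
    y0, y1, y2 = values[(idx - 1) % n], values[idx], values[(idx + 1) % n]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return 0.0, float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return delta, float(y1 - 0.25 * (y0 - y2) * delta)


def _build(channel: str, time: np.ndarray, values: np.ndarray, picks: dict) -> FiducialSet:
    dt = float(time[1] - time[0])
    present = {label: idx for label, idx in picks.items() if idx is not None}
    waves = []
    for label, idx in sorted(present.items(), key=lambda kv: kv[1]):
        delta, value = _refine(values, idx)
        waves.append((label, float(time[idx]) + delta * dt, value))
    return FiducialSet(channel=channel, waves=tuple(waves), beat_window=float(len(time) * dt))


def _nearest(candidates: np.ndarray, pivot: int, side: str):
    sel = candidates[candidates < pivot] if side == "before" else candidates[candidates > pivot]
    if len(sel) == 0:
        return None
    return int(sel[-1] if side == "before" else sel[0])


def detect_displacement_waves(
    time: np.ndarray, values: np.ndarray, channel: str = "scale_disp"
) -> FiducialSet:
    """Label H, I, J, K on one zero-mean displacement beat.

    J is the global maximum; I and K are the nearest minima before and after
    it; H is the local maximum immediately preceding I, when present.
    """
    _check_beat(time, values)
    maxima, minima = _extrema(values)
    j = int(np.argmax(values))
    i = _nearest(minima, j, "before")
    k = _nearest(minima, j, "after")
    h = _nearest(maxima, i, "before") if i is not None else None
    return _build(channel, time, values, {"H": h, "I": i, "J": j, "K": k})


def detect_acceleration_waves(
    time: np.ndarray, values: np.ndarray, channel: str = "wrist_acc"
) -> FiducialSet:
    """Label I, J, K, L on one zero-mean acceleration beat.

    The anchor is K, the global minimum; J is the nearest preceding maximum,
    L the next maximum after K, and I the minimum immediately preceding J when
    present (polarity pattern: I valley, J peak, K valley, L peak).  Anchoring
    at the deepest valley rather than the highest peak makes the labeling the
    exact mirror of the displacement rule: on a sign-flipped displacement beat
    the detected J/K/L land on the displacement I/J/K by construction, which is
    the correspondence double time-differentiation implies for band-limited
    beats (a near-180-degree phase lead).
    """
    _check_beat(time, values)
    maxima, minima = _extrema(values)
    k = int(np.argmin(values))
    j = _nearest(maxima, k, "before")
    ell = _nearest(maxima, k, "after")
    i = _nearest(minima, j, "before") if j is not None else None
    return _build(channel, time, values, {"I": i, "J": j, "K": k, "L": ell})


def intervals_amplitudes(fset: FiducialSet, pairs) -> dict:
    """Wave-to-wave intervals (ms) and amplitudes for ordered label pairs.

    For each pair ``(a, b)`` with ``a`` earlier than ``b``, the interval is
    ``t(b) - t(a)`` in milliseconds and the amplitude ``|value(a) - value(b)|``
    in channel units.  Reversed pairs are rejected; a missing label raises
    :class:`MissingWaveError` naming it.
    """
    out = {}
    for a, b in pairs:
        ta, tb = fset.time(a), fset.time(b)
        if tb <= ta:
            raise ValueError(f"pair ({a}, {b}) not in temporal order for this beat")
        out[f"{a}{b}_ms"] = 1e3 * (tb - ta)
        out[f"{a}{b}_amp"] = abs(fset.value(a) - fset.value(b))
    return out


@dataclass(frozen=True)
class MorphometryTable:
    """Per-subject morphometry rows with mean and standard-error summary."""

    rows: pd.DataFrame
    mean: pd.Series
    se: pd.Series
    n: int

    def to_csv(self, path) -> None:
        table = self.rows.copy()
        table.loc["mean"] = self.mean
        table.loc["se"] = self.se
        table.to_csv(path, float_format="%.6g")


def summarize_cohort(rows) -> MorphometryTable:
    """Summarize per-subject rows (mapping label -> value) as mean +/- SE.

    SE is the sample standard deviation (ddof=1) over sqrt(n); n >= 2 required.
    """
    df = pd.DataFrame(list(rows))
    if len(df) < 2:
        raise ValueError("need at least two subjects to compute a standard error")
    return MorphometryTable(
        rows=df,
        mean=df.mean(),
        se=df.std(ddof=1) / np.sqrt(len(df)),
        n=len(df),
    )


def write_fiducial_csv(fsets, path) -> None:
    """Write fiducial sets as `channel,label,time_ms,value` rows."""
    records = [
        {"channel": f.channel, "label": label, "time_ms": 1e3 * t, "value": v}
        for f in fsets
        for label, t, v in f.waves
    ]
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.9g")
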