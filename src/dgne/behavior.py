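"""Behavioral state segmentation, lap indexing, pupil preprocessing and
event-triggered statistics.

Running epochs follow the standard head-fixed treadmill definition: maximal
intervals of speed >= 4 cm/s lasting at least 2.5 s.  Immobility (rest) is
speed < 4 cm/s.  Supra-threshold bouts shorter than the minimum duration are
assigned to neither state (they are not running by the duration rule, and not
"speeds < 4 cm/s" either); set ``rest_includes_short_bouts=True`` to fold them
into rest instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import Epochs

__all__ = [
    "LapIndex",
    "segment_locomotion",
    "laps_from_position",
    "preprocess_pupil",
    "event_triggered_average",
    "pupil_state_stats",
    "discrimination_index",
]

RUN_THRESHOLD_CM_S = 4.0
MIN_RUN_S = 2.5


@dataclass(frozen=True)
class LapIndex:
    """Per-frame lap number (0-based, non-decreasing) and within-lap position (cm)."""

    lap: np.ndarray
    within_lap_cm: np.ndarray

    @property
    def n_laps(self) -> int:
        return int(self.lap.max()) + 1 if self.lap.size else 0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open intervals where mask is True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def segment_locomotion(
    speed: np.ndarray,
    frame_rate: float,
    run_threshold: float = RUN_THRESHOLD_CM_S,
    min_run_s: float = MIN_RUN_S,
    rest_includes_short_bouts: bool = False,
) -> Epochs:
    """Segment a speed trace into run and rest epochs.

    Run epochs are maximal intervals with ``speed >= run_threshold`` that last
    at least ``min_run_s``; rest epochs are maximal intervals with
    ``speed < run_threshold``.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ValueError("empty speed vector")
    supra = speed >= run_threshold
    min_frames = int(np.ceil(min_run_s * frame_rate))
    run_ivals = [(s, e) for s, e in _runs(supra) if e - s >= min_frames]
    if rest_includes_short_bouts:
        rest_mask = np.ones_like(supra)
        for s, e in run_ivals:
            rest_mask[s:e] = False
    else:
        rest_mask = ~supra
    rest_ivals = _runs(rest_mask)
    return Epochs(run=tuple(run_ivals), rest=tuple(rest_ivals), n_frames=speed.size)


def laps_from_position(position: np.ndarray, belt_length: float) -> LapIndex:
    """Assign lap numbers from belt-position wraps (high -> low transitions)."""
    position = np.asarray(position, dtype=float)
    wraps = np.diff(position) < -belt_length / 2
    lap = np.concatenate([[0], np.cumsum(wraps)]).astype(int)
    return LapIndex(lap=lap, within_lap_cm=position.copy())


def preprocess_pupil(
    raw: np.ndarray,
    blink: np.ndarray | None = None,
    native_rate: float = 100.0,
    target_rate: float = 15.0,
    cutoff_hz: float = 4.0,
    filter_order: int = 4,
) -> np.ndarray:
    """Blink interpolation, zero-phase 4 Hz low-pass, resampling, mean normalization.

    Blink/saccade frames are removed and bridged by linear interpolation so the
    time base stays uniform for filtering; the trace is then low-pass filtered
    (zero-phase Butterworth), resampled to ``target_rate`` and divided by its
    mean, so the output has mean 1.
    """
    raw = np.asarray(raw, dtype=float)
    if native_rate < 2 * cutoff_hz:
        raise ValueError("native_rate must be at least twice the low-pass cutoff")
    x = raw.copy()
    if blink is not None:
        blink = np.asarray(blink).astype(bool)
        if blink.all():
            raise ValueError("all frames are blink frames")
        if blink.mean() > 0.5:
            warnings.warn("more than 50% blink frames; interpolation is unreliable")
        good = np.flatnonzero(~blink)
        x[blink] = np.interp(np.flatnonzero(blink), good, x[good])
    if cutoff_hz < native_rate / 2:
        sos = signal.butter(filter_order, cutoff_hz, fs=native_rate, output="sos")
        pad = min(3 * (2 * filter_order + 1), x.size - 1)
        x = signal.sosfiltfilt(sos, x, padlen=pad)
    if native_rate != target_rate:
        from fractions import Fraction

        frac = Fraction(target_rate / native_rate).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, padtype="line")
    m = x.mean()
    if m == 0:
        raise ValueError("pupil trace has zero mean; cannot normalize")
    return x / m


def event_triggered_average(
    sig: np.ndarray, event_frames: np.ndarray, window_frames: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean and SEM of ``sig`` in ``[-w, +w]`` around each event.

    Events whose full window falls outside the recording are dropped.
    Returns (mean, sem, n_events_used); with a single event the SEM is zero
    by convention.
    """
    sig = np.asarray(sig, dtype=float)
    w = int(window_frames)
    ev = np.asarray(event_frames, dtype=int)
    ev = ev[(ev - w >= 0) & (ev + w < sig.size)]
    if ev.size == 0:
        raise ValueError("no events with a complete window inside the recording")
    snips = np.stack([sig[f - w : f + w + 1] for f in ev])
    mean = snips.mean(axis=0)
    if ev.size > 1:
        sem = snips.std(axis=0, ddof=1) / np.sqrt(ev.size)
    else:
        sem = np.zeros_like(mean)
    return mean, sem, int(ev.size)


def pupil_state_stats(
    pupil: np.ndarray,
    epochs: Epochs,
    ne_frames: np.ndarray,
    frame_rate: float,
) -> dict[str, float]:
    """Mean pupil diameter and mean rate of change per behavioral state.

    States: entire locomotion episodes, entire immobility periods, and the
    single frames coincident with network-event peaks.  Rate of change is the
    per-frame first difference scaled to 1/s.
    """
    pupil = np.asarray(pupil, dtype=float)
    if pupil.size != epochs.n_frames:
        raise ValueError("pupil length does not match epochs")
    deriv = np.concatenate([[0.0], np.diff(pupil)]) * frame_rate
    out: dict[str, float] = {}
    for state in ("run", "rest"):
        m = epochs.mask(state)
        out[f"mean_{state}"] = float(pupil[m].mean()) if m.any() else np.nan
        out[f"dmean_{state}"] = float(deriv[m].mean()) if m.any() else np.nan
    ne = np.asarray(ne_frames, dtype=int)
    ne = ne[(ne >= 0) & (ne < pupil.size)]
    out["mean_ne"] = float(pupil[ne].mean()) if ne.size else np.nan
    out["dmean_ne"] = float(deriv[ne].mean()) if ne.size else np.nan
    return out


def discrimination_index(
    t_displaced: float, t_stationary: float, min_total_s: float = 4.0
) -> tuple[float, bool]:
    """Object-displacement discrimination index with the exclusion rule.

    DI = (displaced - stationary) / (displaced + stationary), in [-1, 1];
    trials with total exploration below ``min_total_s`` are flagged excluded
    (DI returned as NaN).
    """
    if t_displaced < 0 or t_stationary < 0:
        raise ValueError("exploration times must be non-negative")
    total = t_displaced + t_stationary
    if total < min_total_s:
        return float("nan"), True
    return (t_displaced - t_stationary) / total, False
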