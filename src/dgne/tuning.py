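"""Place- and speed-cell identification.

Place coding: the belt is mapped to the unit circle and each running-epoch
event onset contributes a unit vector at the animal's position, weighted by
the reciprocal of the occupancy time of that spatial bin (weights normalized
to sum 1).  The resultant mean vector length is tested against a null built by
redrawing the onset times uniformly over running frames.  Only cells with at
least four running-epoch onsets are tested.

Speed coding: speed is divided into 20 evenly sized bins between 0 and the
maximum; the mean dF/F per bin is correlated (Pearson) with the bin centers.
Candidates need r >= 0.9 and must beat at least 95% of circular time-shift
surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Epochs
from .ensembles import ParticipationMatrix

__all__ = [
    "PlaceResult",
    "SpeedResult",
    "spatial_tuning_vector",
    "place_cell_test",
    "speed_tuning",
    "speed_cell_test",
    "tuning_ne_incorporation",
]

MIN_ONSETS = 4
SPEED_R_MIN = 0.9
SPEED_SHUFFLE_PASS = 0.95


@dataclass
class PlaceResult:
    vector_length: float
    preferred_cm: float
    n_onsets: int
    p_value: float
    is_place: bool
    reason: str = ""


@dataclass
class SpeedResult:
    bin_centers: np.ndarray
    bin_means: np.ndarray
    r: float
    shuffle_pass_fraction: float
    is_speed: bool
    reason: str = ""


def _occupancy_weights(
    position: np.ndarray,
    run_frames: np.ndarray,
    belt_length: float,
    frame_rate: float,
    n_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame occupancy time of each spatial bin over running frames."""
    bins = np.clip(
        (position[run_frames] / belt_length * n_bins).astype(int), 0, n_bins - 1
    )
    occ = np.bincount(bins, minlength=n_bins) / frame_rate  # seconds per bin
    return bins, occ


def spatial_tuning_vector(
    onset_frames: np.ndarray,
    position: np.ndarray,
    epochs: Epochs,
    belt_length: float,
    frame_rate: float = 15.0,
    n_bins: int = 50,
) -> tuple[float, float]:
    """Occupancy-weighted resultant vector of running-epoch onset positions.

    Returns ``(length, preferred_cm)``; length is in [0, 1] (1 = perfectly
    concentrated under any occupancy, since the weights are normalized to
    sum 1).  Raises if fewer than ``MIN_ONSETS`` running onsets are given.
    """
    run_mask = epochs.mask("run")
    run_frames = np.flatnonzero(run_mask)
    onsets = np.asarray(onset_frames, dtype=int)
    onsets = onsets[run_mask[onsets]]
    if onsets.size < MIN_ONSETS:
        raise ValueError(f"need >= {MIN_ONSETS} running-epoch onsets, got {onsets.size}")
    bins_of_run, occ = _occupancy_weights(position, run_frames, belt_length, frame_rate, n_bins)
    onset_bins = np.clip(
        (position[onsets] / belt_length * n_bins).astype(int), 0, n_bins - 1
    )
    w = 1.0 / occ[onset_bins]  # onset implies presence, so occupancy > 0
    w = w / w.sum()
    theta = 2 * np.pi * position[onsets] / belt_length
    resultant = np.sum(w * np.exp(1j * theta))
    angle = float(np.mod(np.angle(resultant), 2 * np.pi))
    return float(np.abs(resultant)), angle * belt_length / (2 * np.pi)


def _vector_lengths_batch(
    positions: np.ndarray, occ: np.ndarray, belt_length: float, n_bins: int
) -> np.ndarray:
    """Resultant lengths for a (n_shuffles, n_onsets) matrix of positions."""
    bins = np.clip((positions / belt_length * n_bins).astype(int), 0, n_bins - 1)
    w = 1.0 / occ[bins]
    w = w / w.sum(axis=1, keepdims=True)
    theta = 2 * np.pi * positions / belt_length
    return np.abs(np.sum(w * np.exp(1j * theta), axis=1))


def place_cell_test(
    onset_frames: np.ndarray,
    position: np.ndarray,
    epochs: Epochs,
    belt_length: float,
    frame_rate: float = 15.0,
    n_bins: int = 50,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> PlaceResult:
    """Shuffle test of the spatial tuning vector length.

    The null redraws the cell's onset times uniformly over running-epoch
    frames; p is the fraction of null vector lengths exceeding the observed
    one.  Cells with fewer than four running onsets are excluded (not place
    cells, with a reason).
    """
    run_mask = epochs.mask("run")
    onsets = np.asarray(onset_frames, dtype=int)
    onsets = onsets[run_mask[onsets]]
    if onsets.size < MIN_ONSETS:
        return PlaceResult(np.nan, np.nan, int(onsets.size), np.nan, False,
                           reason=f"fewer than {MIN_ONSETS} running onsets")
    length, pref = spatial_tuning_vector(
        onsets, position, epochs, belt_length, frame_rate, n_bins
    )
    run_frames = np.flatnonzero(run_mask)
    _, occ = _occupancy_weights(position, run_frames, belt_length, frame_rate, n_bins)
    rng = np.random.default_rng(seed)
    draw = rng.integers(0, run_frames.size, size=(n_shuffles, onsets.size))
    null = _vector_lengths_batch(
        position[run_frames[draw]], occ, belt_length, n_bins
    )
    p = float(np.count_nonzero(null > length) / n_shuffles)
    return PlaceResult(length, pref, int(onsets.size), p, bool(p < alpha))


def speed_tuning(
    dff_cell: np.ndarray, speed: np.ndarray, n_bins: int = 20
) -> SpeedResult:
    """Binned speed tuning curve and its linear correlation.

    Bins span [0, max speed]; empty bins are excluded from r.  Fewer than
    three non-empty bins, or a constant curve, leave r undefined (NaN, not a
    speed cell).
    """
    dff_cell = np.asarray(dff_cell, dtype=float)
    speed = np.asarray(speed, dtype=float)
    vmax = speed.max()
    if vmax <= 0:
        return SpeedResult(np.array([]), np.array([]), np.nan, np.nan, False,
                           reason="no nonzero speed")
    edges = np.linspace(0, vmax, n_bins + 1)
    idx = np.clip(np.digitize(speed, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=dff_cell, minlength=n_bins)
    nonempty = counts > 0
    centers = (edges[:-1] + edges[1:]) / 2
    means = np.full(n_bins, np.nan)
    means[nonempty] = sums[nonempty] / counts[nonempty]
    if np.count_nonzero(nonempty) < 3 or np.std(means[nonempty]) == 0:
        return SpeedResult(centers, means, np.nan, np.nan, False,
                           reason="fewer than 3 non-empty bins or constant curve")
    r = float(np.corrcoef(centers[nonempty], means[nonempty])[0, 1])
    return SpeedResult(centers, means, r, np.nan, False)


def speed_cell_test(
    dff_cell: np.ndarray,
    speed: np.ndarray,
    n_bins: int = 20,
    n_shuffles: int = 1000,
    min_shift_s: float = 5.0,
    frame_rate: float = 15.0,
    seed=None,
) -> SpeedResult:
    """Circular-shift significance test for speed coding.

    Requires a binned-curve Pearson r of at least 0.9 for candidacy; the cell
    is a speed coder if at least 95% of circularly time-shifted surrogates
    yield a smaller r.
    """
    res = speed_tuning(dff_cell, speed, n_bins)
    if not np.isfinite(res.r):
        return res
    n = len(dff_cell)
    min_shift = int(min_shift_s * frame_rate)
    if n < 2 * min_shift + 2:
        raise ValueError("trace shorter than twice the minimum circular shift")
    if res.r < SPEED_R_MIN:
        return SpeedResult(res.bin_centers, res.bin_means, res.r, np.nan, False,
                           reason=f"r < {SPEED_R_MIN}")
    # binning of behavior is fixed; only the trace shifts
    vmax = speed.max()
    edges = np.linspace(0, vmax, n_bins + 1)
    idx = np.clip(np.digitize(speed, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    nonempty = counts > 0
    centers = (edges[:-1] + edges[1:]) / 2
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_shuffles)
    below = 0
    x = centers[nonempty]
    for s in shifts:
        rolled = np.roll(dff_cell, s)
        sums = np.bincount(idx, weights=rolled, minlength=n_bins)
        means = sums[nonempty] / counts[nonempty]
        if np.std(means) == 0:
            below += 1
            continue
        r_s = np.corrcoef(x, means)[0, 1]
        below += r_s < res.r
    frac = below / n_shuffles
    return SpeedResult(
        res.bin_centers, res.bin_means, res.r, float(frac),
        bool(frac >= SPEED_SHUFFLE_PASS),
    )


def tuning_ne_incorporation(
    place_ids: set[int] | np.ndarray,
    speed_ids: set[int] | np.ndarray,
    pm: ParticipationMatrix,
) -> dict[str, float]:
    """How tuned cells and NEs intersect.

    Reports the fraction of place/speed cells participating in at least one
    NE (each tuned-cell population is its own 100%), and the fraction of NEs
    containing at least one place cell.  Undefined fractions (no tuned cells
    or no NEs) are NaN.
    """
    P = pm.P
    place = np.asarray(sorted(set(int(i) for i in place_ids)), dtype=int)
    speed = np.asarray(sorted(set(int(i) for i in speed_ids)), dtype=int)
    out: dict[str, float] = {}
    participates = P.sum(axis=1) > 0
    out["frac_place_in_ne"] = (
        float(participates[place].mean()) if place.size else np.nan
    )
    out["frac_speed_in_ne"] = (
        float(participates[speed].mean()) if speed.size else np.nan
    )
    if pm.n_nes and place.size:
        out["frac_ne_with_place"] = float((P[place].sum(axis=0) > 0).mean())
    else:
        out["frac_ne_with_place"] = np.nan
    return out
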