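"""Synchronous network-event (NE) detection against shuffle-derived nulls.

A network event is the simultaneous activation of several granule cells within
a moving 200 ms window (3 frames at 15 Hz, center frame +/- 1), where multiple
onsets of one cell inside a window count once.  The per-session size threshold
is the smallest number of synchronously active cells at which less than 0.1%
of such events (p < 0.001) can be explained by chance, with chance estimated
from shuffled rasters (default: 1000 shuffles).

Three shuffle methods are available, each conserving per-cell onset counts:

``redistribute``       onset times redrawn uniformly per cell (destroys all
                       temporal correlation),
``trace_shift``        each cell's full onset trace circularly shifted
                       (preserves within-cell inter-onset structure),
``state_constrained``  onsets redrawn uniformly *within* run frames and within
                       rest frames separately (preserves state-dependent rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

from .core_io import Epochs

__all__ = [
    "NetworkEventSet",
    "window_counts",
    "shuffle_raster",
    "size_threshold",
    "detect_network_events",
    "ne_state_stats",
]

WINDOW_FRAMES = 3  # 200 ms at 15 Hz

SHUFFLE_METHODS = ("redistribute", "trace_shift", "state_constrained")


@dataclass
class NetworkEventSet:
    """Detected NEs: peak frames, per-NE participant sets, and the threshold used."""

    ne_frames: np.ndarray
    ne_members: list[set[int]]
    size_threshold: float
    window_frames: int = WINDOW_FRAMES
    null_curves: dict = field(default_factory=dict)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.ne_members], dtype=int)

    def __len__(self) -> int:
        return len(self.ne_members)


def window_counts(raster: np.ndarray, window_frames: int = WINDOW_FRAMES) -> np.ndarray:
    """Per-frame count of distinct cells with >= 1 onset in the centered window.

    Edge frames use truncated windows.  ``window_frames`` must be odd.
    """
    if window_frames % 2 == 0 or window_frames < 1:
        raise ValueError("window_frames must be odd (centered window)")
    active = np.asarray(raster) != 0
    dilated = maximum_filter1d(
        active.astype(np.uint8), size=window_frames, axis=1, mode="constant", cval=0
    )
    return dilated.sum(axis=0).astype(np.int64)


def _sample_distinct(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    """k distinct entries of ``pool`` (uniform), fast for k << len(pool)."""
    n = pool.size
    if k >= n:
        return pool[rng.permutation(n)[:k]]
    idx = np.unique(rng.integers(0, n, size=k))
    while idx.size < k:
        idx = np.unique(np.concatenate([idx, rng.integers(0, n, size=k - idx.size)]))
    return pool[idx]


def shuffle_raster(
    raster: np.ndarray,
    method: str = "redistribute",
    epochs: Epochs | None = None,
    seed=None,
) -> np.ndarray:
    """Surrogate raster under one of the three null models (see module docstring).

    All methods conserve per-cell onset counts exactly; ``state_constrained``
    conserves them within run and within rest frames separately and requires
    ``epochs``.
    """
    if method not in SHUFFLE_METHODS:
        raise ValueError(f"unknown shuffle method {method!r}; choose from {SHUFFLE_METHODS}")
    rng = np.random.default_rng(seed)
    raster = np.asarray(raster)
    n_cells, n_frames = raster.shape
    out = np.zeros_like(raster)
    if method == "trace_shift":
        shifts = rng.integers(0, n_frames, size=n_cells)
        for c in range(n_cells):
            out[c] = np.roll(raster[c], shifts[c])
        return out
    if method == "redistribute":
        pools = [np.arange(n_frames)]
        pool_of_frame = np.zeros(n_frames, dtype=int)
    else:
        if epochs is None:
            raise ValueError("state_constrained shuffle requires epochs")
        run_m = epochs.mask("run")
        rest_m = epochs.mask("rest")
        other_m = ~(run_m | rest_m)
        pools = [np.flatnonzero(run_m), np.flatnonzero(rest_m), np.flatnonzero(other_m)]
        pool_of_frame = np.zeros(n_frames, dtype=int)
        pool_of_frame[pools[1]] = 1
        pool_of_frame[np.flatnonzero(other_m)] = 2
    for c in range(n_cells):
        onsets = np.flatnonzero(raster[c])
        if onsets.size == 0:
            continue
        for pi, pool in enumerate(pools):
            k = int(np.count_nonzero(pool_of_frame[onsets] == pi))
            if k:
                out[c, _sample_distinct(rng, pool, k)] = 1
    return out


def _event_size_curve(counts: np.ndarray, s_max: int) -> np.ndarray:
    """Number of merged candidate events with window count >= s, for s = 2..s_max."""
    curve = np.zeros(max(s_max - 1, 0), dtype=np.int64)
    for i, s in enumerate(range(2, s_max + 1)):
        above = counts >= s
        if not above.any():
            break  # monotone: larger s gives no events either
        n_events = int(above[0]) + int(np.count_nonzero(above[1:] & ~above[:-1]))
        curve[i] = n_events
    return curve


def size_threshold(
    raster: np.ndarray,
    epochs: Epochs | None = None,
    n_shuffles: int = 1000,
    alpha: float = 0.001,
    method: str = "redistribute",
    window_frames: int = WINDOW_FRAMES,
    threshold_rule: str = "ratio",
    report_methods: tuple[str, ...] | None = None,
    seed=None,
) -> tuple[float, dict]:
    """Per-session NE size threshold from a shuffle null.

    For every size s >= 2, candidate events are maximal runs of frames whose
    window count reaches s.  Under the default ``threshold_rule="ratio"`` the
    threshold is the smallest s at which the mean shuffle event count at >= s
    is below ``alpha`` times the real event count at >= s (i.e. less than
    0.1% of observed events explained by chance at the default alpha), or at
    which no real events remain.  ``threshold_rule="per_shuffle"`` instead
    requires the fraction of shuffles containing any event of size >= s to be
    below alpha.

    Returns ``(threshold, null_curves)``; ``null_curves`` maps each computed
    shuffle method to a dict with sizes, shuffle mean/sd counts and the real
    counts.  ``threshold`` is ``inf`` when no size qualifies.
    """
    if threshold_rule not in ("ratio", "per_shuffle"):
        raise ValueError("threshold_rule must be 'ratio' or 'per_shuffle'")
    raster = np.asarray(raster)
    if not (raster != 0).any():
        warnings.warn("raster has no onsets; threshold undefined")
        return float("inf"), {}
    counts = window_counts(raster, window_frames)
    s_max = max(int(counts.max()) + 2, 3)
    real = _event_size_curve(counts, s_max)
    sizes = np.arange(2, s_max + 1)

    methods = (method,) if report_methods is None else tuple(dict.fromkeys((method,) + report_methods))
    ss = np.random.SeedSequence(seed)
    null_curves: dict[str, dict] = {}
    threshold = float("inf")
    method_seeds = ss.spawn(len(methods))
    for m, child in zip(methods, method_seeds):
        rngs = child.spawn(n_shuffles)
        null = np.zeros((n_shuffles, sizes.size), dtype=np.int64)
        for j in range(n_shuffles):
            sh = shuffle_raster(raster, m, epochs, seed=rngs[j])
            null[j] = _event_size_curve(window_counts(sh, window_frames), s_max)
        null_curves[m] = {
            "sizes": sizes,
            "shuffle_mean": null.mean(axis=0),
            "shuffle_sd": null.std(axis=0),
            "real": real,
        }
        if m == method:
            mean_null = null.mean(axis=0)
            any_frac = (null > 0).mean(axis=0)
            for i, s in enumerate(sizes):
                if threshold_rule == "ratio":
                    ok = real[i] == 0 or mean_null[i] < alpha * real[i]
                else:
                    ok = any_frac[i] < alpha
                if ok:
                    threshold = float(s)
                    break
    if not np.isfinite(threshold):
        warnings.warn("no size satisfied the threshold rule; threshold = inf")
    return threshold, null_curves


def detect_network_events(
    raster: np.ndarray,
    threshold: float,
    window_frames: int = WINDOW_FRAMES,
    null_curves: dict | None = None,
) -> NetworkEventSet:
    """Detect NEs as maximal supra-threshold runs of the window-count trace.

    Overlapping supra-threshold windows merge into a single NE whose peak
    frame is the count argmax within the run (earliest on tie); members are
    all cells with an onset inside the run span extended by the half window.
    """
    if threshold < 2:
        raise ValueError("threshold must be >= 2")
    raster = np.asarray(raster)
    counts = window_counts(raster, window_frames)
    hw = window_frames // 2
    above = counts >= threshold
    frames: list[int] = []
    members: list[set[int]] = []
    if above.any():
        d = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(above.size)
        for s, e in zip(starts, ends):
            peak = s + int(np.argmax(counts[s:e]))
            lo = max(s - hw, 0)
            hi = min(e + hw, raster.shape[1])
            cells = np.flatnonzero((raster[:, lo:hi] != 0).any(axis=1))
            frames.append(peak)
            members.append(set(int(c) for c in cells))
    return NetworkEventSet(
        ne_frames=np.asarray(frames, dtype=int),
        ne_members=members,
        size_threshold=float(threshold),
        window_frames=window_frames,
        null_curves=null_curves or {},
    )


def _state_of_frames(frames: np.ndarray, epochs: Epochs) -> np.ndarray:
    state = np.full(epochs.n_frames, "none", dtype=object)
    state[epochs.mask("run")] = "run"
    state[epochs.mask("rest")] = "rest"
    return state[frames]


def ne_state_stats(
    ne_set: NetworkEventSet,
    epochs: Epochs,
    frame_rate: float,
    min_rest_period_s: float = 5.0,
    seed=None,
) -> dict:
    """State-dependent NE statistics.

    Reports per-state counts and per-minute frequencies, duration-equalized
    frequencies (the longer state subsampled to the shorter state's total
    duration by a seeded contiguous chunk), the cumulative occurrence curve
    over session time, and the pooled cumulative position of NEs within rest
    periods longer than ``min_rest_period_s`` (each period normalized to its
    length).
    """
    rng = np.random.default_rng(seed)
    frames = ne_set.ne_frames
    states = _state_of_frames(frames, epochs) if frames.size else np.array([], dtype=object)
    out: dict = {}
    durs = {st: epochs.duration_s(st, frame_rate) for st in ("run", "rest")}
    for st in ("run", "rest"):
        cnt = int(np.count_nonzero(states == st))
        out[f"count_{st}"] = cnt
        out[f"freq_per_min_{st}"] = cnt / (durs[st] / 60.0) if durs[st] > 0 else np.nan

    # duration-equalized frequencies: clip the longer state to a random
    # contiguous stretch of the shorter state's duration
    short, long_ = ("run", "rest") if durs["run"] <= durs["rest"] else ("rest", "run")
    out["equalized"] = {}
    if durs[short] > 0:
        long_frames = epochs.frames(long_)
        need = int(round(durs[short] * frame_rate))
        start = rng.integers(0, max(long_frames.size - need, 0) + 1)
        keep = set(long_frames[start : start + need].tolist())
        cnt_long = sum(
            1 for f, st in zip(frames, states) if st == long_ and int(f) in keep
        )
        out["equalized"][short] = out[f"count_{short}"] / (durs[short] / 60.0)
        out["equalized"][long_] = cnt_long / (durs[short] / 60.0)

    # cumulative occurrence over session time
    n_frames = epochs.n_frames
    if frames.size:
        out["cumulative_session"] = (
            np.sort(frames) / n_frames,
            np.arange(1, frames.size + 1) / frames.size,
        )
    else:
        out["cumulative_session"] = (np.array([]), np.array([]))

    # NEs positioned within long rest periods, each normalized to its length
    positions = []
    min_len = int(min_rest_period_s * frame_rate)
    for s, e in epochs.rest:
        if e - s < min_len:
            continue
        inside = frames[(frames >= s) & (frames < e)]
        positions.extend(((inside - s) / (e - s)).tolist())
    out["rest_period_positions"] = np.asarray(sorted(positions))
    return out
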