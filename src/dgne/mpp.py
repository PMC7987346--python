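"""Bulk MPP input-signal analysis.

The bulk fluorescence trace of the medial perforant path is converted to
dF/F against a very slow (0.01 Hz low-pass) baseline, deconvolved with a
nonnegative sparse inversion under an exponential-decay kernel to obtain an
activity proxy and discrete transient events, and compared to summed granule
cell activity by state statistics, cross-correlation during immobility, a
bivariate Granger F-test, and NE-aligned timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .core_io import Epochs

__all__ = [
    "BulkEvents",
    "GrangerResult",
    "bulk_dff",
    "deconvolve_bulk",
    "bulk_event_state_stats",
    "mpp_gc_crosscorr",
    "granger_test",
    "ne_mpp_delay",
]


@dataclass
class BulkEvents:
    """Deconvolved bulk transients: onset frames and amplitudes.

    ``amplitudes`` are normalized to the standard deviation of the activity
    proxy (per-session units); ``raw_amplitudes`` keep the dF/F scale.
    """

    frames: np.ndarray
    amplitudes: np.ndarray
    raw_amplitudes: np.ndarray
    tau_s: float
    proxy: np.ndarray | None = None

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass
class GrangerResult:
    order: int
    f_stat: float
    p_value: float


def bulk_dff(
    mpp_raw: np.ndarray,
    frame_rate: float,
    baseline_cutoff_hz: float = 0.01,
    filter_order: int = 2,
) -> np.ndarray:
    """dF/F of the bulk trace against a zero-phase low-pass baseline.

    The baseline is the raw trace low-pass filtered at ``baseline_cutoff_hz``
    (Butterworth, zero phase); raw fluorescence must keep the baseline
    positive everywhere.
    """
    mpp_raw = np.asarray(mpp_raw, dtype=float)
    if mpp_raw.size < int(2 * frame_rate / baseline_cutoff_hz * 0.1):
        raise ValueError("trace too short for the requested baseline cutoff")
    sos = signal.butter(filter_order, baseline_cutoff_hz, fs=frame_rate, output="sos")
    baseline = signal.sosfiltfilt(sos, mpp_raw)
    if np.any(baseline <= 0):
        raise ValueError("baseline is non-positive; raw fluorescence must be positive")
    return (mpp_raw - baseline) / baseline


def _ar1_forward(s: np.ndarray, g: float) -> np.ndarray:
    """Convolution with the exponential-decay kernel h[t] = g**t."""
    return signal.lfilter([1.0], [1.0, -g], s)


def _ar1_adjoint(r: np.ndarray, g: float) -> np.ndarray:
    return signal.lfilter([1.0], [1.0, -g], r[::-1])[::-1]


def _noise_sd(y: np.ndarray) -> float:
    """Robust noise estimate from the median absolute first difference."""
    return float(np.median(np.abs(np.diff(y))) / (0.6745 * np.sqrt(2))) if y.size > 1 else 0.0


def deconvolve_bulk(
    dff: np.ndarray,
    frame_rate: float = 15.0,
    tau_s: float = 1.5,
    sparsity: float = 2.5,
    n_iter: int = 300,
) -> BulkEvents:
    """Nonnegative sparse deconvolution of the bulk dF/F trace.

    Solves ``min 0.5*||K s - y||^2 + lam*||s||_1, s >= 0`` (FISTA) where K is
    the exponential-decay kernel with time constant ``tau_s``; ``lam`` scales
    with a robust noise estimate (``sparsity`` noise SDs per unit kernel
    norm), so a noiseless trace is inverted essentially exactly.  Contiguous
    nonzero runs of the proxy collapse to one event at the run's argmax, with
    amplitude equal to the run's summed activity.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    y = np.asarray(dff, dtype=float)
    g = float(np.exp(-1.0 / (tau_s * frame_rate)))
    if not np.any(y != 0):
        return BulkEvents(
            frames=np.array([], dtype=int),
            amplitudes=np.array([]),
            raw_amplitudes=np.array([]),
            tau_s=tau_s,
            proxy=np.zeros_like(y),
        )
    sigma = _noise_sd(y)
    kern_norm = 1.0 / np.sqrt(1.0 - g**2)  # l2 norm of the decay kernel
    lam = sparsity * sigma * kern_norm
    # operator norm of the convolution is sup |H(w)| = 1/(1-g), reached at DC
    L = (1.0 / (1.0 - g)) ** 2 * 1.05
    s = np.zeros_like(y)
    z = s.copy()
    t_k = 1.0
    for _ in range(n_iter):
        grad = _ar1_adjoint(_ar1_forward(z, g) - y, g)
        s_new = np.maximum(z - (grad + lam) / L, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_k**2)) / 2.0
        z = s_new + (t_k - 1.0) / t_new * (s_new - s)
        s, t_k = s_new, t_new
    proxy = s
    active = proxy > max(1e-12, 1e-6 * proxy.max())
    frames: list[int] = []
    raw_amp: list[float] = []
    if active.any():
        d = np.diff(active.astype(np.int8))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if active[0]:
            starts.insert(0, 0)
        if active[-1]:
            ends.append(active.size)
        for a, b in zip(starts, ends):
            frames.append(a + int(np.argmax(proxy[a:b])))
            raw_amp.append(float(proxy[a:b].sum()))
    frames_arr = np.asarray(frames, dtype=int)
    raw = np.asarray(raw_amp)
    sd = proxy.std()
    amps = raw / sd if sd > 0 else raw
    return BulkEvents(
        frames=frames_arr, amplitudes=amps, raw_amplitudes=raw, tau_s=tau_s, proxy=proxy
    )


def bulk_event_state_stats(
    events: BulkEvents, epochs: Epochs, frame_rate: float, sd_factor: float = 2.0
) -> dict:
    """Per-state frequencies and amplitudes of bulk events.

    Large events have amplitudes above ``mean + sd_factor * sd`` computed over
    all events of the session.
    """
    out: dict = {}
    amp = events.amplitudes
    large_cut = amp.mean() + sd_factor * amp.std() if amp.size else np.inf
    is_large = amp > large_cut
    for st in ("run", "rest"):
        mask = epochs.mask(st)
        dur_min = epochs.duration_s(st, frame_rate) / 60.0
        in_state = mask[events.frames] if len(events) else np.array([], dtype=bool)
        out[f"count_{st}"] = int(in_state.sum())
        out[f"freq_per_min_{st}"] = out[f"count_{st}"] / dur_min if dur_min > 0 else np.nan
        out[f"amplitudes_{st}"] = amp[in_state]
        n_large = int((in_state & is_large).sum())
        out[f"large_freq_per_min_{st}"] = n_large / dur_min if dur_min > 0 else np.nan
    out["large_cut"] = float(large_cut)
    return out


def mpp_gc_crosscorr(
    mpp_dff: np.ndarray,
    gc_sum: np.ndarray,
    epochs: Epochs,
    frame_rate: float,
    max_lag_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of MPP and summed GC activity during rest.

    Both signals are restricted to rest frames (epochs concatenated),
    z-scored, and correlated at lags up to ``max_lag_s``.  A positive lag
    means the MPP signal leads.  Returns ``(lags_s, cc)``.
    """
    rest = epochs.frames("rest")
    x = np.asarray(mpp_dff, dtype=float)[rest]
    y = np.asarray(gc_sum, dtype=float)[rest]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant signal; cross-correlation undefined")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    max_lag = int(max_lag_s * frame_rate)
    n = x.size
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.array([
        np.dot(x[max(0, -k) : n - max(0, k)], y[max(0, k) : n - max(0, -k)]) / n
        for k in lags
    ])
    return lags / frame_rate, cc


def _lagged(x: np.ndarray, order: int, start: int) -> np.ndarray:
    return np.column_stack([x[start - k : len(x) - k] for k in range(1, order + 1)])


def granger_test(
    x: np.ndarray,
    y: np.ndarray,
    max_order: int = 15,
    order_rule: str = "bic",
) -> GrangerResult:
    """Does x Granger-cause y?  Nested-AR F-test at an IC-chosen order.

    The lag order minimizes the information criterion (BIC or AIC) of the
    full bivariate model; the F statistic compares the restricted AR model of
    y against the full model including lags of x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(y) < 10 * max_order:
        raise ValueError("series too short for the requested maximum order")
    crit = {"bic": np.log(len(y)), "aic": 2.0}[order_rule.lower()]

    def rss(design: np.ndarray, target: np.ndarray) -> float:
        A = np.column_stack([np.ones(len(target)), design])
        coef, *_ = np.linalg.lstsq(A, target, rcond=None)
        r = target - A @ coef
        return float(r @ r)

    best = None
    for p in range(1, max_order + 1):
        t = y[p:]
        full = np.column_stack([_lagged(y, p, p), _lagged(x, p, p)])
        r_full = rss(full, t)
        n_eff = len(t)
        k = 2 * p + 1
        ic = n_eff * np.log(max(r_full / n_eff, 1e-300)) + crit * k
        if best is None or ic < best[0]:
            best = (ic, p, r_full)
    _, p, rss_full = best
    t = y[p:]
    rss_restr = rss(_lagged(y, p, p), t)
    n_eff = len(t)
    df2 = n_eff - (2 * p + 1)
    f_stat = ((rss_restr - rss_full) / p) / (rss_full / df2)
    p_val = float(stats.f.sf(f_stat, p, df2))
    return GrangerResult(order=p, f_stat=float(f_stat), p_value=p_val)


def ne_mpp_delay(
    ne_frames: np.ndarray, events: BulkEvents, frame_rate: float
) -> np.ndarray:
    """Signed delay (s) from each NE to the closest bulk MPP event.

    Positive values mean the MPP event precedes the NE (MPP leads).
    """
    ne = np.asarray(ne_frames, dtype=int)
    if ne.size == 0 or len(events) == 0:
        raise ValueError("need non-empty NE and MPP event sets")
    ev = np.sort(events.frames)
    idx = np.searchsorted(ev, ne)
    idx_lo = np.clip(idx - 1, 0, ev.size - 1)
    idx_hi = np.clip(idx, 0, ev.size - 1)
    lo, hi = ev[idx_lo], ev[idx_hi]
    nearest = np.where(np.abs(ne - lo) <= np.abs(hi - ne), lo, hi)
    return (ne - nearest) / frame_rate
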