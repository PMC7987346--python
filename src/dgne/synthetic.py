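"""Synthetic session generator with planted ground truth.

Emulates the statistical structure of dentate gyrus recordings on a treadmill:
sparse granule-cell event onsets (~1 event/min/cell), immobility-locked
synchronous network events recruiting ~5-7% of cells, correlated sub-ensembles
that co-activate across multiple network events, a small minority of place- and
speed-tuned cells, bulk MPP input transients that lead network events, and
pupil constriction at network events.  Everything planted is recorded in
:class:`GroundTruth`, so each analysis stage can be scored against a known
answer.  The generator makes no claim of biophysical realism; it is test
scaffolding with field-plausible parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .core_io import Epochs, SessionRecording

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_behavior",
    "plant_raster",
    "events_to_dff",
    "generate_mpp_pupil",
    "generate_session",
    "generate_population_session",
]


@dataclass
class GeneratorParams:
    """Knobs of the synthetic session.

    Defaults mirror the recorded conditions: 20-minute sessions at 15 Hz on a
    150 cm belt, ~1 onset/min/cell background rate, ~30 network events of
    ~11 cells (≈5.7% of 200 cells) during immobility, four sub-ensembles of
    7 cells, 5% place cells (von-Mises tuning, κ=4) and 2% speed cells.
    """

    n_cells: int = 200
    duration_s: float = 1200.0
    frame_rate: float = 15.0
    belt_length: float = 150.0
    baseline_rate: float = 1.0           # events / min / cell
    # behavior: alternating rest/run bouts; ~20% of time running at
    # 8-20 cm/s gives the habituated 30-40 m per 20-min session
    run_bout_mean_s: float = 8.0
    rest_bout_mean_s: float = 30.0
    min_run_bout_s: float = 4.0
    speed_range: tuple[float, float] = (8.0, 20.0)
    speed_ramp_s: float = 1.0
    # network events
    n_planted_nes: int = 30
    ne_size_mean: float = 11.0
    ne_size_sd: float = 2.0
    # observed NE sizes are truncated at the per-session chance threshold;
    # planted sizes stay in the detectable range the recordings report
    ne_size_min: int = 8
    n_clusters: int = 4
    cluster_size: int = 7
    cluster_participation: float = 0.9
    # tuned cells
    place_frac: float = 0.05
    place_kappa: float = 4.0
    place_extra_onsets: float = 25.0     # expected extra in-field run onsets / session
    speed_frac: float = 0.02
    speed_slope: float = 0.2             # relative onset-rate gain per cm/s
    speed_rate_mult: float = 2.0         # mild overall activity elevation
    speed_dff_gain: float = 0.06         # graded dF/F per cm/s (sub-onset activity)
    # MPP bulk channel
    mpp_lead_frames: int = 2
    mpp_baseline: float = 100.0
    mpp_drift_amp: float = 2.0
    mpp_drift_period_s: float = 300.0
    mpp_run_rate_hz: float = 1.0
    mpp_run_amp: float = 1.5
    mpp_ne_amp: float = 15.0
    mpp_noise_sd: float = 0.3
    # pupil channel
    pupil_run_level: float = 1.15
    pupil_rest_level: float = 0.95
    pupil_ne_dip: float = 0.15
    pupil_dip_width_s: float = 0.6
    pupil_tau_s: float = 1.0
    pupil_noise_sd: float = 0.01
    blink_prob: float = 0.005
    # calcium forward model
    calcium_tau_s: float = 1.5
    calcium_amp: float = 1.0
    noise_sd: float = 0.05

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def validate(self) -> None:
        if self.ne_size_mean > self.n_cells:
            raise ValueError("planted NE size exceeds number of cells")
        for name in ("baseline_rate", "duration_s", "frame_rate", "belt_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("place_frac", "speed_frac", "cluster_participation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    ne_frames: np.ndarray                    # planted NE peak frames
    ne_members: list[set[int]]               # cells active in each NE
    cluster_members: list[set[int]]          # planted sub-ensembles
    place_cells: dict[int, tuple[float, float]]   # cell -> (preferred cm, kappa)
    speed_cells: dict[int, float]            # cell -> rate slope (1 / (cm/s))
    mpp_event_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    params_used: dict = field(default_factory=dict)
    seed: int | None = None


def _sample_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct integers from range(n); fast for k << n via rejection."""
    if k >= n:
        return rng.permutation(n)[:k]
    out = np.unique(rng.integers(0, n, size=k))
    while out.size < k:
        extra = rng.integers(0, n, size=k - out.size)
        out = np.unique(np.concatenate([out, extra]))
    return out


def generate_behavior(p: GeneratorParams, seed) -> tuple[np.ndarray, np.ndarray, Epochs]:
    """Alternating rest/run bouts; speed is 0 at rest and ramped during runs.

    Position integrates speed modulo the belt length.
    """
    p.validate()
    rng = np.random.default_rng(seed)
    fr = p.frame_rate
    n = p.n_frames
    speed = np.zeros(n)
    run_ivals: list[tuple[int, int]] = []
    rest_ivals: list[tuple[int, int]] = []
    t = 0
    state_rest = True
    while t < n:
        if state_rest:
            dur = rng.gamma(2.0, p.rest_bout_mean_s / 2.0)
            d = max(int(round(dur * fr)), int(3 * fr))
            e = min(t + d, n)
            rest_ivals.append((t, e))
        else:
            dur = rng.gamma(2.0, p.run_bout_mean_s / 2.0)
            dur = max(dur, p.min_run_bout_s)
            d = int(round(dur * fr))
            e = min(t + d, n)
            plateau = rng.uniform(*p.speed_range)
            ramp = max(int(p.speed_ramp_s * fr), 1)
            prof = np.full(e - t, plateau)
            k = min(ramp, len(prof))
            prof[:k] *= np.linspace(0.3, 1.0, k)
            prof[-k:] *= np.linspace(1.0, 0.3, k)[-k:]
            # smooth within-bout jitter, kept above the 4 cm/s run threshold
            jitter = rng.normal(0, 0.08 * plateau, size=e - t)
            win = max(min(int(fr), e - t), 1)
            jitter = np.convolve(jitter, np.ones(win) / win, mode="same")
            prof = np.maximum(prof + jitter, 4.5)
            speed[t:e] = prof
            run_ivals.append((t, e))
        t = e
        state_rest = not state_rest
    position = np.mod(np.cumsum(speed) / fr, p.belt_length)
    epochs = Epochs(run=tuple(run_ivals), rest=tuple(rest_ivals), n_frames=n)
    return speed, position, epochs


def plant_raster(
    p: GeneratorParams, behavior: tuple[np.ndarray, np.ndarray, Epochs], seed
) -> tuple[np.ndarray, GroundTruth]:
    """Poisson background onsets plus planted NEs, sub-ensembles and tuned cells.

    Planted NEs sit inside rest epochs; each recruits one designated cluster
    (members included with probability ``cluster_participation``) padded with
    random filler cells up to the drawn size, with member onsets jittered by
    at most one frame around the NE peak.
    """
    p.validate()
    rng = np.random.default_rng(seed)
    speed, position, epochs = behavior
    n, fr = p.n_frames, p.frame_rate
    raster = np.zeros((p.n_cells, n), dtype=np.int8)

    # --- cell role assignment (disjoint pools) -----------------------------
    perm = rng.permutation(p.n_cells)
    cursor = 0
    clusters: list[set[int]] = []
    for _ in range(p.n_clusters):
        clusters.append(set(perm[cursor : cursor + p.cluster_size].tolist()))
        cursor += p.cluster_size
    n_place = int(round(p.place_frac * p.n_cells))
    place_ids = perm[cursor : cursor + n_place]
    cursor += n_place
    n_speed = int(round(p.speed_frac * p.n_cells))
    speed_ids = perm[cursor : cursor + n_speed]

    # --- background Poisson onsets (speed cells rate-scaled) ----------------
    base_p = p.baseline_rate / 60.0 / fr
    prob = np.full((p.n_cells, n), base_p)
    for c in speed_ids:
        prob[c] = base_p * p.speed_rate_mult * (1.0 + p.speed_slope * speed)
    raster[rng.random((p.n_cells, n)) < prob] = 1

    # --- place cells: extra in-field onsets during run ----------------------
    place_cells: dict[int, tuple[float, float]] = {}
    run_frames = epochs.frames("run")
    theta = 2 * np.pi * position / p.belt_length
    for c in place_ids:
        mu = rng.uniform(0, 2 * np.pi)
        place_cells[int(c)] = (mu * p.belt_length / (2 * np.pi), p.place_kappa)
        if run_frames.size == 0:
            continue
        dens = np.exp(p.place_kappa * np.cos(theta[run_frames] - mu))
        dens = dens / dens.sum()
        n_extra = rng.poisson(p.place_extra_onsets)
        if n_extra:
            hits = rng.choice(run_frames, size=n_extra, p=dens)
            raster[c, hits] = 1

    # --- planted network events during rest ---------------------------------
    rest_pool = [iv for iv in epochs.rest if iv[1] - iv[0] > 12]
    candidate = np.concatenate(
        [np.arange(s + 3, e - 3) for s, e in rest_pool]
    ) if rest_pool else np.array([], dtype=int)
    ne_frames: list[int] = []
    ne_members: list[set[int]] = []
    if p.n_planted_nes and candidate.size:
        chosen: list[int] = []
        shuffled = rng.permutation(candidate)
        for f in shuffled:
            if all(abs(f - g) >= 10 for g in chosen):
                chosen.append(int(f))
            if len(chosen) == p.n_planted_nes:
                break
        chosen.sort()
        others = np.setdiff1d(np.arange(p.n_cells), perm[: p.n_clusters * p.cluster_size])
        cluster_of_ne = rng.permuted(
            np.resize(np.arange(max(p.n_clusters, 1)), len(chosen))
        )
        for i, f in enumerate(chosen):
            size = int(round(rng.normal(p.ne_size_mean, p.ne_size_sd)))
            size = int(np.clip(size, p.ne_size_min, p.n_cells))
            members: set[int] = set()
            if clusters:
                cl = clusters[cluster_of_ne[i]]
                members |= {c for c in cl if rng.random() < p.cluster_participation}
            if len(members) < size:
                fill = rng.permutation(others)[: size - len(members)]
                members |= set(int(c) for c in fill)
            for c in members:
                raster[c, int(np.clip(f + rng.integers(-1, 2), 0, n - 1))] = 1
            ne_frames.append(f)
            ne_members.append(members)

    gt = GroundTruth(
        ne_frames=np.asarray(ne_frames, dtype=int),
        ne_members=ne_members,
        cluster_members=clusters,
        place_cells=place_cells,
        speed_cells={int(c): p.speed_slope for c in speed_ids},
        params_used=asdict(p),
        seed=None if not np.isscalar(seed) else int(seed),
    )
    return raster, gt


def events_to_dff(
    raster: np.ndarray,
    tau_s: float = 1.5,
    frame_rate: float = 15.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
    seed=None,
) -> np.ndarray:
    """Forward calcium model: instantaneous rise, exponential decay, white noise.

    Each onset adds ``amplitude * exp(-t / tau)``; contributions superpose
    linearly (single-exponential GCaMP6s-like kernel).
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    rng = np.random.default_rng(seed)
    g = np.exp(-1.0 / (tau_s * frame_rate))
    dff = signal.lfilter([amplitude], [1.0, -g], raster.astype(float), axis=-1)
    if noise_sd > 0:
        dff = dff + rng.normal(0.0, noise_sd, size=dff.shape)
    return dff


def generate_mpp_pupil(
    p: GeneratorParams,
    behavior: tuple[np.ndarray, np.ndarray, Epochs],
    ne_frames: np.ndarray,
    seed,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bulk MPP trace, pupil trace and blink mask.

    MPP: slow baseline drift, small frequent transients during running, and a
    large transient leading every NE by ``mpp_lead_frames``.  Pupil: dilation
    toward ``pupil_run_level`` during running, relaxation to ``pupil_rest_level``
    at rest, a transient dip centered on each NE, and sporadic blink frames.

    Returns (mpp, pupil, blink_mask, planted_mpp_event_frames).
    """
    rng = np.random.default_rng(seed)
    speed, position, epochs = behavior
    n, fr = p.n_frames, p.frame_rate
    t = np.arange(n) / fr

    impulses = np.zeros(n)
    mpp_event_frames: list[int] = []
    run_mask = epochs.mask("run")
    small = (rng.random(n) < p.mpp_run_rate_hz / fr) & run_mask
    for f in np.flatnonzero(small):
        impulses[f] += rng.exponential(p.mpp_run_amp)
        mpp_event_frames.append(int(f))
    for f in np.asarray(ne_frames, dtype=int):
        g = int(np.clip(f - p.mpp_lead_frames, 0, n - 1))
        impulses[g] += p.mpp_ne_amp * rng.uniform(0.8, 1.2)
        mpp_event_frames.append(g)
    gdec = np.exp(-1.0 / (p.calcium_tau_s * fr))
    transients = signal.lfilter([1.0], [1.0, -gdec], impulses)
    drift = p.mpp_drift_amp * np.sin(2 * np.pi * t / p.mpp_drift_period_s + rng.uniform(0, 2 * np.pi))
    mpp = p.mpp_baseline + drift + transients + rng.normal(0, p.mpp_noise_sd, n)

    target = np.where(run_mask, p.pupil_run_level, p.pupil_rest_level)
    a = 1.0 - np.exp(-1.0 / (p.pupil_tau_s * fr))
    pupil = np.empty(n)
    pupil[0] = target[0]
    for i in range(1, n):  # first-order relaxation toward the state level
        pupil[i] = pupil[i - 1] + a * (target[i] - pupil[i - 1])
    width = max(p.pupil_dip_width_s * fr / 2.355, 1.0)  # FWHM -> sigma
    half = int(np.ceil(4 * width))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / width) ** 2)
    dips = np.zeros(n)
    dips[np.clip(np.asarray(ne_frames, dtype=int), 0, n - 1)] = 1.0
    pupil = pupil - p.pupil_ne_dip * np.convolve(dips, kern, mode="same")
    pupil = pupil + rng.normal(0, p.pupil_noise_sd, n)
    blink = (rng.random(n) < p.blink_prob).astype(np.int8)
    pupil[blink == 1] = 0.0
    pupil = np.maximum(pupil, 0.0)
    return mpp, pupil, blink, np.unique(np.asarray(mpp_event_frames, dtype=int))


def generate_session(
    p: GeneratorParams | None = None, seed: int = 0
) -> tuple[SessionRecording, GroundTruth]:
    """Compose behavior, raster, dF/F, MPP and pupil into one valid session.

    Deterministic given ``(p, seed)``: one master seed spawns independent
    child streams per stage.
    """
    p = p or GeneratorParams()
    p.validate()
    ss = np.random.SeedSequence(seed)
    s_beh, s_rast, s_dff, s_mp = ss.spawn(4)
    behavior = generate_behavior(p, s_beh)
    raster, gt = plant_raster(p, behavior, s_rast)
    gt.seed = int(seed)
    dff = events_to_dff(
        raster, p.calcium_tau_s, p.frame_rate, p.calcium_amp, p.noise_sd, s_dff
    )
    # speed cells additionally show graded, kernel-filtered fluorescence that
    # tracks running speed (activity below the event-detection threshold)
    if gt.speed_cells and p.speed_dff_gain > 0:
        speed, _, _ = behavior
        g = np.exp(-1.0 / (p.calcium_tau_s * p.frame_rate))
        graded = signal.lfilter([1.0 - g], [1.0, -g], speed)  # unit DC gain
        for c in gt.speed_cells:
            dff[c] += p.speed_dff_gain * graded
    mpp, pupil, blink, mpp_frames = generate_mpp_pupil(p, behavior, gt.ne_frames, s_mp)
    gt.mpp_event_frames = mpp_frames
    speed, position, _ = behavior
    rec = SessionRecording(
        raster=raster,
        dff=dff,
        speed=speed,
        position=position,
        frame_rate=p.frame_rate,
        belt_length=p.belt_length,
        session_id=f"synthetic-{seed}",
        mpp=mpp,
        pupil=pupil,
        blink=blink,
    )
    return rec, gt


def generate_population_session(
    n_cells: int = 100,
    n_factors: int = 5,
    n_run_frames: int = 3000,
    n_nes: int = 20,
    ne_window_frames: int = 31,
    frame_rate: float = 15.0,
    replay: bool = True,
    factor_sd: float = 1.0,
    shared_gain: float = 10.0,
    private_gain: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, Epochs, np.ndarray]:
    """Factor-model population control for subspace-similarity analyses.

    Run-epoch activity is a low-rank latent-factor process (loadings L,
    smooth factors) plus per-cell private slow variability and white noise.
    During each NE window the population either re-expresses the *same*
    shared factors (``replay=True``; the NE covariance shares the run
    subspace) or shows only private/isotropic activity (``replay=False``;
    no shared structure beyond chance).  The private component keeps
    single-cell statistics realistic and ensures that subspace similarity
    can only come from genuine cell-cell co-fluctuation.

    Returns ``(dff, epochs, ne_frames)`` with one run epoch followed by one
    rest epoch containing the NE windows.
    """
    rng = np.random.default_rng(seed)
    half = ne_window_frames // 2
    gap = ne_window_frames + 10
    n_rest = int(n_nes * gap + 4 * half + 20)
    n = n_run_frames + n_rest
    L = rng.normal(0, 1, size=(n_cells, n_factors))
    L /= np.linalg.norm(L, axis=1, keepdims=True)  # equal per-cell coupling:
    # similarity must come from cell-cell correlation, not variance profiles

    def smooth(rows, m):
        f = rng.normal(0, factor_sd, size=(rows, m))
        win = int(frame_rate / 2)
        k = np.ones(win) / np.sqrt(win)
        return np.apply_along_axis(lambda v: np.convolve(v, k, mode="same"), 1, f)

    X = rng.normal(0, noise_sd, size=(n_cells, n)) * 0.2
    X += private_gain * smooth(n_cells, n)
    X[:, :n_run_frames] += shared_gain * (L @ smooth(n_factors, n_run_frames))
    ne_frames = n_run_frames + half + 5 + gap * np.arange(n_nes)
    for f in ne_frames:
        sl = slice(f - half, f + half + 1)
        if replay:
            X[:, sl] += shared_gain * (L @ smooth(n_factors, ne_window_frames))
        else:
            X[:, sl] += private_gain * smooth(n_cells, ne_window_frames)
    epochs = Epochs(
        run=((0, n_run_frames),), rest=((n_run_frames, n),), n_frames=n
    )
    return X, epochs, ne_frames.astype(int)
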