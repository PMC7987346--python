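"""PCA of population activity and run-vs-NE subspace similarity.

The z-scored dF/F matrix X (cells x frames) is decomposed by SVD as X = V W
with orthonormal principal directions V (cell space) and weights W.  Bases
are computed independently for locomotion data (X_run) and for 2 s windows
around network events (X_net), each truncated to the smallest number of
components explaining 50% of variance.  Similarity measures:

* projected variance ratio  trace(V_netT cov(X_run) V_net) /
  trace(V_runT cov(X_run) V_run)
* S_PCA = trace(V_netT V_run V_runT V_net) = sum_i cos^2(theta_i)
  (theta_i = principal angles between the subspaces)
* EROS  = sum_i w_i |cos(theta_i)| with paired component angles and
  eigenvalue-fraction weights (w normalized to sum 1)

each tested against three shuffle nulls that randomize only the NE side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import Epochs
from .behavior import LapIndex

__all__ = [
    "PCABasis",
    "SimilarityResult",
    "zscore_rows",
    "pca_basis",
    "extract_state_matrices",
    "projected_variance_ratio",
    "spca",
    "eros",
    "geometry_shuffle_test",
    "weight_lap_autocorr",
]

GEOMETRY_SHUFFLES = ("time_shift", "within_ne_identity", "per_cell_ne_reassign")


@dataclass
class PCABasis:
    """SVD basis of a population matrix.

    V has orthonormal columns (cell space), W = V.T X are the weights,
    eigenvalues are per-component variances, and k is the number of leading
    components that together explain at least ``var_frac`` of the variance.
    """

    V: np.ndarray
    W: np.ndarray
    eigenvalues: np.ndarray
    k: int
    var_frac: float

    @property
    def V_k(self) -> np.ndarray:
        return self.V[:, : self.k]

    @property
    def eig_frac(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class SimilarityResult:
    projected_variance_ratio: float
    s_pca: float
    eros: float
    principal_angles: np.ndarray
    k_run: int
    k_net: int
    null: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    p_values: dict[str, dict[str, float]] = field(default_factory=dict)


def zscore_rows(dff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scoring; constant rows are dropped with a warning.

    Returns ``(X, kept_row_indices)``.
    """
    dff = np.asarray(dff, dtype=float)
    sd = dff.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size == 0:
        raise ValueError("all rows are constant; nothing to z-score")
    if kept.size < dff.shape[0]:
        dropped = np.setdiff1d(np.arange(dff.shape[0]), kept)
        warnings.warn(f"dropped constant rows (cells): {dropped.tolist()}")
    X = (dff[kept] - dff[kept].mean(axis=1, keepdims=True)) / sd[kept, None]
    return X, kept


def pca_basis(X: np.ndarray, var_frac: float = 0.5) -> PCABasis:
    """Principal components of X by SVD, with the 50%-variance component count.

    Rows are centered before decomposition; rank-deficient inputs keep only
    the non-degenerate components.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = sv.max() * max(Xc.shape) * np.finfo(float).eps if sv.size else 0.0
    rank = int(np.count_nonzero(sv > tol))
    U, sv = U[:, :rank], sv[:rank]
    # deterministic sign: largest-magnitude loading positive
    for j in range(rank):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    eig = sv**2 / max(X.shape[1] - 1, 1)
    cum = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(cum, var_frac) + 1)
    return PCABasis(V=U, W=U.T @ X, eigenvalues=eig, k=k, var_frac=var_frac)


def _ne_window_slices(
    ne_frames: np.ndarray, half: int, n_frames: int
) -> list[tuple[int, int]]:
    return [
        (max(int(f) - half, 0), min(int(f) + half + 1, n_frames))
        for f in np.asarray(ne_frames, dtype=int)
    ]


def extract_state_matrices(
    X: np.ndarray,
    epochs: Epochs,
    ne_frames: np.ndarray,
    frame_rate: float = 15.0,
    ne_window_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Column subsets of X for running epochs and NE windows.

    NE windows are centered on the peak frames (+/- half of ``ne_window_s``),
    clipped at the recording edges; frames shared by overlapping windows
    appear once.
    """
    X = np.asarray(X, dtype=float)
    run = epochs.frames("run")
    if run.size == 0:
        raise ValueError("no running frames")
    ne_frames = np.asarray(ne_frames, dtype=int)
    if ne_frames.size == 0:
        raise ValueError("no network events")
    half = int(round(ne_window_s * frame_rate / 2))
    cols = np.unique(
        np.concatenate(
            [np.arange(a, b) for a, b in _ne_window_slices(ne_frames, half, X.shape[1])]
        )
    )
    return X[:, run], X[:, cols]


def projected_variance_ratio(
    X_run: np.ndarray, V_run: np.ndarray, V_net: np.ndarray
) -> float:
    """Run-activity covariance captured by the NE subspace, normalized by the
    run subspace's own capture."""
    if V_run.shape[0] != V_net.shape[0] or X_run.shape[0] != V_run.shape[0]:
        raise ValueError("cell dimensions do not match")
    C = np.cov(X_run)
    num = float(np.trace(V_net.T @ C @ V_net))
    den = float(np.trace(V_run.T @ C @ V_run))
    return num / den


def spca(V_a: np.ndarray, V_b: np.ndarray) -> tuple[float, np.ndarray]:
    """Krzanowski subspace similarity sum(cos^2 theta_i) and the principal angles.

    Bases are truncated to the smaller component count; angles come from the
    singular values of V_aT V_b.
    """
    k = min(V_a.shape[1], V_b.shape[1])
    if k == 0:
        raise ValueError("need at least one component")
    sv = np.linalg.svd(V_a[:, :k].T @ V_b[:, :k], compute_uv=False)
    sv = np.clip(sv, 0.0, 1.0)
    return float(np.sum(sv**2)), np.arccos(sv)


def eros(
    V_a: np.ndarray,
    V_b: np.ndarray,
    eigvals_a: np.ndarray,
    eigvals_b: np.ndarray,
) -> float:
    """EROS similarity: eigenvalue-weighted sum of |cos| of *paired* component angles.

    The weight of component i is the mean of the two bases' eigenvalue
    fractions at i, renormalized over the compared components to sum 1 (a
    two-matrix reduction of the corpus-level weighting in the original
    definition).
    """
    k = min(V_a.shape[1], V_b.shape[1])
    if k == 0:
        raise ValueError("need at least one component")
    fa = np.asarray(eigvals_a, dtype=float)
    fb = np.asarray(eigvals_b, dtype=float)
    fa = fa / fa.sum()
    fb = fb / fb.sum()
    w = (fa[:k] + fb[:k]) / 2.0
    w = w / w.sum()
    cosines = np.abs(np.sum(V_a[:, :k] * V_b[:, :k], axis=0))
    return float(np.sum(w * np.clip(cosines, 0.0, 1.0)))


def _similarity_measures(
    X_run: np.ndarray, basis_run: PCABasis, basis_net: PCABasis, C_run: np.ndarray
) -> tuple[float, float, float]:
    Vr, Vn = basis_run.V_k, basis_net.V_k
    num = float(np.trace(Vn.T @ C_run @ Vn))
    den = float(np.trace(Vr.T @ C_run @ Vr))
    s, _ = spca(Vn, Vr)
    e = eros(Vn, Vr, basis_net.eigenvalues, basis_run.eigenvalues)
    return num / den, s, e


def geometry_shuffle_test(
    X: np.ndarray,
    epochs: Epochs,
    ne_frames: np.ndarray,
    frame_rate: float = 15.0,
    ne_window_s: float = 2.0,
    methods: tuple[str, ...] = GEOMETRY_SHUFFLES,
    n_shuffles: int = 1000,
    var_frac: float = 0.5,
    min_shift_s: float = 5.0,
    seed=None,
) -> SimilarityResult:
    """Run-vs-NE subspace similarity with three shuffle nulls.

    The run basis and data stay fixed; each shuffle randomizes only the NE
    side and recomputes a surrogate NE basis V_rand:

    ``time_shift``            each cell's concatenated immobility trace is
                              circularly shifted (>= ``min_shift_s``) before
                              the original NE windows are re-applied;
    ``within_ne_identity``    within each NE window, cell rows are permuted
                              (NE sizes kept, composition randomized);
    ``per_cell_ne_reassign``  each cell's per-NE activity segments are
                              permuted across NEs (per-cell participation
                              kept, cell-cell pairings randomized).

    p per measure = fraction of shuffled values >= observed (one-sided).
    Only full-length NE windows enter the shuffled concatenated-NE matrix.
    """
    for m in methods:
        if m not in GEOMETRY_SHUFFLES:
            raise ValueError(f"unknown shuffle method {m!r}")
    X = np.asarray(X, dtype=float)
    n_frames = X.shape[1]
    half = int(round(ne_window_s * frame_rate / 2))
    win_len = 2 * half + 1
    ne_frames = np.asarray(ne_frames, dtype=int)
    full = ne_frames[(ne_frames - half >= 0) & (ne_frames + half < n_frames)]
    if full.size == 0:
        raise ValueError("no NE with a complete window")

    X_run, X_net = extract_state_matrices(X, epochs, ne_frames, frame_rate, ne_window_s)
    basis_run = pca_basis(X_run, var_frac)
    basis_net = pca_basis(X_net, var_frac)
    C_run = np.cov(X_run)
    pvr, s_pca_val, eros_val = _similarity_measures(X_run, basis_run, basis_net, C_run)
    _, angles = spca(basis_net.V_k, basis_run.V_k)
    observed = {"pvr": pvr, "s_pca": s_pca_val, "eros": eros_val}

    # block-structured concatenated NE matrix for shuffles 2 and 3
    blocks = np.stack([X[:, f - half : f + half + 1] for f in full])  # (n_ne, cells, w)
    rest = epochs.frames("rest")
    rest_series = X[:, rest]
    # positions of NE-window frames within the rest-concatenated series
    pos_in_rest = np.full(n_frames, -1)
    pos_in_rest[rest] = np.arange(rest.size)

    ss = np.random.SeedSequence(seed)
    rngs = dict(zip(methods, [np.random.default_rng(s) for s in ss.spawn(len(methods))]))
    min_shift = max(int(min_shift_s * frame_rate), 1)

    null: dict[str, dict[str, np.ndarray]] = {}
    p_values: dict[str, dict[str, float]] = {}
    n_cells = X.shape[0]
    for m in methods:
        rng = rngs[m]
        vals = {k: np.empty(n_shuffles) for k in observed}
        for j in range(n_shuffles):
            if m == "time_shift":
                shifts = rng.integers(min_shift, rest.size - min_shift, size=n_cells)
                shifted = np.empty_like(rest_series)
                for c in range(n_cells):
                    shifted[c] = np.roll(rest_series[c], shifts[c])
                segs = []
                for f in full:
                    p0 = pos_in_rest[f - half : f + half + 1]
                    ok = p0 >= 0
                    if ok.all():
                        segs.append(shifted[:, p0])
                Xn = np.concatenate(segs, axis=1) if segs else shifted[:, :win_len]
            elif m == "within_ne_identity":
                shuf = np.empty_like(blocks)
                for i in range(blocks.shape[0]):
                    shuf[i] = blocks[i][rng.permutation(n_cells)]
                Xn = np.concatenate(list(shuf), axis=1)
            else:  # per_cell_ne_reassign
                shuf = blocks.copy()
                for c in range(n_cells):
                    shuf[rng.permutation(blocks.shape[0]), c, :] = blocks[:, c, :]
                Xn = np.concatenate(list(shuf), axis=1)
            basis_rand = pca_basis(Xn, var_frac)
            vals["pvr"][j], vals["s_pca"][j], vals["eros"][j] = _similarity_measures(
                X_run, basis_run, basis_rand, C_run
            )
        null[m] = vals
        p_values[m] = {
            k: float((np.count_nonzero(vals[k] >= observed[k]) + 1) / (n_shuffles + 1))
            for k in observed
        }

    return SimilarityResult(
        projected_variance_ratio=pvr,
        s_pca=s_pca_val,
        eros=eros_val,
        principal_angles=angles,
        k_run=basis_run.k,
        k_net=basis_net.k,
        null=null,
        p_values=p_values,
    )


def weight_lap_autocorr(
    W: np.ndarray,
    laps: LapIndex,
    belt_length: float,
    n_components: int = 5,
    pos_bins: int = 150,
    min_coverage: float = 0.8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lap-periodicity of PCA weights.

    Each of the first ``n_components`` weight series is resampled onto a
    uniform position grid per complete lap (laps covering at least
    ``min_coverage`` of the position bins), the laps are concatenated, and
    the normalized autocorrelation is evaluated; the peak near a lag of one
    lap (``pos_bins`` samples, +/-10%) quantifies spatial periodicity.

    Returns ``(lag_laps, autocorr_per_component, mean_peak_at_lap1)``.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[1] != laps.lap.size:
        raise ValueError("W columns must align with the lap index frames")
    n_components = min(n_components, W.shape[0])
    bin_idx = np.clip(
        (laps.within_lap_cm / belt_length * pos_bins).astype(int), 0, pos_bins - 1
    )
    complete = []
    for l in range(laps.n_laps):
        sel = laps.lap == l
        if np.unique(bin_idx[sel]).size >= min_coverage * pos_bins:
            complete.append(l)
    if len(complete) < 3:
        raise ValueError("need at least three complete laps")
    centers = np.arange(pos_bins)
    acs = []
    for ci in range(n_components):
        series = []
        for l in complete:
            sel = laps.lap == l
            b = bin_idx[sel]
            w = W[ci, sel]
            sums = np.bincount(b, weights=w, minlength=pos_bins)
            cnts = np.bincount(b, minlength=pos_bins)
            prof = np.full(pos_bins, np.nan)
            prof[cnts > 0] = sums[cnts > 0] / cnts[cnts > 0]
            missing = np.isnan(prof)
            if missing.any():
                prof[missing] = np.interp(
                    centers[missing], centers[~missing], prof[~missing]
                )
            series.append(prof)
        a = np.concatenate(series)
        a = a - a.mean()
        var = float(a @ a) / len(a)
        if var == 0:
            acs.append(np.zeros(len(a)))
            continue
        raw = np.correlate(a, a, mode="full")[len(a) - 1 :]
        overlap = len(a) - np.arange(len(a))  # unbiased: divide by overlap length
        acs.append(raw / overlap / var)
    acs = np.array([a[: min(map(len, acs))] for a in acs])
    lag_laps = np.arange(acs.shape[1]) / pos_bins
    lo = int(0.9 * pos_bins)
    hi = min(int(1.1 * pos_bins) + 1, acs.shape[1])
    peak = float(np.mean([a[lo:hi].max() for a in acs])) if hi > lo else np.nan
    return lag_laps, acs, peak
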