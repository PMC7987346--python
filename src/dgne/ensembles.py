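"""NE orthogonality and correlated sub-ensemble discovery.

Each network event is summarized as a binary participation vector over cells.
Orthogonality is quantified by the pairwise cosine similarity of these vectors
(1 = identical membership, 0 = disjoint), with the fraction of exactly
orthogonal pairs tested against a permutation null that preserves per-NE
sizes.  Sub-ensembles are found by agglomerative hierarchical clustering of
the cells' participation profiles (standardized Euclidean distance, weighted
average linkage), with merging gated by a permutation-derived threshold on the
mean within-cluster Pearson r (95th percentile of the shuffled-r null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .network_events import NetworkEventSet

__all__ = [
    "ParticipationMatrix",
    "ClusterAssignment",
    "participation_matrix",
    "cosine_similarity_pairs",
    "orthogonal_fraction_test",
    "cluster_threshold_null",
    "hierarchical_clusters",
    "cluster_tuning_overlap",
]


@dataclass
class ParticipationMatrix:
    """Binary cells x NEs matrix; P[c, e] = 1 iff cell c participated in NE e."""

    P: np.ndarray
    cell_ids: np.ndarray
    ne_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.P.shape[0]

    @property
    def n_nes(self) -> int:
        return self.P.shape[1]


@dataclass
class ClusterAssignment:
    """Cell -> cluster labels (-1 = unclustered) plus the permutation threshold."""

    labels: np.ndarray                # over the cells of the source matrix
    cluster_mean_r: np.ndarray        # mean intra-cluster Pearson r per cluster
    r_threshold: float
    linkage_tree: np.ndarray | None = None
    included_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_mean_r.size)

    def members(self, k: int) -> set[int]:
        return set(np.flatnonzero(self.labels == k).tolist())

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(self.members(k)) for k in range(self.n_clusters)], dtype=int)


def participation_matrix(ne_set: NetworkEventSet, n_cells: int) -> ParticipationMatrix:
    """Build the binary participation matrix from a detected NE set."""
    P = np.zeros((n_cells, len(ne_set)), dtype=np.int8)
    for e, members in enumerate(ne_set.ne_members):
        P[sorted(members), e] = 1
    return ParticipationMatrix(
        P=P, cell_ids=np.arange(n_cells), ne_ids=np.arange(len(ne_set))
    )


def cosine_similarity_pairs(P: np.ndarray) -> np.ndarray:
    """Condensed pairwise cosine similarity between NE participation vectors.

    For binary vectors the similarity lies in [0, 1]; zero columns are
    excluded with a warning (they cannot arise from a valid NE set).
    """
    P = np.asarray(P, dtype=float)
    if P.shape[1] < 2:
        raise ValueError("need at least two NEs for pairwise similarity")
    norms = np.linalg.norm(P, axis=0)
    if (norms == 0).any():
        warnings.warn("zero participation column(s) excluded from similarity")
        P = P[:, norms > 0]
        if P.shape[1] < 2:
            raise ValueError("fewer than two nonzero NE vectors")
    sim = 1.0 - pdist(P.T, metric="cosine")
    return np.clip(sim, 0.0, 1.0)


def orthogonal_fraction_test(
    P: np.ndarray, n_shuffles: int = 1000, seed=None
) -> tuple[float, np.ndarray, float]:
    """Fraction of exactly orthogonal (disjoint) NE pairs vs a size-preserving null.

    The null redraws each NE's participants uniformly without replacement,
    keeping every NE's size; p is the one-sided fraction of null fractions at
    least as large as the observed one (greater orthogonality by chance).
    """
    P = np.asarray(P)
    n_cells, n_nes = P.shape
    observed = float(np.mean(cosine_similarity_pairs(P) == 0.0))
    rng = np.random.default_rng(seed)
    sizes = P.sum(axis=0).astype(int)
    null = np.empty(n_shuffles)
    for j in range(n_shuffles):
        Q = np.zeros_like(P)
        for e, k in enumerate(sizes):
            Q[rng.permutation(n_cells)[:k], e] = 1
        null[j] = np.mean(cosine_similarity_pairs(Q) == 0.0)
    p = float((np.count_nonzero(null >= observed) + 1) / (n_shuffles + 1))
    return observed, null, p


def _row_permuted(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each cell's participations across NEs (conserves row sums)."""
    Q = np.empty_like(P)
    n = P.shape[1]
    for c in range(P.shape[0]):
        Q[c] = P[c, rng.permutation(n)]
    return Q


def _pairwise_r(P: np.ndarray) -> np.ndarray:
    """Pearson r matrix over rows; constant rows yield NaN rows/columns."""
    P = np.asarray(P, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(P)
    return np.atleast_2d(R)


def cluster_threshold_null(
    P: np.ndarray, n_shuffles: int = 1000, seed=None
) -> float:
    """95th percentile of the pooled pairwise-r null under row-wise permutation.

    Each shuffle reassigns every cell's NE-related events to uniformly chosen
    NEs (independent permutation of each row of P); all off-diagonal pairwise
    Pearson r values are pooled over shuffles and the 95th percentile returned.
    """
    P = np.asarray(P)
    if P.shape[1] < 2:
        raise ValueError("need at least two NEs to build an r null")
    keep = P.std(axis=1) > 0
    if np.count_nonzero(keep) < 2:
        raise ValueError("need at least two cells with non-constant participation")
    P = P[keep]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(P.shape[0], k=1)
    pool = np.empty((n_shuffles, iu[0].size))
    for j in range(n_shuffles):
        R = _pairwise_r(_row_permuted(P, rng))
        pool[j] = R[iu]
    vals = pool[np.isfinite(pool)]
    return float(np.percentile(vals, 95))


def _mean_intra_r(R: np.ndarray, members: np.ndarray) -> float:
    sub = R[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def hierarchical_clusters(
    P: np.ndarray,
    r_threshold: float,
    merge_stop_rule: str = "cluster",
) -> ClusterAssignment:
    """Threshold-gated agglomerative clustering of cell participation profiles.

    A linkage tree (standardized Euclidean distance, weighted average linkage)
    is built over the cells' participation row-vectors; cells with no NE
    participation (or constant rows) are excluded first.  Merges are applied
    in tree order.  Under the default ``merge_stop_rule="cluster"`` a merge is
    refused when the merged cluster's own mean intra-r would fall below the
    threshold (refused branches freeze); under ``"global"`` agglomeration
    halts entirely when the pooled mean within-cluster r of all multi-member
    clusters would drop below the threshold.  Only clusters whose mean
    intra-r exceeds the threshold are reported.  Identical non-constant rows
    count as perfectly correlated (r = 1).
    """
    if merge_stop_rule not in ("cluster", "global"):
        raise ValueError("merge_stop_rule must be 'cluster' or 'global'")
    P = np.asarray(P, dtype=float)
    n_all = P.shape[0]
    included = np.flatnonzero(P.std(axis=1) > 0)
    labels = np.full(n_all, -1, dtype=int)
    if included.size < 3:
        return ClusterAssignment(
            labels=labels,
            cluster_mean_r=np.array([]),
            r_threshold=r_threshold,
            included_cells=included,
        )
    X = P[included]
    R = _pairwise_r(X)
    # identical rows -> r exactly 1 even with float noise
    np.fill_diagonal(R, 1.0)

    feat = X[:, X.std(axis=0) > 0]  # constant NE columns carry no distance info
    if feat.shape[1] == 0:
        feat = X
    uniq = np.unique(feat, axis=0)
    if uniq.shape[0] == 1:
        # all profiles identical: one cluster of everything
        labels[included] = 0
        return ClusterAssignment(
            labels=labels,
            cluster_mean_r=np.array([1.0]),
            r_threshold=r_threshold,
            included_cells=included,
        )
    d = pdist(feat, metric="seuclidean")
    d[~np.isfinite(d)] = 0.0
    Z = linkage(d, method="weighted")

    m = included.size
    members: dict[int, np.ndarray] = {i: np.array([i]) for i in range(m)}
    frozen: set[int] = set()
    active: set[int] = set(range(m))

    def global_mean(extra_sets: list[np.ndarray]) -> float:
        vals: list[float] = []
        for s in extra_sets:
            if len(s) > 1:
                sub = R[np.ix_(s, s)]
                iu = np.triu_indices(len(s), k=1)
                vals.extend(sub[iu][np.isfinite(sub[iu])].tolist())
        return float(np.mean(vals)) if vals else np.inf

    for step, (a, b, _, _) in enumerate(Z):
        a, b = int(a), int(b)
        new = m + step
        if a in frozen or b in frozen:
            frozen.add(new)
            continue
        merged = np.concatenate([members[a], members[b]])
        mean_r = _mean_intra_r(R, merged)
        if merge_stop_rule == "cluster":
            if not np.isfinite(mean_r) or mean_r < r_threshold:
                frozen.add(new)
                continue
        else:
            trial = [members[i] for i in active if i not in (a, b)] + [merged]
            if global_mean(trial) < r_threshold:
                break
        members[new] = merged
        active.discard(a)
        active.discard(b)
        active.add(new)

    final: list[tuple[np.ndarray, float]] = []
    for i in active:
        s = members[i]
        if len(s) < 2:
            continue
        mr = _mean_intra_r(R, s)
        if np.isfinite(mr) and mr > r_threshold:
            final.append((s, mr))
    final.sort(key=lambda t: -len(t[0]))
    mean_rs = []
    for k, (s, mr) in enumerate(final):
        labels[included[s]] = k
        mean_rs.append(mr)
    return ClusterAssignment(
        labels=labels,
        cluster_mean_r=np.asarray(mean_rs),
        r_threshold=r_threshold,
        linkage_tree=Z,
        included_cells=included,
    )


def cluster_tuning_overlap(
    clusters: ClusterAssignment,
    place_ids: set[int] | np.ndarray,
    speed_ids: set[int] | np.ndarray,
) -> dict[str, float]:
    """Fractions of clusters containing place cells, speed cells or both,
    and the mean count of each per cluster."""
    place = set(int(i) for i in place_ids)
    speed = set(int(i) for i in speed_ids)
    k = clusters.n_clusters
    if k == 0:
        return {
            "frac_with_place": np.nan,
            "frac_with_speed": np.nan,
            "frac_with_both": np.nan,
            "mean_place_per_cluster": np.nan,
            "mean_speed_per_cluster": np.nan,
            "n_clusters": 0,
        }
    with_p = with_s = with_b = 0
    n_p = n_s = 0
    for i in range(k):
        mem = clusters.members(i)
        p = len(mem & place)
        s = len(mem & speed)
        n_p += p
        n_s += s
        with_p += p > 0
        with_s += s > 0
        with_b += p > 0 and s > 0
    return {
        "frac_with_place": with_p / k,
        "frac_with_speed": with_s / k,
        "frac_with_both": with_b / k,
        "mean_place_per_cluster": n_p / k,
        "mean_speed_per_cluster": n_s / k,
        "n_clusters": k,
    }
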