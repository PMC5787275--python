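"""Temporal expression profiles by fuzzy c-means soft clustering.

Pipeline: variance-filter the stage matrix (sample variance strictly above a
threshold), standardize each gene trajectory to mean 0 / sd 1 so clustering
sees shape rather than magnitude, soft-cluster into k initial profiles with
fuzzy c-means, hard-assign each gene to its maximum-membership profile, and
merge highly correlated profiles (Pearson r of centroids above a threshold)
into composite clusters labelled with ids above 200. Components whose high
correlations are not fully reciprocal are split by average-linkage
hierarchical clustering on 1 - r, cut at 1 - r_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data

from .expression_io import StageExpressionMatrix, logger

#: Composite cluster ids start here; initial profiles are 1..k.
COMPOSITE_ID_BASE = 200


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def filter_by_variance(matrix: StageExpressionMatrix, threshold: float = 5.0) -> StageExpressionMatrix:
    """Keep genes whose sample variance (ddof=1) across stages is strictly > threshold."""
    var = matrix.data.var(axis=1, ddof=1)
    kept = matrix.data.loc[var > threshold]
    if kept.empty:
        logger.warning("variance filter at %g removed every gene", threshold)
    return StageExpressionMatrix(kept)


def standardize(matrix: StageExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score: each row to mean 0 and sample (ddof=1) sd 1.

    Returns a plain DataFrame because standardized trajectories are signed and
    no longer carry FPKM semantics.
    """
    df = matrix.data if isinstance(matrix, StageExpressionMatrix) else matrix
    sd = df.std(axis=1, ddof=1)
    zero = sd[sd == 0]
    if not zero.empty:
        raise ValueError(f"zero-variance row cannot be standardized: gene {zero.index[0]!r}")
    return df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)


# ---------------------------------------------------------------------------
# fuzzy c-means estimator
# ---------------------------------------------------------------------------


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means soft clustering (Bezdek alternating optimization).

    Memberships ``u[g, i] = 1 / sum_j (d[g, i] / d[g, j])**(2 / (m - 1))``
    with Euclidean distances d to the centroids; centroids are the
    u**m-weighted means of the rows. Iteration stops when the largest
    centroid coordinate change falls below `tol` or after `max_iter` rounds.
    Centroids are initialized by sampling `n_clusters` distinct rows.

    Parameters
    ----------
    n_clusters : int, default=150
        Number of profiles.
    m : float, default=1.25
        Fuzzifier (> 1); m -> 1 approaches hard k-means.
    tol : float, default=1e-6
        Convergence threshold on the max absolute centroid change.
    max_iter : int, default=1000
    random_state : int, RandomState instance or None

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    membership_ : ndarray of shape (n_samples, n_clusters)
        Row-normalized soft memberships (each row sums to 1).
    labels_ : ndarray of shape (n_samples,)
        argmax membership; ties go to the lowest cluster index.
    n_iter_ : int
    objective_path_ : list of float
        The objective J_m = sum u**m d^2 after each iteration (non-increasing).
    """

    def __init__(self, n_clusters: int = 150, m: float = 1.25, tol: float = 1e-6,
                 max_iter: int = 1000, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _init_centers(self, X: np.ndarray, rng) -> np.ndarray:
        """Sample n_clusters distinct rows as initial centroids, k-means++ style.

        The first row is uniform; each further row is drawn with probability
        proportional to its squared distance to the nearest chosen centroid,
        so duplicated trajectories (e.g. noise-free archetypes) cannot seed
        two coincident centroids while distinct shapes exist.
        """
        n = X.shape[0]
        chosen = [int(rng.randint(n))]
        d2 = ((X - X[chosen[0]]) ** 2).sum(axis=1)
        for _ in range(1, self.n_clusters):
            weights = d2.copy()
            weights[chosen] = 0.0
            total = weights.sum()
            if total > 0:
                idx = int(rng.choice(n, p=weights / total))
            else:  # all remaining rows coincide with a centroid
                idx = int(rng.choice([i for i in range(n) if i not in chosen]))
            chosen.append(idx)
            d2 = np.minimum(d2, ((X - X[idx]) ** 2).sum(axis=1))
        return X[chosen].copy()

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        d = cdist(X, centers)
        u = np.zeros_like(d)
        on_center = d <= 1e-12
        coincident = on_center.any(axis=1)
        if coincident.any():
            rows = on_center[coincident]
            u[coincident] = rows / rows.sum(axis=1, keepdims=True)
        free = ~coincident
        if free.any():
            w = d[free] ** (-2.0 / (self.m - 1.0))
            u[free] = w / w.sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=2)
        if self.m <= 1.0:
            raise ValueError(f"fuzzifier m must be > 1, got {self.m}")
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the number of rows {X.shape[0]}"
            )
        rng = check_random_state(self.random_state)
        centers = self._init_centers(X, rng)

        self.objective_path_ = []
        for iteration in range(1, self.max_iter + 1):
            u = self._memberships(X, centers)
            um = u ** self.m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            self.objective_path_.append(
                float((u ** self.m * cdist(X, centers) ** 2).sum())
            )
            if shift < self.tol:
                break
        self.cluster_centers_ = centers
        self.membership_ = self._memberships(X, centers)
        self.labels_ = self.membership_.argmax(axis=1)
        self.n_iter_ = iteration
        return self

    def predict_membership(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self._memberships(X, self.cluster_centers_)

    def predict(self, X) -> np.ndarray:
        return self.predict_membership(X).argmax(axis=1)


# ---------------------------------------------------------------------------
# profile set container and merging
# ---------------------------------------------------------------------------


@dataclass
class ProfileSet:
    """Soft-cluster profiles over stages, with optional composite merges.

    ``centroids`` is indexed by profile id (1..k for initial profiles, > 200
    for composites); ``memberships`` is genes x profile ids; ``assignment``
    maps each gene to its argmax-membership profile; ``merged_from`` maps each
    composite id to the set of initial ids it absorbed.
    """

    centroids: pd.DataFrame
    memberships: pd.DataFrame
    assignment: pd.Series
    k: int
    m: float
    merged_from: dict[int, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        sums = self.memberships.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")

    @property
    def profile_ids(self) -> list[int]:
        return list(self.centroids.index)

    def genes_in(self, profile_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == profile_id])

    def counts(self) -> pd.Series:
        """Number of hard-assigned genes per profile (empty profiles included)."""
        return self.assignment.value_counts().reindex(self.centroids.index, fill_value=0)


def fuzzy_cmeans(
    standardized: pd.DataFrame,
    k: int = 150,
    m: float = 1.25,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ProfileSet:
    """Cluster standardized trajectories into k profiles (ids 1..k)."""
    est = FuzzyCMeans(n_clusters=k, m=m, tol=tol, max_iter=max_iter, random_state=seed)
    est.fit(standardized.to_numpy())
    ids = list(range(1, k + 1))
    centroids = pd.DataFrame(est.cluster_centers_, index=ids, columns=standardized.columns)
    memberships = pd.DataFrame(est.membership_, index=standardized.index, columns=ids)
    # argmax with ties to the lowest id (np.argmax already takes the first max)
    assignment = pd.Series(
        np.asarray(ids)[est.labels_], index=standardized.index, name="profile_id"
    )
    logger.info("fuzzy c-means: k=%d, m=%g, %d iterations", k, m, est.n_iter_)
    return ProfileSet(centroids=centroids, memberships=memberships, assignment=assignment, k=k, m=m)


def _restandardize(vec: np.ndarray) -> np.ndarray:
    sd = vec.std(ddof=1)
    return (vec - vec.mean()) / sd if sd > 0 else vec - vec.mean()


def _average_linkage_groups(dist: np.ndarray, cut: float) -> list[list[int]]:
    """Agglomerative average-linkage (UPGMA) grouping cut at height `cut`.

    Returns index groups over ``dist``'s rows. Cluster-pair distance is the
    mean of the original pairwise distances between members; equal-distance
    merges are broken in favour of the pair containing the lowest index, then
    the lowest partner. Merging stops once the closest pair exceeds `cut`.
    """
    tol = 1e-9  # distances this close count as tied
    clusters: list[list[int]] = [[i] for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best_key: tuple[float, int, int] | None = None
        best_pair: tuple[int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist[np.ix_(clusters[i], clusters[j])].mean()
                key = (d, clusters[i][0], clusters[j][0])
                if (
                    best_key is None
                    or d < best_key[0] - tol
                    or (abs(d - best_key[0]) <= tol and key[1:] < best_key[1:])
                ):
                    best_key, best_pair = key, (i, j)
        if best_key[0] > cut:
            break
        i, j = best_pair
        merged = sorted(clusters[i] + clusters[j])
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return clusters


def merge_profiles(
    profiles: ProfileSet,
    r_threshold: float = 0.95,
    dendrogram_cut: float | None = None,
) -> ProfileSet:
    """Merge correlated profiles into composite clusters (ids 201, 202, ...).

    Profiles whose centroid Pearson r exceeds `r_threshold` are linked; each
    connected component merges wholesale when all its pairwise correlations
    clear the threshold (a clique), otherwise it is split by average-linkage
    hierarchical clustering on distance 1 - r, cut at `dendrogram_cut`
    (default 1 - r_threshold). Composite centroids are gene-count-weighted
    means of member centroids, re-standardized; composite ids are numbered in
    order of the smallest member id.
    """
    if dendrogram_cut is None:
        dendrogram_cut = 1.0 - r_threshold
    ids = profiles.profile_ids
    if len(ids) < 2:
        return profiles
    C = profiles.centroids.to_numpy()
    r = np.corrcoef(C)

    graph = nx.Graph()
    graph.add_nodes_from(range(len(ids)))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if r[i, j] > r_threshold:
                graph.add_edge(i, j)

    groups: list[list[int]] = []  # index groups of size >= 2 to merge
    for component in nx.connected_components(graph):
        members = sorted(component)
        if len(members) < 2:
            continue
        sub = r[np.ix_(members, members)]
        if (sub[np.triu_indices(len(members), k=1)] > r_threshold).all():
            groups.append(members)  # fully reciprocal: merge the clique wholesale
        else:
            dist = np.clip(1.0 - sub, 0.0, None)
            np.fill_diagonal(dist, 0.0)
            for sub_group in _average_linkage_groups(dist, dendrogram_cut):
                if len(sub_group) >= 2:
                    groups.append([members[i] for i in sub_group])

    if not groups:
        return ProfileSet(
            centroids=profiles.centroids.copy(),
            memberships=profiles.memberships.copy(),
            assignment=profiles.assignment.copy(),
            k=profiles.k,
            m=profiles.m,
            merged_from={},
        )

    groups.sort(key=lambda g: ids[g[0]])
    counts = profiles.counts()
    merged_from: dict[int, frozenset[int]] = {}
    new_centroids: dict[int, np.ndarray] = {}
    id_remap: dict[int, int] = {}
    for offset, group in enumerate(groups, start=1):
        composite_id = COMPOSITE_ID_BASE + offset
        member_ids = [ids[i] for i in group]
        merged_from[composite_id] = frozenset(member_ids)
        weights = counts.loc[member_ids].to_numpy(dtype=float)
        if weights.sum() == 0:
            weights = np.ones(len(member_ids))
        new_centroids[composite_id] = _restandardize(
            np.average(C[group], axis=0, weights=weights)
        )
        for pid in member_ids:
            id_remap[pid] = composite_id

    surviving = [pid for pid in ids if pid not in id_remap]
    out_ids = surviving + sorted(new_centroids)
    centroids = pd.DataFrame(
        np.vstack(
            [profiles.centroids.loc[surviving].to_numpy()]
            + ([np.vstack([new_centroids[c] for c in sorted(new_centroids)])] if new_centroids else [])
        )
        if surviving
        else np.vstack([new_centroids[c] for c in sorted(new_centroids)]),
        index=out_ids,
        columns=profiles.centroids.columns,
    )

    memberships = profiles.memberships.T.groupby(
        lambda pid: id_remap.get(pid, pid)
    ).sum().T.reindex(columns=out_ids)
    assignment = profiles.assignment.map(lambda pid: id_remap.get(pid, pid))
    logger.info("merged %d profiles into %d composite clusters", len(id_remap), len(groups))
    return ProfileSet(
        centroids=centroids,
        memberships=memberships,
        assignment=assignment,
        k=profiles.k,
        m=profiles.m,
        merged_from=merged_from,
    )


def assign_to_profiles(rows: pd.DataFrame, profiles: ProfileSet) -> pd.Series:
    """Nearest-centroid (Euclidean) assignment of standardized rows; ties -> lowest id."""
    if rows.shape[1] != profiles.centroids.shape[1]:
        raise ValueError(
            f"row length {rows.shape[1]} != centroid length {profiles.centroids.shape[1]}"
        )
    order = sorted(profiles.profile_ids)
    d = cdist(rows.to_numpy(), profiles.centroids.loc[order].to_numpy())
    return pd.Series(np.asarray(order)[d.argmin(axis=1)], index=rows.index, name="profile_id")


def build_profiles(
    matrix: StageExpressionMatrix,
    variance_threshold: float = 5.0,
    k: int = 150,
    m: float = 1.25,
    r_threshold: float = 0.95,
    seed: int | None = None,
) -> ProfileSet:
    """Full profile construction: variance filter, standardize, cluster, merge."""
    filtered = filter_by_variance(matrix, variance_threshold)
    return merge_profiles(
        fuzzy_cmeans(standardize(filtered), k=k, m=m, seed=seed), r_threshold=r_threshold
    )
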