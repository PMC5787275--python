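import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from etch.expression_io import STAGES, StageExpressionMatrix
from etch.synthetic_data import ArchetypeSpec, generate_stage_matrix
from etch.temporal_profiles import (
    FuzzyCMeans,
    ProfileSet,
    assign_to_profiles,
    build_profiles,
    filter_by_variance,
    fuzzy_cmeans,
    merge_profiles,
    standardize,
)


def _matrix(rows, genes=None, stages=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    stages = stages or list(STAGES)[: rows.shape[1]]
    return StageExpressionMatrix(pd.DataFrame(rows, index=genes, columns=stages))


def _profile_set(centroids, ids, genes_per_profile=1):
    """ProfileSet with hard memberships and `genes_per_profile` genes per centroid."""
    centroids = np.asarray(centroids, float)
    gene_ids, assignment_vals = [], []
    for pid in ids:
        for j in range(genes_per_profile):
            gene_ids.append(f"p{pid}_g{j}")
            assignment_vals.append(pid)
    memberships = pd.DataFrame(0.0, index=gene_ids, columns=list(ids))
    for g, pid in zip(gene_ids, assignment_vals):
        memberships.at[g, pid] = 1.0
    return ProfileSet(
        centroids=pd.DataFrame(centroids, index=list(ids), columns=list(STAGES)),
        memberships=memberships,
        assignment=pd.Series(assignment_vals, index=gene_ids),
        k=len(ids),
        m=1.25,
    )


def correlated_vectors(R, dim=7, seed=0):
    """Mean-zero vectors whose sample correlation matrix equals R (via Cholesky)."""
    R = np.asarray(R, float)
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(dim, R.shape[0]))
    raw -= raw.mean(axis=0)
    basis, _ = np.linalg.qr(raw)  # orthonormal, mean-zero columns
    return np.linalg.cholesky(R) @ basis.T


class TestVarianceFilter:
    def test_constant_gene_removed(self):
        m = _matrix([[3] * 7, [0, 0, 0, 0, 0, 0, 100]])
        kept = filter_by_variance(m)
        assert kept.genes == ["g1"]

    def test_high_variance_gene_kept(self):
        m = _matrix([[0, 0, 0, 0, 0, 0, 100]])
        # sample variance = (6*(100/7)^2 + (600/7)^2) / 6 ~ 1428.6 > 5
        assert filter_by_variance(m).genes == ["g0"]

    def test_boundary_variance_exactly_threshold_removed(self):
        # [7,1,1,1,1,1,2]: mean 2, squared deviations sum to 30, var = 30/6 = 5
        row = [7, 1, 1, 1, 1, 1, 2]
        assert np.var(row, ddof=1) == 5.0
        assert len(filter_by_variance(_matrix([row]))) == 0

    def test_empty_result_warns(self, caplog):
        with caplog.at_level("WARNING", logger="etch"):
            filter_by_variance(_matrix([[1] * 7]))
        assert "removed every gene" in caplog.text


class TestStandardize:
    def test_three_stage_row(self):
        z = standardize(_matrix([[1, 2, 3]]))
        assert np.allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_rows_have_zero_mean_unit_sd(self, noisy_matrix):
        matrix, _ = noisy_matrix
        z = standardize(filter_by_variance(matrix))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_rejected_by_name(self):
        with pytest.raises(ValueError, match="g1"):
            standardize(_matrix([[1, 2, 3, 4, 5, 6, 7], [2] * 7], genes=["g0", "g1"]))


class TestFuzzyCMeans:
    def test_k1_gives_unit_membership_and_mean_centroid(self):
        X = np.random.default_rng(0).normal(size=(20, 7))
        est = FuzzyCMeans(n_clusters=1, random_state=0).fit(X)
        assert np.allclose(est.membership_, 1.0)
        assert np.allclose(est.cluster_centers_[0], X.mean(axis=0), atol=1e-6)

    def test_two_noiseless_archetypes_recovered(self, noiseless_two_archetype_matrix):
        matrix, truth = noiseless_two_archetype_matrix
        z = standardize(filter_by_variance(matrix))
        ps = fuzzy_cmeans(z, k=2, m=1.25, seed=5)
        # each centroid equals one standardized archetype trajectory
        shapes = {
            name: standardize(_matrix([shape])).to_numpy()[0]
            for name, shape in [("decay", (8, 4, 2, 1, 0.5, 0.2, 0.1)),
                                ("pulse8c", (0.5, 0.5, 1, 2, 10, 2, 1))]
        }
        for name, target in shapes.items():
            err = np.abs(ps.centroids.to_numpy() - target).max(axis=1).min()
            assert err < 1e-6, name
        # own-cluster memberships are essentially hard
        assert ps.memberships.max(axis=1).min() > 0.99
        # hard assignment matches the planted archetypes
        grouping = ps.assignment.groupby(pd.Series(truth.gene_to_archetype)).nunique()
        assert (grouping == 1).all()

    def test_membership_rows_sum_to_one(self, noisy_matrix):
        matrix, _ = noisy_matrix
        z = standardize(filter_by_variance(matrix))
        est = FuzzyCMeans(n_clusters=8, random_state=1).fit(z.to_numpy())
        assert np.allclose(est.membership_.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_non_increasing(self):
        X = np.random.default_rng(2).normal(size=(120, 7))
        est = FuzzyCMeans(n_clusters=6, random_state=2, tol=0.0, max_iter=40).fit(X)
        assert (np.diff(est.objective_path_) <= 1e-8).all()

    def test_seed_determinism(self):
        X = np.random.default_rng(3).normal(size=(60, 7))
        a = FuzzyCMeans(n_clusters=4, random_state=7).fit(X)
        b = FuzzyCMeans(n_clusters=4, random_state=7).fit(X)
        assert np.array_equal(a.cluster_centers_, b.cluster_centers_)
        assert np.array_equal(a.labels_, b.labels_)

    def test_parameter_recovery_six_archetypes(self):
        """Zero-noise data with k_true <= 6 shapes: centroids match archetypes."""
        matrix, _ = generate_stage_matrix(noise_log_sd=0.0, seed=13)
        z = standardize(filter_by_variance(matrix))
        ps = fuzzy_cmeans(z, k=6, m=1.25, seed=13)
        targets = np.unique(np.round(z.to_numpy(), 9), axis=0)
        r = np.corrcoef(np.vstack([ps.centroids.to_numpy(), targets]))[:6, 6:]
        assert (r.max(axis=1) > 0.999).all()

    def test_invalid_inputs_rejected(self):
        X = np.zeros((5, 7))
        with pytest.raises(ValueError, match="n_clusters"):
            FuzzyCMeans(n_clusters=6).fit(X)
        with pytest.raises(ValueError, match="fuzzifier"):
            FuzzyCMeans(n_clusters=2, m=1.0).fit(np.random.default_rng(0).normal(size=(5, 7)))

    def test_sklearn_clone_compatible(self):
        est = FuzzyCMeans(n_clusters=3, m=1.5, random_state=0)
        params = clone(est).get_params()
        assert params["n_clusters"] == 3 and params["m"] == 1.5


class TestMergeProfiles:
    def test_identical_centroids_merge_to_201(self):
        v = correlated_vectors(np.eye(1), seed=1)[0]
        ps = _profile_set([v, v], ids=[1, 2])
        merged = merge_profiles(ps)
        assert merged.merged_from == {201: frozenset({1, 2})}
        assert list(merged.centroids.index) == [201]
        assert set(merged.assignment.unique()) == {201}

    def test_uncorrelated_profiles_unchanged(self):
        vectors = correlated_vectors(np.eye(3) * 0.9 + 0.1, seed=2)
        ps = _profile_set(vectors, ids=[1, 2, 3])
        merged = merge_profiles(ps)
        assert merged.merged_from == {}
        assert list(merged.centroids.index) == [1, 2, 3]

    def test_chain_resolved_by_average_linkage(self):
        # r(A,B)=r(B,C)=0.96 but r(A,C)=0.90: not a clique. Average linkage on
        # 1-r merges {A,B} at 0.04; d({A,B},C) = (0.04+0.10)/2 = 0.07 > 0.05
        # cut, so C stays single.
        R = np.array([[1.0, 0.96, 0.90], [0.96, 1.0, 0.96], [0.90, 0.96, 1.0]])
        vectors = correlated_vectors(R, seed=3)
        ps = _profile_set(vectors, ids=[1, 2, 3])
        merged = merge_profiles(ps, r_threshold=0.95)
        assert merged.merged_from == {201: frozenset({1, 2})}
        assert set(merged.centroids.index) == {3, 201}

    def test_clique_merge_invariant_to_input_order(self):
        R = np.full((3, 3), 0.97)
        np.fill_diagonal(R, 1.0)
        vectors = correlated_vectors(R, seed=4)
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            ps = _profile_set(vectors[order], ids=[1, 2, 3])
            merged = merge_profiles(ps)
            assert merged.merged_from == {201: frozenset({1, 2, 3})}

    def test_no_surviving_pair_correlates_above_threshold(self):
        matrix, _ = generate_stage_matrix(noise_log_sd=0.3, seed=21)
        ps = fuzzy_cmeans(standardize(filter_by_variance(matrix)), k=12, m=1.25, seed=21)
        merged = merge_profiles(ps, r_threshold=0.95)
        # clique components were collapsed: survivors of each merged clique
        # are the composites themselves
        r = np.corrcoef(merged.centroids.to_numpy())
        originals = [i for i, pid in enumerate(merged.centroids.index) if pid <= ps.k]
        sub = r[np.ix_(originals, originals)]
        assert (sub[np.triu_indices(len(originals), k=1)] <= 0.95 + 1e-12).all()

    def test_memberships_regrouped_and_normalized(self):
        v = correlated_vectors(np.eye(1), seed=5)[0]
        ps = _profile_set([v, v, -v], ids=[1, 2, 3], genes_per_profile=4)
        merged = merge_profiles(ps)
        assert np.allclose(merged.memberships.sum(axis=1), 1.0)
        assert merged.counts()[201] == 8


class TestAssignToProfiles:
    def test_centroid_maps_to_its_profile(self):
        vectors = correlated_vectors(np.eye(2), seed=6)
        ps = _profile_set(vectors, ids=[1, 2])
        rows = pd.DataFrame(vectors, index=["a", "b"], columns=list(STAGES))
        assert assign_to_profiles(rows, ps).tolist() == [1, 2]

    def test_equidistant_tie_goes_to_lowest_id(self):
        vectors = correlated_vectors(np.eye(2), seed=7)
        ps = _profile_set(vectors, ids=[1, 2])
        midpoint = vectors.mean(axis=0)
        rows = pd.DataFrame([midpoint], index=["mid"], columns=list(STAGES))
        assert assign_to_profiles(rows, ps).tolist() == [1]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        vectors = correlated_vectors(np.eye(3), seed=8)
        ps = _profile_set(vectors, ids=[1, 2, 3])
        rows = pd.DataFrame(rng.normal(size=(10, 7)),
                            index=[f"g{i}" for i in range(10)], columns=list(STAGES))
        fwd = assign_to_profiles(rows, ps)
        rev = assign_to_profiles(rows.iloc[::-1], ps)
        assert fwd.sort_index().equals(rev.sort_index())

    def test_dimension_mismatch_rejected(self):
        ps = _profile_set(correlated_vectors(np.eye(2), seed=9), ids=[1, 2])
        rows = pd.DataFrame(np.zeros((1, 3)), index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="length"):
            assign_to_profiles(rows, ps)


def test_build_profiles_end_to_end(noisy_matrix):
    matrix, _ = noisy_matrix
    ps = build_profiles(matrix, k=10, seed=3)
    assert len(ps.profile_ids) <= 10
    assert np.allclose(ps.memberships.sum(axis=1), 1.0)
    assert set(ps.assignment.unique()) <= set(ps.profile_ids)
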