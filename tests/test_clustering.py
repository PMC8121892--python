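import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from riverdiv import clustering as rc
from riverdiv.river_network import RiverNetwork


def blobs(rng, n_per=6, spread=0.05, centres=((0, 0), (10, 10))):
    pts = np.vstack(
        [rng.normal(c, spread, size=(n_per, 2)) for c in centres]
    )
    truth = np.repeat(np.arange(len(centres)), n_per)
    return pd.DataFrame(pts + 20.0), truth  # shift positive for canberra


def euclid(X):
    arr = np.asarray(X, dtype=float)
    d = np.sqrt(((arr[:, None] - arr[None]) ** 2).sum(-1))
    return pd.DataFrame(d)


class TestCanberra:
    def test_identical_rows_zero(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]])
        assert rc.canberra_matrix(X).iloc[0, 1] == 0.0

    def test_hand_sum(self):
        X = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        assert rc.canberra_matrix(X).iloc[0, 1] == pytest.approx(2.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 30, size=(6, 10)).astype(float)
        D = rc.canberra_matrix(pd.DataFrame(X)).to_numpy()
        for i in range(6):
            for j in range(6):
                s = 0.0
                for v in range(10):
                    tot = X[i, v] + X[j, v]
                    if tot > 0:
                        s += abs(X[i, v] - X[j, v]) / tot
                assert D[i, j] == pytest.approx(s, abs=1e-12)


class TestWard2:
    def test_separated_pairs_merge_first(self):
        X = pd.DataFrame([[0.0, 0], [0.1, 0], [50, 50], [50.1, 50]])
        Z = rc.ward2_linkage(euclid(X))
        first_two = {frozenset(map(int, Z[0, :2])), frozenset(map(int, Z[1, :2]))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("n", [5, 9, 14, 20])
    def test_merge_heights_match_scipy_ward(self, n):
        rng = np.random.default_rng(n)
        pts = rng.random((n, 3))
        D = euclid(pts)
        Z_ours = rc.ward2_linkage(D)
        Z_ref = linkage(squareform(D.to_numpy(), checks=False), method="ward")
        assert Z_ours[:, 2] == pytest.approx(Z_ref[:, 2], rel=1e-9)
        assert (np.diff(Z_ours[:, 2]) >= -1e-9).all()  # monotone merges

    def test_boundary_cuts(self):
        rng = np.random.default_rng(1)
        D = euclid(rng.random((7, 2)))
        Z = rc.ward2_linkage(D)
        assert rc.cut_tree(Z, 7).nunique() == 7
        assert rc.cut_tree(Z, 1).nunique() == 1
        with pytest.raises(ValueError):
            rc.cut_tree(Z, 8)

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            rc.ward2_linkage(bad)

    def test_newick_export_parses(self):
        import dendropy

        rng = np.random.default_rng(2)
        D = euclid(rng.random((5, 2)))
        Z = rc.ward2_linkage(D)
        nwk = rc.linkage_to_newick(Z, [f"s{i}" for i in range(5)])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {
            f"s{i}" for i in range(5)
        }


class TestPartitioningMethods:
    @pytest.mark.parametrize("method", ["hierarchical", "kmeans", "pam", "diana"])
    def test_all_methods_recover_two_blobs(self, method):
        rng = np.random.default_rng(4)
        X, truth = blobs(rng)
        res = rc.cluster_data(X, method, 2, distance="euclidean", seed=0)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_pam_objective_against_exhaustive_search(self):
        """BUILD+SWAP nearly always attains the global medoid optimum.

        The SWAP phase is a steepest descent over single exchanges, so on
        rare instances it stops in a swap-local optimum (the reference
        implementation in R's cluster package stops at the same point);
        every solution must still be swap-locally optimal and never
        beat the exhaustive bound.
        """
        hits = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            D = euclid(rng.random((8, 2)))
            res = rc.pam(D, 2)
            Dn = D.to_numpy()
            best = min(
                rc.pam_objective(Dn, pair)
                for pair in itertools.combinations(range(8), 2)
            )
            assert res.objective >= best - 1e-12
            hits += abs(res.objective - best) < 1e-12
            # exhaustively verify single-swap local optimality
            med = list(res.medoids)
            for mi in range(2):
                for h in range(8):
                    if h in med:
                        continue
                    trial = med[:mi] + [h] + med[mi + 1 :]
                    assert rc.pam_objective(Dn, trial) >= res.objective - 1e-12
        assert hits >= 4

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        D = euclid(rng.random((5, 2)))
        for bad_k in (1, 5):
            with pytest.raises(ValueError):
                rc.pam(D, bad_k)
            with pytest.raises(ValueError):
                rc.kmeans(pd.DataFrame(rng.random((5, 2))), bad_k, seed=0)

    def test_diana_first_split_separates_blobs(self):
        rng = np.random.default_rng(9)
        X, truth = blobs(rng, n_per=5)
        res = rc.diana(euclid(X), k=2)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_labels_are_contiguous_from_one(self):
        rng = np.random.default_rng(3)
        D = euclid(rng.random((9, 2)))
        for res in (rc.pam(D, 3), rc.diana(D, k=3), rc.hclust_ward2(D, k=3)):
            assert sorted(res.labels.unique()) == [1, 2, 3]


# --- naive reference implementations for the internal measures -------------

def ref_connectivity(D, labels, L):
    n = len(labels)
    total = 0.0
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i), key=lambda j: (D[i, j], j)
        )
        for rank, j in enumerate(order[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def ref_dunn(D, labels):
    inter = min(
        D[i, j]
        for i in range(len(labels))
        for j in range(len(labels))
        if labels[i] != labels[j]
    )
    intra = max(
        (
            D[i, j]
            for i in range(len(labels))
            for j in range(len(labels))
            if labels[i] == labels[j]
        ),
        default=0.0,
    )
    return inter / intra


def ref_silhouette(D, labels):
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestInternalMeasures:
    def test_two_tight_distant_clusters(self):
        rng = np.random.default_rng(5)
        X, truth = blobs(rng, spread=1e-4)
        D = euclid(X).to_numpy()
        m = rc.internal_measures(D, truth + 1, L=3)
        assert m["connectivity"] == 0.0
        assert m["silhouette"] > 0.999
        assert m["dunn"] > 100

    @pytest.mark.parametrize("seed", range(5))
    def test_match_naive_references(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        D = euclid(rng.random((n, 2))).to_numpy()
        labels = rng.integers(1, 4, size=n)
        while len(set(labels)) < 2:
            labels = rng.integers(1, 4, size=n)
        assert rc.connectivity(D, labels, L=4) == pytest.approx(
            ref_connectivity(D, labels, 4)
        )
        assert rc.dunn_index(D, labels) == pytest.approx(ref_dunn(D, labels))
        assert rc.silhouette(D, labels) == pytest.approx(ref_silhouette(D, labels))

    def test_silhouette_agrees_with_sklearn(self):
        rng = np.random.default_rng(8)
        X = rng.random((15, 3))
        labels = rng.integers(0, 3, size=15)
        while len(set(labels)) < 2 or min(np.bincount(labels)) < 2:
            labels = rng.integers(0, 3, size=15)
        D = euclid(X).to_numpy()
        assert rc.silhouette(D, labels) == pytest.approx(
            silhouette_score(D, labels, metric="precomputed")
        )

    def test_silhouette_range(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(6, 14))
            D = euclid(rng.random((n, 2))).to_numpy()
            labels = rng.integers(1, 4, size=n)
            if len(set(labels)) < 2:
                continue
            s = rc.silhouette(D, labels)
            assert -1.0 <= s <= 1.0

    def test_single_cluster_rejected(self):
        D = euclid(np.random.default_rng(0).random((6, 2))).to_numpy()
        with pytest.raises(ValueError):
            rc.dunn_index(D, np.ones(6, dtype=int))
        with pytest.raises(ValueError):
            rc.silhouette(D, np.ones(6, dtype=int))


# --- reference implementation of the stability measures --------------------

def ref_stability(X: pd.DataFrame, method: str, k: int):
    """Straightforward loop version of APN/AD/ADM/FOM for the test only."""
    n, p = X.shape
    full = rc.cluster_data(X, method, k, distance="euclidean", seed=0).labels.to_numpy()
    D = euclid(X).to_numpy()
    Xv = X.to_numpy(dtype=float)
    apn, ad, adm, fom = [], [], [], []
    for col in range(p):
        red = rc.cluster_data(
            X.drop(columns=[X.columns[col]]), method, k, distance="euclidean", seed=0
        ).labels.to_numpy()
        for i in range(n):
            c0 = [j for j in range(n) if full[j] == full[i]]
            cl = [j for j in range(n) if red[j] == red[i]]
            inter = len(set(c0) & set(cl))
            apn.append(1 - inter / len(c0))
            ad.append(np.mean([D[a, b] for a in c0 for b in cl]))
            adm.append(
                np.linalg.norm(Xv[cl].mean(axis=0) - Xv[c0].mean(axis=0))
            )
        sq = 0.0
        for c in set(red):
            idx = [j for j in range(n) if red[j] == c]
            mu = Xv[idx, col].mean()
            sq += sum((Xv[j, col] - mu) ** 2 for j in idx)
        fom.append(np.sqrt(sq / n) * np.sqrt(n / (n - k)))
    return {
        "APN": np.mean(apn),
        "AD": np.mean(ad),
        "ADM": np.mean(adm),
        "FOM": np.mean(fom),
    }


class TestStabilityMeasures:
    def test_duplicated_columns_are_perfectly_stable(self):
        rng = np.random.default_rng(6)
        base = rng.random((10, 3)) * np.array([1, 5, 20]) + 1
        X = pd.DataFrame(np.hstack([base, base]))
        out = rc.stability_measures(X, "hierarchical", 2, distance="euclidean", seed=0)
        assert out["APN"] == pytest.approx(0.0)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random((6, 4)) * 10 + 1)
        ours = rc.stability_measures(X, "hierarchical", 2, distance="euclidean", seed=0)
        ref = ref_stability(X, "hierarchical", 2)
        for key in ("APN", "AD", "ADM", "FOM"):
            assert ours[key] == pytest.approx(ref[key]), key

    def test_apn_range_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            X = pd.DataFrame(rng.random((8, 4)) + 0.5)
            out = rc.stability_measures(X, "hierarchical", 2, distance="euclidean", seed=0)
            assert 0.0 <= out["APN"] <= 1.0
            assert out["AD"] >= 0 and out["ADM"] >= 0 and out["FOM"] >= 0


class TestHopkins:
    def test_uniform_data_near_half(self):
        rng = np.random.default_rng(0)
        hs = [
            rc.hopkins(rng.random((200, 2)), seed=s) for s in range(100)
        ]
        assert 0.45 <= np.mean(hs) <= 0.55

    def test_two_tight_blobs_clustered(self):
        rng = np.random.default_rng(1)
        X, _ = blobs(rng, n_per=100, spread=0.01)
        assert rc.hopkins(X.to_numpy(), seed=0) > 0.8

    def test_range_and_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.random((30, 3))
        h1, h2 = rc.hopkins(X, seed=5), rc.hopkins(X, seed=5)
        assert h1 == h2
        assert 0.0 < h1 < 1.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            rc.hopkins(np.ones((10, 2)), seed=0)


@pytest.fixture(scope="module")
def grid():
    rng = np.random.default_rng(10)
    X, _ = blobs(rng, n_per=6, spread=0.3)
    X.columns = ["a", "b"]
    X["c"] = X["a"] * 0.9 + rng.normal(0, 0.1, len(X))
    return rc.validate_grid(X, k_range=[2, 3, 4], distance="euclidean", seed=0)


class TestValidateGrid:

    def test_grid_dimensions(self, grid):
        assert grid.scores.shape[0] == 7 * len(rc.DEFAULT_METHODS) * 3

    def test_optima_respect_directions(self, grid):
        for measure, row in grid.optima.iterrows():
            sub = grid.scores.loc[measure]["score"]
            if rc.MEASURE_DIRECTIONS[measure] == "min":
                assert row["score"] == pytest.approx(sub.min())
            else:
                assert row["score"] == pytest.approx(sub.max())

    def test_well_separated_blobs_select_k2(self, grid):
        internal = grid.optima.loc[["connectivity", "dunn", "silhouette"], "k"]
        assert (internal == 2).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.random((10, 4)) + 1)
        g1 = rc.validate_grid(X, methods=("hierarchical", "pam"), k_range=[2, 3], seed=4)
        g2 = rc.validate_grid(X, methods=("hierarchical", "pam"), k_range=[2, 3], seed=4)
        pd.testing.assert_frame_equal(g1.scores, g2.scores)

    def test_k_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.random((5, 3)))
        with pytest.raises(ValueError):
            rc.validate_grid(X, k_range=[2, 5], seed=0)


class TestProjectClusters:
    def chain(self, n=5):
        return RiverNetwork.from_edges(
            [(f"s{i}", f"s{i+1}", 1.0) for i in range(n - 1)], outlet="s0"
        )

    def test_single_cluster_counts_all_adjacent_pairs(self):
        net = self.chain(5)
        labels = pd.Series(1, index=[f"s{i}" for i in range(5)])
        _, coherence = rc.project_clusters(labels, net)
        assert coherence == {1: 4}

    def test_alternating_labels_have_zero_coherence(self):
        net = self.chain(6)
        labels = pd.Series([1, 2, 1, 2, 1, 2], index=[f"s{i}" for i in range(6)])
        _, coherence = rc.project_clusters(labels, net)
        assert coherence == {1: 0, 2: 0}

    def test_unlabeled_site_raises(self):
        net = self.chain(3)
        labels = pd.Series([1, 1], index=["s0", "s1"])
        with pytest.raises(ValueError, match="s2"):
            rc.project_clusters(labels, net)

    def test_junctions_are_contracted(self):
        net = RiverNetwork.from_edges(
            [("s0", "j", 1.0), ("j", "s1", 1.0)], outlet="s0"
        )
        labels = pd.Series([1, 1], index=["s0", "s1"])
        _, coherence = rc.project_clusters(labels, net, sites=["s0", "s1"])
        assert coherence == {1: 1}
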