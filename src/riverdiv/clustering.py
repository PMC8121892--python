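"""Biogeographical-unit discovery: distances, clustering, validation.

The site x taxon count matrix (cross-assay maximum counts) is turned into
a Canberra distance matrix and clustered with four methods — agglomerative
hierarchical clustering with the ward.D2 Lance-Williams update, k-means,
partitioning around medoids (PAM), and divisive analysis (DIANA). Cluster
solutions over a k range are scored with three internal measures
(connectivity, Dunn index, silhouette) and four leave-one-column-out
stability measures (APN, AD, ADM, FOM), and clustering tendency is
quantified with the Hopkins statistic. The winning (method, k) pairs per
measure form the validation report; labels can be projected back onto the
river network to summarise spatial coherence of the clusters.

Tie-breaking is deterministic throughout: smallest index pair for merges,
smallest k then method order for optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

#: measure name -> optimisation direction
MEASURE_DIRECTIONS = {
    "connectivity": "min",
    "dunn": "max",
    "silhouette": "max",
    "APN": "min",
    "AD": "min",
    "ADM": "min",
    "FOM": "min",
}
INTERNAL_MEASURES = ("connectivity", "dunn", "silhouette")
STABILITY_MEASURES = ("APN", "AD", "ADM", "FOM")
DEFAULT_METHODS = ("hierarchical", "kmeans", "pam", "diana")


@dataclass
class ClusteringResult:
    """A flat clustering, plus the merge tree for hierarchical methods."""

    method: str
    k: int
    labels: pd.Series  # site -> 1..k
    linkage: np.ndarray | None = field(default=None, repr=False)
    objective: float | None = None  # WSS (kmeans) or medoid cost (pam)
    medoids: list | None = None


@dataclass
class ValidationReport:
    """Measure x method x k score grid with per-measure optima."""

    scores: pd.DataFrame  # index (measure, method, k) -> score
    optima: pd.DataFrame  # index measure -> method, k, score, direction
    hopkins: float

    def to_table(self) -> pd.DataFrame:
        """Printable analogue of a validation-summary table."""
        kind = {m: ("Internal" if m in INTERNAL_MEASURES else "Stability") for m in self.optima.index}
        out = self.optima.copy()
        out.insert(0, "type", [kind[m] for m in out.index])
        return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def canberra_matrix(m) -> pd.DataFrame:
    """Site x site Canberra distance matrix of a count community matrix.

    d(x, y) = sum_j |x_j - y_j| / (x_j + y_j) over variables with
    x_j + y_j > 0; variables zero at both sites contribute 0 and are not
    rescaled for (a dialect choice some implementations differ on).
    """
    values = m.values if hasattr(m, "values") else m
    X = np.asarray(values, dtype=float)
    if (X < 0).any():
        raise ValueError("Canberra distance requires non-negative values")
    D = squareform(pdist(X, metric="canberra"))
    index = values.index if isinstance(values, pd.DataFrame) else pd.RangeIndex(len(X))
    return pd.DataFrame(D, index=index, columns=index)


def _check_distance(d) -> np.ndarray:
    D = np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    return D


# ---------------------------------------------------------------------------
# hierarchical: ward.D2
# ---------------------------------------------------------------------------

def ward2_linkage(d) -> np.ndarray:
    """Agglomerate by the ward.D2 Lance-Williams update; scipy-format Z.

    At each step the closest active pair merges (ties broken by the
    lexicographically smallest pair of smallest-original-member indices)
    and distances to the merged cluster follow

        d(ij, l) = sqrt[ ((n_i + n_l) d_il^2 + (n_j + n_l) d_jl^2
                          - n_l d_ij^2) / (n_i + n_j + n_l) ].

    Returns an (n-1) x 4 linkage array (child, child, height, size) in
    scipy convention.
    """
    D = _check_distance(d).copy()
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 objects")
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}  # smallest original member, for ties
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    big = np.full(n, np.inf)
    work = np.full((2 * n - 1, 2 * n - 1), np.inf)
    work[:n, :n] = D
    np.fill_diagonal(work, np.inf)
    next_id = n
    for step in range(n - 1):
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                u, v = active[ai], active[bi]
                duv = work[u, v]
                pair = tuple(sorted((rep[u], rep[v])))
                if duv < best[0] - 1e-15 or (
                    abs(duv - best[0]) <= 1e-15 and best[1] is not None and pair < best[1]
                ):
                    best = (duv, pair, (u, v))
        duv, _, (u, v) = best
        nu, nv = size[u], size[v]
        for w in active:
            if w in (u, v):
                continue
            nw = size[w]
            d2 = (
                (nu + nw) * work[u, w] ** 2
                + (nv + nw) * work[v, w] ** 2
                - nw * duv**2
            ) / (nu + nv + nw)
            work[next_id, w] = work[w, next_id] = np.sqrt(max(d2, 0.0))
        Z[step] = (min(u, v), max(u, v), duv, nu + nv)
        size[next_id] = nu + nv
        rep[next_id] = min(rep[u], rep[v])
        active.remove(u)
        active.remove(v)
        active.append(next_id)
        next_id += 1
    return Z


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster codes to 1..k in order of first appearance."""
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


def cut_tree(Z: np.ndarray, k: int, index=None) -> pd.Series:
    """Cut a linkage into k groups by descending merge height."""
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_first_occurrence(raw)
    return pd.Series(labels, index=index if index is not None else pd.RangeIndex(n))


def hclust_ward2(d, k: int | None = None) -> ClusteringResult:
    """Ward.D2 hierarchical clustering of a distance matrix."""
    index = d.index if isinstance(d, pd.DataFrame) else None
    Z = ward2_linkage(d)
    n = Z.shape[0] + 1
    kk = k if k is not None else 1
    labels = cut_tree(Z, kk, index=index)
    return ClusteringResult(method="hierarchical", k=kk, labels=labels, linkage=Z)


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialise a linkage as a Newick string, branch lengths from heights."""
    n = Z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    node = {i: str(leaf_names[i]) for i in range(n)}
    for step in range(n - 1):
        a, b, h, _ = Z[step]
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + step] = h
    return node[2 * n - 2] + ";"


# ---------------------------------------------------------------------------
# partitioning methods
# ---------------------------------------------------------------------------

def kmeans(X, k: int, n_start: int = 25, max_iter: int = 100, seed: int | None = None) -> ClusteringResult:
    """Lloyd k-means on the raw data rows, best of ``n_start`` random inits."""
    values = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    n = len(values)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}]")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_start,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=None if seed is None else seed % (2**32),
    ).fit(values.to_numpy(dtype=float))
    labels = _relabel_first_occurrence(km.labels_)
    return ClusteringResult(
        method="kmeans",
        k=k,
        labels=pd.Series(labels, index=values.index),
        objective=float(km.inertia_),
    )


def pam_objective(D: np.ndarray, medoids: Sequence[int]) -> float:
    """Total dissimilarity of every object to its nearest medoid."""
    return float(D[:, list(medoids)].min(axis=1).sum())


def pam(d, k: int) -> ClusteringResult:
    """Partitioning around medoids: greedy BUILD then steepest-descent SWAP.

    BUILD seeds with the object of minimum total dissimilarity and adds
    the medoid with the largest cost reduction; SWAP applies the single
    best (medoid, non-medoid) exchange until no exchange lowers the total
    cost. All ties resolve to the smallest object index.
    """
    index = d.index if isinstance(d, pd.DataFrame) else None
    D = _check_distance(d)
    n = D.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}]")
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        nearest = D[:, medoids].min(axis=1)
        gains = np.array(
            [
                np.maximum(nearest - D[:, j], 0.0).sum() if j not in medoids else -np.inf
                for j in range(n)
            ]
        )
        medoids.append(int(np.argmax(gains)))  # argmax takes first (smallest index) on ties
    # SWAP
    cost = pam_objective(D, medoids)
    improved = True
    while improved:
        improved = False
        best = (cost, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                c = pam_objective(D, trial)
                if c < best[0] - 1e-12:
                    best = (c, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            cost = best[0]
            improved = True
    assign = np.argmin(D[:, medoids], axis=1)
    labels = _relabel_first_occurrence(assign)
    return ClusteringResult(
        method="pam",
        k=k,
        labels=pd.Series(labels, index=index if index is not None else pd.RangeIndex(n)),
        objective=cost,
        medoids=[medoids[i] for i in range(k)],
    )


def _diana_split(D: np.ndarray, members: list[int]) -> tuple[list[int], list[int]]:
    """Macnaughton-Smith splinter split of one cluster."""
    rest = list(members)
    sub = D[np.ix_(rest, rest)]
    avg = sub.sum(axis=1) / (len(rest) - 1)
    start = int(np.argmax(avg))  # first index on ties
    splinter = [rest.pop(start)]
    while len(rest) > 1:
        diffs = []
        for pos, i in enumerate(rest):
            others = [j for j in rest if j != i]
            a = D[i, others].mean()
            b = D[i, splinter].mean()
            diffs.append(a - b)
        pos = int(np.argmax(diffs))
        if diffs[pos] <= 0:
            break
        splinter.append(rest.pop(pos))
    return splinter, rest


def diana(d, k: int | None = None) -> ClusteringResult:
    """Divisive analysis clustering of a distance matrix.

    Repeatedly splits the cluster with the largest diameter, seeding the
    splinter group with the object of maximal average dissimilarity and
    moving objects while they sit closer (on average) to the splinter
    than to the remainder. ``cut`` at k stops after k - 1 splits. The
    recorded ``linkage`` lists splits with the parent diameter as height.
    """
    index = d.index if isinstance(d, pd.DataFrame) else None
    D = _check_distance(d)
    n = D.shape[0]
    kk = k if k is not None else n
    if not 1 <= kk <= n:
        raise ValueError(f"k must be in [1, {n}]")
    clusters: list[list[int]] = [list(range(n))]
    while len(clusters) < kk:
        diameters = [
            D[np.ix_(c, c)].max() if len(c) > 1 else 0.0 for c in clusters
        ]
        target = int(np.argmax(diameters))
        if diameters[target] == 0.0:
            break  # only duplicate points remain
        members = clusters.pop(target)
        splinter, rest = _diana_split(D, members)
        clusters.extend([splinter, rest])
    labels_arr = np.empty(n, dtype=int)
    for cid, c in enumerate(clusters):
        labels_arr[c] = cid
    labels = _relabel_first_occurrence(labels_arr)
    return ClusteringResult(
        method="diana",
        k=len(clusters),
        labels=pd.Series(labels, index=index if index is not None else pd.RangeIndex(n)),
    )


# ---------------------------------------------------------------------------
# unified runner
# ---------------------------------------------------------------------------

def cluster_data(
    X: pd.DataFrame,
    method: str,
    k: int,
    distance: Callable | str = "canberra",
    seed: int | None = None,
) -> ClusteringResult:
    """Cluster rows of ``X`` with one of the registered methods.

    ``kmeans`` works on the raw rows; the other methods work on the
    distance matrix (Canberra by default, or any callable giving a
    DataFrame).
    """
    if method == "kmeans":
        return kmeans(X, k, seed=seed)
    if callable(distance):
        D = distance(X)
    elif distance == "canberra":
        D = canberra_matrix(X)
    elif distance == "euclidean":
        arr = squareform(pdist(np.asarray(X, dtype=float)))
        D = pd.DataFrame(arr, index=X.index, columns=X.index)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    if method == "hierarchical":
        return hclust_ward2(D, k=k)
    if method == "pam":
        return pam(D, k)
    if method == "diana":
        return diana(D, k=k)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# internal validation measures
# ---------------------------------------------------------------------------

def connectivity(d, labels, L: int = 10) -> float:
    """Degree to which nearest neighbours share a cluster (minimise).

    Each observation contributes 1/j for every j-th nearest neighbour
    (j = 1..L) assigned to a different cluster; neighbour ties break by
    index.
    """
    D = _check_distance(d)
    lab = np.asarray(labels)
    n = len(lab)
    if L >= n:
        raise ValueError("neighbourhood L must be smaller than n")
    total = 0.0
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        order = order[order != i][:L]
        for j, nb in enumerate(order, start=1):
            if lab[nb] != lab[i]:
                total += 1.0 / j
    return total


def dunn_index(d, labels) -> float:
    """Min inter-cluster distance over max intra-cluster diameter (maximise)."""
    D = _check_distance(d)
    lab = np.asarray(labels)
    ks = np.unique(lab)
    if len(ks) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    inter = np.inf
    diam = 0.0
    for a in range(len(ks)):
        ia = np.where(lab == ks[a])[0]
        if len(ia) > 1:
            diam = max(diam, D[np.ix_(ia, ia)].max())
        for b in range(a + 1, len(ks)):
            ib = np.where(lab == ks[b])[0]
            inter = min(inter, D[np.ix_(ia, ib)].min())
    if diam == 0.0:
        return np.inf
    return float(inter / diam)


def silhouette(d, labels) -> float:
    """Mean silhouette width; singletons score 0 (maximise)."""
    D = _check_distance(d)
    lab = np.asarray(labels)
    ks = np.unique(lab)
    if len(ks) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(lab)
    s = np.zeros(n)
    for i in range(n):
        own = np.where(lab == lab[i])[0]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, lab == c].mean() for c in ks if c != lab[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def internal_measures(d, labels, L: int = 10) -> dict[str, float]:
    """Connectivity, Dunn index and mean silhouette for one clustering."""
    return {
        "connectivity": connectivity(d, labels, L=L),
        "dunn": dunn_index(d, labels),
        "silhouette": silhouette(d, labels),
    }


# ---------------------------------------------------------------------------
# stability validation measures
# ---------------------------------------------------------------------------

def stability_measures(
    X: pd.DataFrame,
    method: str,
    k: int,
    distance: Callable | str = "canberra",
    seed: int | None = None,
    full_result: ClusteringResult | None = None,
) -> dict[str, float]:
    """Leave-one-column-out stability of a clustering (all minimised).

    The data are reclustered once per deleted taxon column with the same
    method, k and seed; APN measures label-set non-overlap, AD the
    average full-data distance between an observation's original and
    perturbed co-cluster members, ADM the Euclidean shift of its cluster
    centroid (full-data column means), and FOM the residual spread of
    the deleted column around the perturbed clustering's cluster means,
    with the sqrt(n/(n-k)) adjustment. Columns on which the reclustering
    fails are skipped with a warning.
    """
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if p < 2:
        raise ValueError("need at least 2 columns")
    if full_result is None:
        full_result = cluster_data(X, method, k, distance=distance, seed=seed)
    lab0 = full_result.labels.to_numpy()
    if callable(distance) or distance != "canberra":
        arr = squareform(pdist(Xv))
        D = arr
    else:
        D = canberra_matrix(X).to_numpy()
    members0 = {c: np.where(lab0 == c)[0] for c in np.unique(lab0)}
    cent0 = {c: Xv[idx].mean(axis=0) for c, idx in members0.items()}
    apn_terms, ad_terms, adm_terms, fom_terms = [], [], [], []
    for col in range(p):
        Xl = X.drop(columns=[X.columns[col]])
        try:
            res_l = cluster_data(Xl, method, k, distance=distance, seed=seed)
        except Exception as exc:  # pragma: no cover - degenerate reduced data
            warnings.warn(f"clustering failed with column {X.columns[col]!r} removed: {exc}")
            continue
        lab_l = res_l.labels.to_numpy()
        members_l = {c: np.where(lab_l == c)[0] for c in np.unique(lab_l)}
        cent_l = {c: Xv[idx].mean(axis=0) for c, idx in members_l.items()}
        for i in range(n):
            c0 = members0[lab0[i]]
            cl = members_l[lab_l[i]]
            inter = np.intersect1d(c0, cl, assume_unique=True)
            apn_terms.append(1.0 - len(inter) / len(c0))
            ad_terms.append(D[np.ix_(c0, cl)].mean())
            adm_terms.append(float(np.linalg.norm(cent_l[lab_l[i]] - cent0[lab0[i]])))
        x_col = Xv[:, col]
        sq = 0.0
        for c, idx in members_l.items():
            mu = x_col[idx].mean()
            sq += ((x_col[idx] - mu) ** 2).sum()
        fom_terms.append(np.sqrt(sq / n) * np.sqrt(n / (n - k)))
    return {
        "APN": float(np.mean(apn_terms)),
        "AD": float(np.mean(ad_terms)),
        "ADM": float(np.mean(adm_terms)),
        "FOM": float(np.mean(fom_terms)),
    }


# ---------------------------------------------------------------------------
# clustering tendency
# ---------------------------------------------------------------------------

def hopkins(X, m: int | None = None, seed: int | None = None) -> float:
    """Hopkins clustering-tendency statistic in (0, 1).

    Compares nearest-neighbour distances of m sampled data rows (w_i,
    distance to the nearest *other* row) with those of m uniform
    pseudo-points drawn in the per-column min-max bounding box (u_i,
    distance to the nearest data row): H = sum(u) / (sum(u) + sum(w)).
    Around 0.5 for spatially random data, toward 1 for clustered data.
    """
    Xv = np.asarray(X, dtype=float)
    n = Xv.shape[0]
    if n < 5:
        raise ValueError("need at least 5 rows")
    if np.ptp(Xv, axis=0).max() == 0:
        raise ValueError("degenerate data: all rows identical")
    if m is None:
        m = max(2, int(np.floor(0.1 * n)))
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=m, replace=False)
    lo, hi = Xv.min(axis=0), Xv.max(axis=0)
    pseudo = rng.uniform(lo, hi, size=(m, Xv.shape[1]))
    from scipy.spatial.distance import cdist

    dw = cdist(Xv[rows], Xv)
    dw[np.arange(m), rows] = np.inf  # exclude self
    w = dw.min(axis=1)
    u = cdist(pseudo, Xv).min(axis=1)
    return float(u.sum() / (u.sum() + w.sum()))


# ---------------------------------------------------------------------------
# validation grid & projection
# ---------------------------------------------------------------------------

def validate_grid(
    X: pd.DataFrame,
    methods: Sequence[str] = DEFAULT_METHODS,
    k_range: Sequence[int] = tuple(range(2, 11)),
    measures: Sequence[str] = tuple(MEASURE_DIRECTIONS),
    distance: Callable | str = "canberra",
    L: int = 10,
    seed: int | None = None,
) -> ValidationReport:
    """Score every (measure, method, k) combination and pick optima.

    Internal measures are computed on the Canberra distance matrix of the
    full data; stability measures recluster once per deleted column.
    Per-measure optima follow each measure's direction, with ties broken
    by smallest k and then by method order as supplied.
    """
    n = len(X)
    bad = [k for k in k_range if not 2 <= k <= n - 1]
    if bad:
        raise ValueError(f"k values out of [2, {n - 1}]: {bad}")
    L = min(L, n - 1)  # connectivity neighbourhood cannot exceed n - 1
    if distance == "canberra":
        D = canberra_matrix(X)
    elif callable(distance):
        D = distance(X)
    else:
        arr = squareform(pdist(np.asarray(X, dtype=float)))
        D = pd.DataFrame(arr, index=X.index, columns=X.index)
    want_internal = [m for m in measures if m in INTERNAL_MEASURES]
    want_stability = [m for m in measures if m in STABILITY_MEASURES]
    rows = []
    for method in methods:
        for k in k_range:
            res = cluster_data(X, method, k, distance=distance, seed=seed)
            scores: dict[str, float] = {}
            if want_internal:
                scores.update(internal_measures(D, res.labels, L=L))
            if want_stability:
                scores.update(
                    stability_measures(X, method, k, distance=distance, seed=seed, full_result=res)
                )
            for meas in measures:
                rows.append({"measure": meas, "method": method, "k": k, "score": scores[meas]})
    grid = pd.DataFrame(rows).set_index(["measure", "method", "k"])
    method_order = {m: i for i, m in enumerate(methods)}
    optima_rows = []
    for meas in measures:
        sub = grid.loc[meas].reset_index()
        direction = MEASURE_DIRECTIONS[meas]
        key = sub["score"] if direction == "min" else -sub["score"]
        sub = sub.assign(_key=key, _m=sub["method"].map(method_order))
        sub = sub.sort_values(["_key", "k", "_m"], kind="stable")
        top = sub.iloc[0]
        optima_rows.append(
            {
                "measure": meas,
                "method": top["method"],
                "k": int(top["k"]),
                "score": float(top["score"]),
                "direction": direction,
            }
        )
    optima = pd.DataFrame(optima_rows).set_index("measure")
    h = hopkins(X.to_numpy(dtype=float), seed=seed)
    return ValidationReport(scores=grid, optima=optima, hopkins=h)


def project_clusters(labels: pd.Series, net, sites: Sequence[str] | None = None):
    """Project cluster labels onto the river network.

    Returns the site -> cluster table and, per cluster, the number of
    network-adjacent same-cluster site pairs (two sites are adjacent when
    joined by a channel path passing through no other site). Raises if a
    network site is unlabeled.
    """
    import networkx as nx

    site_list = list(sites) if sites is not None else list(net.graph.nodes)
    unlabeled = [s for s in site_list if s not in labels.index]
    if unlabeled:
        raise ValueError(f"unlabeled site(s): {unlabeled}")
    site_set = set(site_list)
    adj = nx.Graph()
    adj.add_nodes_from(site_list)
    # contract junction-only paths so adjacency means "no site in between"
    for s in site_list:
        seen = {s}
        frontier = [(s, nb) for nb in net.graph.neighbors(s)]
        while frontier:
            origin, node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in site_set:
                adj.add_edge(s, node)
            else:
                frontier.extend((node, nb) for nb in net.graph.neighbors(node))
    table = pd.DataFrame({"site_id": site_list, "cluster": [labels[s] for s in site_list]})
    coherence = {int(c): 0 for c in sorted(labels.loc[site_list].unique())}
    for u, v in adj.edges:
        if labels[u] == labels[v]:
            coherence[int(labels[u])] += 1
    return table, coherence
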