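"""Clustering heuristics built on jury ranking and profile hashing.

Three heuristics cover different needs:

* ``hash_cluster`` — Hash(K, F): micro-clusters by exact key identity,
  coarsened by removing high-entropy key positions until the K largest
  groups hold F% of the data.
* ``rpart_cluster`` — Rpart(K, F): reference-based partitioning; spheres of
  an adaptively bisected Hamming radius are peeled off around successive
  jury-selected reference models.
* ``tree_cluster`` — approximate hierarchical clustering: micro-clusters
  from Hash/Rpart seeding (large K, F = 100) are reduced to their jury
  centroids, and ordinary average-linkage agglomeration runs on the
  centroids only, giving O(N*L + k_micro^2) work instead of O(N^2).

A k-medoids baseline, dendrogram cutting, the Rand index and model-quality
selection metrics round out the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .hashing import group_by_key, key_entropy, key_matrix, make_hash_keys, quantize_frequency
from .jury import JuryResult, jury_rank, jury_rank_frequency
from .profiles import FrequencyProfile, ProfileSet
from .similarity import kabsch_rmsd, pairwise_hamming_matrix
from .structio import ModelSet, extract_trace

__all__ = [
    "ClusteringParams",
    "ClusterSolution",
    "Dendrogram",
    "hash_cluster",
    "rpart_cluster",
    "tree_cluster",
    "kmedoids_cluster",
    "cut_dendrogram",
    "rand_index",
    "evaluate_selection",
    "write_clusters",
]

COVERAGE_TOL = 0.5  # percentage points


@dataclass
class ClusteringParams:
    """K = target cluster count; F = target data coverage in percent."""

    K: int
    F: float = 100.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.F <= 100):
            raise ValueError("F must be in (0, 100]")


@dataclass
class ClusterSolution:
    """K (or fewer populated) disjoint clusters with centroid ids.

    ``coverage`` is the achieved percentage of all models contained in the
    reported clusters; models outside them are listed in ``unassigned``.
    """

    clusters: list[tuple[list[str], str]]  # (member ids, centroid id)
    coverage: float
    unassigned: list[str] = field(default_factory=list)

    def labels(self, ids: list[str]) -> np.ndarray:
        """Integer label per id; unassigned models get label -1."""
        lab = {mid: -1 for mid in ids}
        for c, (members, _cent) in enumerate(self.clusters):
            for m in members:
                lab[m] = c
        return np.asarray([lab[mid] for mid in ids])

    @property
    def centroid_ids(self) -> list[str]:
        return [cent for _members, cent in self.clusters]


@dataclass
class Dendrogram:
    """Binary merge tree over micro-cluster leaves.

    Leaves are ``(centroid_id, member_ids)`` records; ``merges`` follows the
    scipy convention: merge t joins nodes a and b (leaf indices < n_leaves,
    internal nodes n_leaves + t') at the given average-linkage height.
    """

    leaves: list[tuple[str, list[str]]]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def model_ids(self) -> list[str]:
        return [m for _cid, members in self.leaves for m in members]

    def to_newick(self) -> str:
        """Newick string with leaf labels ``centroidID_size``."""
        n = self.n_leaves

        def render(node: int) -> str:
            if node < n:
                cid, members = self.leaves[node]
                return f"{cid}_{len(members)}"
            a, b, h = self.merges[node - n]
            ha = self.merges[a - n][2] if a >= n else 0.0
            hb = self.merges[b - n][2] if b >= n else 0.0
            return f"({render(a)}:{h - ha:.6g},{render(b)}:{h - hb:.6g})"

        if not self.merges:
            return render(0) + ";"
        return render(n + len(self.merges) - 1) + ";"


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _subset_jury_centroid(profiles: ProfileSet, member_ids: list[str]) -> str:
    """Id of the member with the highest jury score within the subset."""
    if len(member_ids) == 1:
        return member_ids[0]
    idx = {mid: i for i, mid in enumerate(profiles.ids)}
    sub = ProfileSet(profiles.alphabet, [profiles.profiles[idx[m]] for m in member_ids])
    return jury_rank(sub).reference_id


def _top_k_groups(index_groups: dict, k: int) -> list[bytes]:
    """Keys of the k largest groups; ties keep earlier first appearance."""
    order = sorted(index_groups, key=lambda p: -len(index_groups[p]))
    return order[:k]  # sorted() is stable -> insertion (first appearance) order on ties


# ---------------------------------------------------------------------------
# Hash(K, F)
# ---------------------------------------------------------------------------

def hash_cluster(profiles: ProfileSet, params: ClusteringParams) -> ClusterSolution:
    """Hash(K, F): entropy-guided key coarsening until the K largest
    micro-clusters cover F% of the models.

    Keys are built against the 1D-jury reference.  While the K largest
    key-identity groups hold less than F% of the data, the remaining key
    position of maximal bit entropy (ties to the lowest index) is removed
    and the models regrouped on the surviving positions.  If every position
    is exhausted the best coverage seen is returned (with a warning).
    Centroids are the members with the highest within-group jury score.
    """
    N = len(profiles)
    if params.K > N:
        raise ValueError(f"K={params.K} exceeds the number of models N={N}")
    ref = jury_rank(profiles)
    ref_profile = profiles.profiles[profiles.ids.index(ref.reference_id)]
    keys = make_hash_keys(profiles, ref_profile)

    # bit entropies never change as positions are dropped: fix removal order
    ent = key_entropy(keys)
    removal_order = np.lexsort((np.arange(len(ent)), -ent))

    L = profiles.length
    active = np.ones(L, dtype=bool)
    best: tuple[float, dict] | None = None
    n_removed = 0
    while True:
        index = group_by_key(keys, reference_id=ref.reference_id,
                             positions=np.flatnonzero(active))
        top = _top_k_groups(index.groups, params.K)
        coverage = 100.0 * sum(len(index.groups[p]) for p in top) / N
        if best is None or coverage > best[0]:
            best = (coverage, {p: index.groups[p] for p in top})
        if coverage >= params.F:
            break
        if n_removed == L:
            warnings.warn(
                f"Hash({params.K},{params.F}): coverage target unreachable; "
                f"returning best coverage {best[0]:.1f}%"
            )
            break
        active[removal_order[n_removed]] = False
        n_removed += 1

    coverage, top_groups = best
    clusters = [(members, _subset_jury_centroid(profiles, members))
                for members in top_groups.values()]
    assigned = {m for members, _c in clusters for m in members}
    unassigned = [m for m in profiles.ids if m not in assigned]
    return ClusterSolution(clusters=clusters, coverage=coverage, unassigned=unassigned)


# ---------------------------------------------------------------------------
# Rpart(K, F)
# ---------------------------------------------------------------------------

def initial_radius(d_max: int) -> int:
    """Initial clustering radius: a quarter of the maximum Hamming distance
    from the jury reference, rounded up."""
    return math.ceil(d_max / 4)


def rpart_cluster(profiles: ProfileSet, params: ClusteringParams,
                  candidate_window_factor: float = 2.0) -> ClusterSolution:
    """Rpart(K, F): reference-based partitioning in binary key space.

    The model set is reduced to binary keys against the 1D-jury reference.
    An inner pass peels off up to K spheres: each sphere collects the
    unassigned models within the current Hamming radius of the current
    reference key; the next reference is the unassigned model of highest
    (global) jury score among those closer than ``candidate_window_factor``
    times the initial radius to the original reference (falling back to all
    unassigned models when that window is empty), and the cluster radius
    resets to that model's distance from the original reference, scaled by
    the outer loop's current radius factor.  The outer loop is an integer
    bisection on the bracketing radius (initially a quarter of the maximum
    distance to the jury reference, which also fixes the scale factor 1):
    the radius is increased while coverage falls short of F and decreased
    once F is met, so the returned partition is the most granular one that
    attains the coverage target.
    """
    N = len(profiles)
    if params.K > N:
        raise ValueError(f"K={params.K} exceeds the number of models N={N}")
    ref = jury_rank(profiles)
    ids = profiles.ids
    ref_idx = ids.index(ref.reference_id)
    ref_profile = profiles.profiles[ref_idx]
    keys = make_hash_keys(profiles, ref_profile)
    B = key_matrix(keys)
    d_orig = B.sum(axis=1).astype(np.int64)  # popcount = distance to jury reference
    scores = np.asarray([ref.scores[i] for i in ids])
    D_max = int(d_orig.max())

    if D_max == 0:  # all profiles identical
        return ClusterSolution(clusters=[(list(ids), ref.reference_id)],
                               coverage=100.0, unassigned=[])

    r0_init = initial_radius(D_max)
    window = candidate_window_factor * r0_init

    def inner_pass(r0: int) -> tuple[float, list[tuple[list[str], str]]]:
        scale = r0 / r0_init
        unassigned = np.ones(N, dtype=bool)
        clusters: list[tuple[list[str], str]] = []
        cur_idx, cur_radius = ref_idx, r0
        for _ in range(params.K):
            d_cur = (B ^ B[cur_idx]).sum(axis=1).astype(np.int64)
            members = np.flatnonzero(unassigned & (d_cur <= cur_radius))
            if len(members) == 0:  # sphere at least holds its own reference
                members = np.asarray([cur_idx])
            clusters.append(([ids[i] for i in members], ids[cur_idx]))
            unassigned[members] = False
            if not unassigned.any():
                break
            cand = unassigned & (d_orig < window)
            pool = np.flatnonzero(cand) if cand.any() else np.flatnonzero(unassigned)
            cur_idx = int(pool[np.argmax(scores[pool])])
            # reset to the new reference's distance from the original jury
            # reference, rescaled by the outer loop's radius factor
            cur_radius = max(1, round(d_orig[cur_idx] * scale))
        coverage = 100.0 * (N - int(unassigned.sum())) / N
        return coverage, clusters

    # Integer bisection for the smallest radius whose coverage reaches F:
    # a larger radius is tried when coverage falls short, a smaller one when
    # F is (already) met, so the returned partition is as granular as the
    # coverage target allows.  Coverage at r = D_max is always 100%, so the
    # search cannot fail for any F <= 100.
    lo, hi = 1, D_max
    r = min(max(r0_init, lo), hi)
    best_covering: tuple[float, list] | None = None
    best_seen: tuple[float, list] | None = None
    while True:
        coverage, clusters = inner_pass(r)
        if best_seen is None or coverage > best_seen[0]:
            best_seen = (coverage, clusters)
        if coverage >= params.F - COVERAGE_TOL:
            best_covering = (coverage, clusters)
            hi = r - 1
        else:
            lo = r + 1
        if lo > hi:
            break
        r = (lo + hi) // 2

    coverage, clusters = best_covering if best_covering is not None else best_seen
    assigned = {m for members, _c in clusters for m in members}
    unassigned_ids = [m for m in ids if m not in assigned]
    return ClusterSolution(clusters=clusters, coverage=coverage, unassigned=unassigned_ids)


# ---------------------------------------------------------------------------
# Approximate hierarchical clustering (Tree)
# ---------------------------------------------------------------------------

def _centroid_distance_matrix(centroid_ids: list[str], distance: str,
                              profiles, model_set: ModelSet | None,
                              trace_atom: str) -> np.ndarray:
    if distance == "hamming":
        idx = {mid: i for i, mid in enumerate(profiles.ids)}
        X = profiles.matrix()[[idx[c] for c in centroid_ids]]
        return pairwise_hamming_matrix(X)
    if distance == "cosine":
        by_id = {v.model_id: v for v in profiles}
        V = np.stack([by_id[c].counts / np.linalg.norm(by_id[c].counts)
                      for c in centroid_ids])
        D = 1.0 - np.clip(V @ V.T, -1.0, 1.0)
        np.fill_diagonal(D, 0.0)
        return D
    if distance == "rmsd":
        if model_set is None:
            raise ValueError("distance='rmsd' requires the model coordinates")
        by_id = {m.id: m for m in model_set}
        traces = [extract_trace(by_id[c], trace_atom).coords for c in centroid_ids]
        n = len(traces)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = kabsch_rmsd(traces[i], traces[j]).rmsd
        return D
    raise ValueError(f"unknown distance {distance!r}")


def _size_weighted_average_linkage(D: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Lance-Williams average linkage weighting clusters by member counts."""
    n = len(D)
    D = D.astype(float).copy()
    active = {i: (i, float(sizes[i])) for i in range(n)}  # node -> (scipy id, weight)
    Z = []
    next_id = n
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], sorted(kv[0])))
        i, j = sorted(i for i in (i, j))
        (id_i, w_i), (id_j, w_j) = active[i], active[j]
        Z.append((id_i, id_j, h))
        for k in list(active):
            if k in (i, j):
                continue
            d_new = (w_i * dist[frozenset((k, i))] + w_j * dist[frozenset((k, j))]) / (w_i + w_j)
            dist[frozenset((k, i))] = d_new
            del dist[frozenset((k, j))]
        del dist[frozenset((i, j))]
        del active[j]
        active[i] = (next_id, w_i + w_j)
        next_id += 1
    return np.asarray([[a, b, h, 0.0] for a, b, h in Z])


def tree_cluster(profiles, distance: str = "hamming", k_micro: int = 1000,
                 seeding: str = "rpart", model_set: ModelSet | None = None,
                 trace_atom: str = "CA", size_weighted: bool = False) -> Dendrogram:
    """Approximate hierarchical clustering via micro-cluster centroids.

    Micro-clusters come from the chosen seeding heuristic run with
    (K = k_micro, F = 100); models the seeding pass leaves unassigned become
    singleton leaves so the tree always covers all models.  Each leaf is
    represented by its within-cluster 1D-jury centroid, and unweighted
    average-linkage agglomeration (scipy) runs on centroid-to-centroid
    distances: Hamming for state profiles, cosine for frequency profiles,
    or Kabsch RMSD on centroid coordinates.

    Parameters
    ----------
    profiles : ProfileSet or list of FrequencyProfile
        State profiles (hamming/rmsd seeding basis) or frequency profiles
        (cosine; hashed via count quantisation for seeding).
    """
    if isinstance(profiles, ProfileSet):
        if distance == "cosine":
            raise ValueError("cosine distance requires frequency profiles")
        state_profiles = profiles
        freq = None
    else:
        vectors = list(profiles)
        if not vectors or not isinstance(vectors[0], FrequencyProfile):
            raise ValueError("profiles must be a ProfileSet or frequency profiles")
        if distance == "hamming":
            raise ValueError("hamming distance requires state profiles")
        freq = vectors
        state_profiles = ProfileSet(
            quantize_frequency(vectors[0]).alphabet,
            [quantize_frequency(v) for v in vectors],
        )
    if distance == "rmsd" and model_set is None:
        raise ValueError("distance='rmsd' requires model_set coordinates")

    params = ClusteringParams(K=min(k_micro, len(state_profiles)), F=100.0)
    if seeding == "rpart":
        solution = rpart_cluster(state_profiles, params)
    elif seeding == "hash":
        solution = hash_cluster(state_profiles, params)
    else:
        raise ValueError(f"unknown seeding {seeding!r}")

    micro = [list(members) for members, _c in solution.clusters if members]
    micro += [[mid] for mid in solution.unassigned]

    if freq is not None:
        by_id = {v.model_id: v for v in freq}

        def centroid_of(members: list[str]) -> str:
            if len(members) == 1:
                return members[0]
            return jury_rank_frequency([by_id[m] for m in members]).reference_id
    else:
        def centroid_of(members: list[str]) -> str:
            return _subset_jury_centroid(state_profiles, members)

    leaves = [(centroid_of(members), members) for members in micro]
    centroid_ids = [cid for cid, _m in leaves]
    if len(leaves) == 1:
        return Dendrogram(leaves=leaves, merges=[])

    D = _centroid_distance_matrix(centroid_ids, distance,
                                  freq if freq is not None else state_profiles,
                                  model_set, trace_atom)
    if size_weighted:
        Z = _size_weighted_average_linkage(D, np.asarray([len(m) for _c, m in leaves]))
    else:
        Z = sch.linkage(squareform(D, checks=False), method="average")
    merges = [(int(a), int(b), float(h)) for a, b, h, _cnt in Z]
    return Dendrogram(leaves=leaves, merges=merges)


def cut_dendrogram(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into k clusters by removing the k - 1 highest merges.

    Returns a model_id -> cluster label map (labels 0..k-1 in order of
    first appearance over the leaf order); micro-cluster members inherit
    their leaf's label.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, _h) in enumerate(tree.merges[: n - k]):
        node = n + t
        parent[find(a)] = node
        parent[find(b)] = node

    labels: dict[str, int] = {}
    root_label: dict[int, int] = {}
    for leaf, (_cid, members) in enumerate(tree.leaves):
        root = find(leaf)
        lab = root_label.setdefault(root, len(root_label))
        for m in members:
            labels[m] = lab
    return labels


# ---------------------------------------------------------------------------
# K-medoids baseline
# ---------------------------------------------------------------------------

def kmedoids_cluster(items, K: int, distance: str = "hamming", seed: int = 0,
                     max_iter: int = 100, model_set: ModelSet | None = None,
                     trace_atom: str = "CA") -> ClusterSolution:
    """PAM-style k-medoids with seeded random initial medoids.

    Works with any of the metric kernels (no coordinate mean is required,
    so RMSD and Hamming distances are handled uniformly); deterministic for
    a fixed seed.
    """
    if isinstance(items, ProfileSet):
        ids = items.ids
        if distance == "rmsd":
            D = _centroid_distance_matrix(ids, "rmsd", items, model_set, trace_atom)
        else:
            D = pairwise_hamming_matrix(items.matrix())
    elif isinstance(items, ModelSet):
        ids = items.ids
        D = _centroid_distance_matrix(ids, "rmsd", None, items, trace_atom)
    else:
        vectors = list(items)
        ids = [v.model_id for v in vectors]
        V = np.stack([v.counts / np.linalg.norm(v.counts) for v in vectors])
        D = 1.0 - np.clip(V @ V.T, -1.0, 1.0)
        np.fill_diagonal(D, 0.0)
    N = len(ids)
    if K > N:
        raise ValueError(f"K={K} exceeds N={N}")

    # farthest-point initialisation from a seeded random start: robust to
    # duplicate items (purely random medoids can coincide and strand a
    # cluster), deterministic for a fixed seed
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(N))]
    while len(medoids) < K:
        mind = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(mind)))
    medoids = np.asarray(medoids)

    def _assign(meds: np.ndarray) -> np.ndarray:
        a = np.argmin(D[:, meds], axis=1)
        a[meds] = np.arange(len(meds))  # a medoid belongs to its own cluster
        return a

    assign = _assign(medoids)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(K):
            members = np.flatnonzero(assign == c)
            if len(members) == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[int(np.argmin(within))]
        new_assign = _assign(new_medoids)
        if np.array_equal(new_assign, assign) and np.array_equal(new_medoids, medoids):
            break
        medoids, assign = new_medoids, new_assign

    clusters = []
    for c in range(K):
        members = [ids[i] for i in np.flatnonzero(assign == c)]
        if members:
            clusters.append((members, ids[medoids[c]]))
    return ClusterSolution(clusters=clusters, coverage=100.0, unassigned=[])


# ---------------------------------------------------------------------------
# Evaluation utilities
# ---------------------------------------------------------------------------

def rand_index(labels_a, labels_b) -> float:
    """Fraction of item pairs on which two partitions agree (co-clustered
    in both or separated in both)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and equal length")
    n = len(a)
    if n < 2:
        return 1.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)
    sum_sq = (contingency.astype(np.float64) ** 2).sum()
    sum_a = (contingency.sum(axis=1).astype(np.float64) ** 2).sum()
    sum_b = (contingency.sum(axis=0).astype(np.float64) ** 2).sum()
    total = n * (n - 1) / 2.0
    same_both = (sum_sq - n) / 2.0
    same_a = (sum_a - n) / 2.0
    same_b = (sum_b - n) / 2.0
    disagreements = (same_a - same_both) + (same_b - same_both)
    return float((total - disagreements) / total)


def evaluate_selection(solution, quality: dict[str, float], mode: str,
                       top_n: int = 5, gap: float = 0.2) -> dict:
    """Model-quality evaluation of a selection.

    For cluster solutions the selection is the centroids of the ``top_n``
    largest clusters; for jury results it is the single top-ranked model.
    ``maxsub_gap`` flags the selection good when its best quality is within
    ``gap`` of the best quality in the whole set; ``rmsd_to_native``
    reports the minimum quality value (RMSD to the native structure) over
    the selected centroids.
    """
    if isinstance(solution, JuryResult):
        selected = [solution.ranking[0]]
    elif isinstance(solution, ClusterSolution):
        order = sorted(range(len(solution.clusters)),
                       key=lambda c: -len(solution.clusters[c][0]))
        selected = [solution.clusters[c][1] for c in order[:top_n]]
    else:
        raise TypeError("solution must be a ClusterSolution or JuryResult")
    missing = [s for s in selected if s not in quality]
    if missing:
        raise KeyError(f"no quality value for model(s): {', '.join(missing)}")
    values = [quality[s] for s in selected]
    record = {"selected": selected, "mode": mode}
    if mode == "maxsub_gap":
        best_overall = max(quality.values())
        best_selected = max(values)
        record.update(best_selected=best_selected, best_overall=best_overall,
                      good=bool(best_selected >= best_overall - gap))
    elif mode == "rmsd_to_native":
        record.update(min_rmsd=min(values))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return record


def write_clusters(solution: ClusterSolution, path: str, header: str | None = None) -> None:
    """Write the cluster TSV: model_id, cluster_id, is_centroid."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("model_id\tcluster_id\tis_centroid\n")
        for c, (members, centroid) in enumerate(solution.clusters):
            for m in members:
                fh.write(f"{m}\t{c}\t{1 if m == centroid else 0}\n")
        for m in solution.unassigned:
            fh.write(f"{m}\t-1\t0\n")
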