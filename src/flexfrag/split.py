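"""Conformation-blocked train/test splits via two-step RMSD clustering.

Blocking reduces the conformational overlap between the train and test sets
of every class so that good test performance demonstrates shape abstraction
rather than memorization.  Per class the recipe is:

1. cap at 5,000 randomly chosen samples and compute the pairwise
   heavy-atom RMSD matrix (optimal rigid superposition);
2. leader (Butina) clustering at a threshold of 75% of the mean
   off-diagonal RMSD;
3. clusters sorted by size; samples of the bottom 25% of the cluster list
   go exclusively to the test set;
4. remaining clusters with more than 30 samples: 2D stochastic-neighbor
   embedding of the RMSD sub-matrix, agglomerative clustering into 10
   subclusters, up to 10 random picks per subcluster ordered by parent
   subcluster size; the first 2/3 of that list are train candidates
   (<= 10 kept per cluster), the last 1/3 test candidates (<= 5 kept);
5. remaining small clusters: random 2:1 split of at most 15 samples;
   everything unselected is marked excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.manifold import TSNE

from .geometry import kabsch_rmsd

__all__ = [
    "SplitParams",
    "SplitRecord",
    "superpose_rmsd",
    "pairwise_rmsd",
    "butina_cluster",
    "subcluster",
    "build_baseline_split",
    "random_split",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitParams:
    """Knobs of the blocking recipe (defaults are the standard protocol)."""

    sample_cap: int = 5000
    threshold_factor: float = 0.75
    bottom_fraction: float = 0.25
    large_cluster_gate: int = 30
    n_subclusters: int = 10
    max_train_per_cluster: int = 10
    max_test_per_cluster: int = 5
    small_cluster_take: int = 15
    tsne_perplexity: float = 30.0


@dataclass
class SplitRecord:
    """Per-sample split assignment with cluster provenance."""

    sample_id: int
    label: str
    assignment: str  # train | test | excluded
    cluster: int
    subcluster: int | None = None

    def to_dict(self):
        return asdict(self)


def superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD (A) over rigid-body superposition of paired atom sets."""
    return kabsch_rmsd(a, b)


def pairwise_rmsd(coords: np.ndarray, cap: int = 5000,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise superposition RMSD over a capped random subset.

    ``coords`` has shape (n, m, 3) with identical atom correspondence across
    samples (one class).  Returns ``(matrix, kept_indices)``; the matrix is
    symmetric with a zero diagonal.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("expected coordinates of shape (n, m, 3)")
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    if n > cap:
        kept = np.sort(rng.choice(n, size=cap, replace=False))
    else:
        kept = np.arange(n)
    sub = coords[kept]
    k = len(kept)
    # center once; the Kabsch RMSD uses centered covariances only
    centered = sub - sub.mean(axis=1, keepdims=True)
    norms = np.einsum("nij,nij->n", centered, centered)
    m = sub.shape[1]
    out = np.zeros((k, k))
    for i in range(k):
        ai = centered[i]
        h = np.einsum("ij,njk->nik", ai.T, centered[i + 1:])
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(u @ vt)
        s[:, -1] *= np.sign(det)
        msd = (norms[i] + norms[i + 1:] - 2.0 * s.sum(axis=1)) / m
        out[i, i + 1:] = out[i + 1:, i] = np.sqrt(np.maximum(msd, 0.0))
    return out, kept


def butina_cluster(dist: np.ndarray, threshold: float) -> list[list[int]]:
    """Leader-style (Butina) clustering on a distance matrix.

    Repeatedly picks the sample with the most unassigned neighbors within
    ``threshold`` as a centroid and assigns those neighbors to it.  Returns
    clusters sorted by decreasing size (ties: lower centroid index first);
    every sample appears in exactly one cluster.
    """
    dist = np.asarray(dist, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    within = dist <= threshold
    np.fill_diagonal(within, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))
        members = np.flatnonzero(within[centroid] & unassigned)
        cluster = [centroid] + [int(i) for i in members if i != centroid]
        for i in cluster:
            unassigned[i] = False
        clusters.append(sorted(cluster))
    clusters.sort(key=len, reverse=True)
    return clusters


def subcluster(dist_sub: np.ndarray, k: int = 10, seed: int = 0,
               perplexity: float = 30.0) -> np.ndarray:
    """Subdivide one cluster: 2D t-SNE on the RMSD sub-matrix + Ward linkage.

    Returns integer labels in [0, k).  Deterministic given ``seed``.
    """
    dist_sub = np.asarray(dist_sub, float)
    n = dist_sub.shape[0]
    if n <= k:
        raise ValueError(f"cluster of size {n} too small for {k} subclusters")
    perp = min(perplexity, (n - 1) / 3.0)
    emb = TSNE(n_components=2, metric="precomputed", init="random",
               random_state=seed, perplexity=perp).fit_transform(dist_sub)
    return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(emb)


def _take_small(rng, members, params):
    """Random 2:1 split of at most ``small_cluster_take`` samples."""
    members = list(members)
    take = min(len(members), params.small_cluster_take)
    picked = list(rng.choice(len(members), size=take, replace=False))
    n_train = min(params.max_train_per_cluster, (2 * take) // 3)
    train = [members[i] for i in picked[:n_train]]
    test = [members[i] for i in
            picked[n_train:n_train + params.max_test_per_cluster]]
    return train, test


def build_baseline_split(coords: np.ndarray, label: str = "",
                         seed: int = 0,
                         params: SplitParams = SplitParams(),
                         dist: np.ndarray | None = None) -> list[SplitRecord]:
    """Blocked split of one class of conformers; see the module docstring.

    ``coords``: (n, m, 3) heavy-atom coordinates in template order, or pass a
    precomputed distance matrix via ``dist`` (then ``coords`` may be the
    matrix size).  Degenerate all-identical classes (mean RMSD 0) fall back
    to the small-cluster 2:1 path with a warning.
    """
    rng = np.random.default_rng(seed)
    if dist is None:
        dist, kept = pairwise_rmsd(coords, cap=params.sample_cap, seed=seed)
    else:
        dist = np.asarray(dist, float)
        kept = np.arange(dist.shape[0])
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    off = dist[~np.eye(n, dtype=bool)]
    mean_rmsd = float(off.mean())
    records = {int(i): SplitRecord(int(i), label, "excluded", -1)
               for i in kept}

    if mean_rmsd <= 0.0:
        log.warning("class %s has zero conformational diversity; using the "
                    "small-cluster 2:1 path", label or "<unnamed>")
        train, test, = _take_small(rng, list(kept), params)
        for i in train:
            records[int(i)].assignment = "train"
            records[int(i)].cluster = 0
        for i in test:
            records[int(i)].assignment = "test"
            records[int(i)].cluster = 0
        for rec in records.values():
            rec.cluster = 0
        return list(records.values())

    threshold = params.threshold_factor * mean_rmsd
    clusters = butina_cluster(dist, threshold)
    n_bottom = int(len(clusters) * params.bottom_fraction)

    for ci, members in enumerate(clusters):
        global_members = [int(kept[i]) for i in members]
        for gi in global_members:
            records[gi].cluster = ci
        if n_bottom > 0 and ci >= len(clusters) - n_bottom:
            # low-likelihood conformations: exclusively test
            for gi in global_members:
                records[gi].assignment = "test"
            continue
        if len(members) > params.large_cluster_gate:
            local = np.asarray(members)
            labels = subcluster(dist[np.ix_(local, local)],
                                k=params.n_subclusters, seed=seed,
                                perplexity=params.tsne_perplexity)
            groups = []
            for g in range(params.n_subclusters):
                idx = local[labels == g]
                if len(idx):
                    groups.append(list(idx))
            groups.sort(key=len, reverse=True)
            selection = []  # (local index, subcluster rank)
            for rank, group in enumerate(groups):
                take = min(len(group), 10)
                picks = rng.choice(len(group), size=take, replace=False)
                selection.extend((group[p], rank) for p in picks)
            cut = (2 * len(selection)) // 3
            train_cand = selection[:cut]
            test_cand = selection[cut:]
            for li, sub in train_cand[:params.max_train_per_cluster]:
                records[int(kept[li])].assignment = "train"
                records[int(kept[li])].subcluster = sub
            for li, sub in test_cand[:params.max_test_per_cluster]:
                records[int(kept[li])].assignment = "test"
                records[int(kept[li])].subcluster = sub
        else:
            train, test = _take_small(rng, members, params)
            for li in train:
                records[int(kept[li])].assignment = "train"
            for li in test:
                records[int(kept[li])].assignment = "test"
    return list(records.values())


def random_split(n: int, n_train: int, n_test: int,
                 seed: int = 0) -> list[SplitRecord]:
    """Unblocked control: uniform random train/test assignment."""
    if n_train + n_test > n:
        raise ValueError("not enough samples for the requested split sizes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    records = []
    for pos, i in enumerate(order):
        if pos < n_train:
            a = "train"
        elif pos < n_train + n_test:
            a = "test"
        else:
            a = "excluded"
        records.append(SplitRecord(int(i), "", a, -1))
    records.sort(key=lambda r: r.sample_id)
    return records
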