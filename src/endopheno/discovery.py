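"""Unsupervised subgroup discovery.

The discovery chain: an RBF affinity over patients in the transformed
expression space, spectral clustering on the symmetric normalised Laplacian,
algorithm selection by partitional consistency (mean pairwise adjusted Rand
index across variations of each algorithm), gene-set sizing by bootstrap
cluster stability (mean best-match Jaccard, the clusterboot convention), and
selection of the number of subgroups k by majority voting over a registry of
internal validity indexes.

Conventions fixed here:

* RBF kernel ``A_ij = exp(-sigma * ||x_i - x_j||^2)`` (kernlab
  parameterisation); the automatic bandwidth takes ``sigma`` as the
  reciprocal of the median pairwise squared distance.
* Spectral embedding: top-k eigenvectors of ``D^{-1/2} A D^{-1/2}``,
  rows renormalised to unit length, partitioned by k-means with 25 restarts.
* Cluster labels are canonicalised to descending cluster size, 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .preprocess import ExpressionMatrix

__all__ = [
    "AffinityMatrix",
    "Partition",
    "StabilityResult",
    "KVoteResult",
    "rbf_affinity",
    "spectral_cluster",
    "adjusted_rand_index",
    "compare_algorithms",
    "select_stable_geneset",
    "internal_index",
    "INDEX_REGISTRY",
    "vote_k",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class AffinityMatrix:
    values: np.ndarray
    sample_ids: list[str]
    sigma: float

    def __post_init__(self) -> None:
        a = self.values
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("affinity matrix must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("affinity matrix must be symmetric")
        if (a < -1e-12).any() or (a > 1 + 1e-12).any():
            raise ValueError("affinities must lie in [0, 1]")


@dataclass
class Partition:
    """Sample -> subgroup labels, contiguous 1..k, canonical by cluster size."""

    labels: pd.Series  # index = sample ids, values = 1..k
    k: int
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_labels(cls, raw_labels, sample_ids, provenance=None) -> "Partition":
        """Canonicalise arbitrary labels: rank clusters by descending size
        (ties by first appearance) and relabel 1..k."""
        raw = np.asarray(raw_labels)
        uniq, counts = np.unique(raw, return_counts=True)
        first_pos = {u: int(np.argmax(raw == u)) for u in uniq}
        order = sorted(uniq, key=lambda u: (-counts[list(uniq).index(u)], first_pos[u]))
        remap = {u: i + 1 for i, u in enumerate(order)}
        labels = pd.Series([remap[u] for u in raw], index=list(sample_ids), dtype=int)
        return cls(labels=labels, k=len(uniq), provenance=provenance or {})

    def members(self, subgroup: int) -> list[str]:
        return list(self.labels.index[self.labels == subgroup])

    def as_array(self) -> np.ndarray:
        return self.labels.to_numpy()


@dataclass
class StabilityResult:
    per_size: dict[int, dict]  # size -> {"per_cluster": [...], "mean": float}
    n_bootstrap: int
    chosen_size: int


@dataclass
class KVoteResult:
    scores: dict[str, dict[int, float]]  # index -> k -> score
    votes: dict[str, int]  # index -> voted k
    tally: dict[int, int]
    majority_k: int


# ---------------------------------------------------------------------------
# affinity and spectral clustering


def _sample_coords(m: ExpressionMatrix) -> np.ndarray:
    return m.values.to_numpy().T  # samples x genes


def rbf_affinity(m: ExpressionMatrix, sigma: float | str = "auto") -> AffinityMatrix:
    """Radial-basis-function affinity between samples.

    ``sigma="auto"`` sets sigma = 1 / median pairwise squared distance, which
    puts the typical affinity at exp(-1).
    """
    x = _sample_coords(m)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in expression matrix")
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    if sigma == "auto":
        med = np.median(d2[np.triu_indices_from(d2, k=1)])
        sigma = 1.0 / med if med > 0 else 1.0
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = np.exp(-sigma * d2)
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(values=a, sample_ids=m.sample_ids, sigma=sigma)


def spectral_embedding(a: AffinityMatrix, k: int) -> np.ndarray:
    """Top-k eigenvectors of the normalised affinity, row-normalised."""
    n = a.values.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, {n}]")
    deg = a.values.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(deg)
    sym = d_isqrt[:, None] * a.values * d_isqrt[None, :]
    # eigh returns ascending eigenvalues; top-k of sym = bottom-k of L_sym
    vals, vecs = eigh(sym, subset_by_index=(n - k, n - 1))
    emb = vecs[:, ::-1]
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    return emb / norms[:, None]


def spectral_cluster(a: AffinityMatrix, k: int, seed: int = 0) -> Partition:
    """Normalised-Laplacian spectral clustering with seeded k-means (25 restarts)."""
    thresh = a.values > 1e-12
    n_comp, _ = connected_components(thresh, directed=False)
    if n_comp > k:
        warnings.warn(
            f"affinity graph has {n_comp} components but k={k}; clusters may merge components"
        )
    emb = spectral_embedding(a, k)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    raw = km.fit_predict(emb)
    return Partition.from_labels(
        raw, a.sample_ids, provenance={"algorithm": "spectral", "k": k, "seed": seed, "sigma": a.sigma}
    )


# ---------------------------------------------------------------------------
# adjusted Rand index


def adjusted_rand_index(p: Partition | np.ndarray, q: Partition | np.ndarray) -> float:
    """Chance-corrected partition agreement from the pair-counting contingency
    table: ``(sum_ij C(n_ij,2) - E) / (max - E)`` with
    ``E = sum_i C(a_i,2) sum_j C(b_j,2) / C(n,2)``.
    """
    la, lb = (x.as_array() if isinstance(x, Partition) else np.asarray(x) for x in (p, q))
    if isinstance(p, Partition) and isinstance(q, Partition):
        if list(p.labels.index) != list(q.labels.index):
            raise ValueError("partitions cover different sample sets")
    if la.shape != lb.shape:
        raise ValueError("label vectors differ in length")
    n = la.size
    ua, ia = np.unique(la, return_inverse=True)
    ub, ib = np.unique(lb, return_inverse=True)
    cont = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(cont, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# algorithm-consistency selection


def _run_variation(m: ExpressionMatrix, algorithm: str, k: int, variation: dict) -> Partition:
    x = _sample_coords(m)
    if algorithm == "spectral":
        a = rbf_affinity(m, sigma=variation.get("sigma", "auto"))
        return spectral_cluster(a, k, seed=variation.get("seed", 0))
    if algorithm == "kmeans":
        km = KMeans(n_clusters=k, n_init=variation.get("n_init", 10), random_state=variation.get("seed", 0))
        return Partition.from_labels(km.fit_predict(x), m.sample_ids, {"algorithm": "kmeans", **variation})
    if algorithm == "hierarchical":
        hc = AgglomerativeClustering(n_clusters=k, linkage=variation.get("linkage", "ward"))
        return Partition.from_labels(hc.fit_predict(x), m.sample_ids, {"algorithm": "hierarchical", **variation})
    raise ValueError(f"unknown algorithm {algorithm!r}")


DEFAULT_VARIATIONS = {
    "spectral": [{"sigma": "auto", "seed": s} for s in (0, 1, 2)]
    + [{"sigma": "scale:0.5", "seed": 0}, {"sigma": "scale:2.0", "seed": 0}],
    "kmeans": [{"seed": s, "n_init": 1} for s in range(5)],
    "hierarchical": [{"linkage": lk} for lk in ("ward", "complete", "average")],
}


def compare_algorithms(
    m: ExpressionMatrix, k: int, variations: dict[str, list[dict]] | None = None
) -> pd.DataFrame:
    """Mean/SD of pairwise ARI across each algorithm's variations.

    The most consistent algorithm (highest mean ARI, SD as tiebreak) is the
    one whose partitions are least sensitive to its own nuisance choices
    (kernel width, seed, linkage).
    """
    variations = variations or DEFAULT_VARIATIONS
    rows = []
    for algo, specs in variations.items():
        if len(specs) < 2:
            raise ValueError(f"algorithm {algo!r} needs >= 2 variations")
        parts = []
        for v in specs:
            v = dict(v)
            sig = v.get("sigma")
            if isinstance(sig, str) and sig.startswith("scale:"):
                base = rbf_affinity(m, "auto").sigma
                v["sigma"] = base * float(sig.split(":")[1])
            parts.append(_run_variation(m, algo, k, v))
        aris = [
            adjusted_rand_index(parts[i], parts[j])
            for i in range(len(parts))
            for j in range(i + 1, len(parts))
        ]
        rows.append({"algorithm": algo, "mean_ari": np.mean(aris), "sd_ari": np.std(aris, ddof=1) if len(aris) > 1 else 0.0, "n_pairs": len(aris)})
    out = pd.DataFrame(rows).set_index("algorithm")
    out["winner"] = False
    out.loc[out.sort_values(["mean_ari", "sd_ari"], ascending=[False, True]).index[0], "winner"] = True
    return out


# ---------------------------------------------------------------------------
# bootstrap stability gene-set sizing


def _bootstrap_jaccard(a_full: AffinityMatrix, base: Partition, k: int, n_boot: int, rng) -> list[float]:
    """clusterboot-style stability: recluster bootstrap resamples, match each
    original cluster to its best-Jaccard bootstrap cluster."""
    n = len(a_full.sample_ids)
    base_arr = base.as_array()
    per_cluster = np.zeros((n_boot, base.k))
    for b in range(n_boot):
        idx = np.unique(rng.integers(0, n, size=n))  # distinct resampled samples
        sub = AffinityMatrix(
            values=a_full.values[np.ix_(idx, idx)],
            sample_ids=[a_full.sample_ids[i] for i in idx],
            sigma=a_full.sigma,
        )
        bp = spectral_cluster(sub, k, seed=int(rng.integers(0, 2**31 - 1)))
        bp_arr = bp.as_array()
        for ci in range(1, base.k + 1):
            orig = set(np.nonzero(base_arr == ci)[0]) & set(idx.tolist())
            orig = {int(i) for i in orig}
            best = 0.0
            for cj in range(1, bp.k + 1):
                boot = {int(idx[i]) for i in np.nonzero(bp_arr == cj)[0]}
                inter = len(orig & boot)
                union = len(orig | boot)
                if union:
                    best = max(best, inter / union)
            per_cluster[b, ci - 1] = best
    return per_cluster.mean(axis=0).tolist()


def select_stable_geneset(
    m: ExpressionMatrix,
    sizes: list[int],
    k: int,
    n_boot: int = 100,
    seed: int = 0,
) -> StabilityResult:
    """Choose the variance-ranked gene-set size whose clustering is most
    stable under bootstrap resampling of samples (mean best-match Jaccard).

    Ties break toward the smallest size.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    from .preprocess import rank_genes_by_variability

    _, gene_sets = rank_genes_by_variability(m, sizes=sizes)
    rng = np.random.default_rng(seed)
    per_size: dict[int, dict] = {}
    for size, genes in zip(sizes, gene_sets):
        sub = m.subset_genes(genes)
        aff = rbf_affinity(sub, "auto")
        base = spectral_cluster(aff, k, seed=int(rng.integers(0, 2**31 - 1)))
        per_cluster = _bootstrap_jaccard(aff, base, k, n_boot, rng)
        per_size[size] = {"per_cluster": per_cluster, "mean": float(np.mean(per_cluster))}
    best = max(sorted(per_size), key=lambda s: (per_size[s]["mean"], -s))
    return StabilityResult(per_size=per_size, n_bootstrap=n_boot, chosen_size=best)


# ---------------------------------------------------------------------------
# internal validity indexes

# Each entry: (function(x, labels) -> float, orientation); orientation "max"
# means larger is better.  x is the samples x features embedding-space data.


def _pairwise(x):
    return squareform(pdist(x))


def _dunn_index(x, labels):
    d = _pairwise(x)
    uniq = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for i, a in enumerate(uniq):
        ia = labels == a
        da = d[np.ix_(ia, ia)]
        if da.size > 1:
            max_within = max(max_within, da.max())
        for b in uniq[i + 1:]:
            ib = labels == b
            min_between = min(min_between, d[np.ix_(ia, ib)].min())
    return min_between / max_within if max_within > 0 else np.inf


def _connectivity(x, labels, n_neighbors=10):
    """Sum over samples of 1/rank for nearest neighbours assigned to another
    cluster (lower = better-connected clusters)."""
    d = _pairwise(x)
    n = d.shape[0]
    nn = min(n_neighbors, n - 1)
    conn = 0.0
    for i in range(n):
        order = np.argsort(d[i])
        neighbours = [j for j in order if j != i][:nn]
        for r, j in enumerate(neighbours, start=1):
            if labels[j] != labels[i]:
                conn += 1.0 / r
    return conn


def _wss_bss(x, labels):
    centroid = x.mean(axis=0)
    wss = 0.0
    bss = 0.0
    for c in np.unique(labels):
        xc = x[labels == c]
        mu = xc.mean(axis=0)
        wss += ((xc - mu) ** 2).sum()
        bss += len(xc) * ((mu - centroid) ** 2).sum()
    return wss, bss


def _wb_ratio(x, labels):
    wss, bss = _wss_bss(x, labels)
    return wss / bss if bss > 0 else np.inf


def _pbm_index(x, labels):
    centroid = x.mean(axis=0)
    e_t = np.linalg.norm(x - centroid, axis=1).sum()
    e_w = 0.0
    centres = []
    for c in np.unique(labels):
        xc = x[labels == c]
        mu = xc.mean(axis=0)
        centres.append(mu)
        e_w += np.linalg.norm(xc - mu, axis=1).sum()
    centres = np.asarray(centres)
    d_b = _pairwise(centres).max() if len(centres) > 1 else 0.0
    k = len(centres)
    if e_w == 0:
        return np.inf
    return ((e_t / e_w) * d_b / k) ** 2


def _c_index(x, labels):
    d = _pairwise(x)
    iu = np.triu_indices_from(d, k=1)
    dists = d[iu]
    same = (labels[iu[0]] == labels[iu[1]])
    s_w = dists[same].sum()
    nw = int(same.sum())
    if nw == 0:
        return 0.0
    ds = np.sort(dists)
    s_min = ds[:nw].sum()
    s_max = ds[-nw:].sum()
    return (s_w - s_min) / (s_max - s_min) if s_max > s_min else 0.0


INDEX_REGISTRY: dict[str, tuple] = {
    "silhouette": (lambda x, l: silhouette_score(x, l), "max"),
    "calinski_harabasz": (lambda x, l: calinski_harabasz_score(x, l), "max"),
    "davies_bouldin": (lambda x, l: davies_bouldin_score(x, l), "min"),
    "dunn": (_dunn_index, "max"),
    "connectivity": (_connectivity, "min"),
    "wb_ratio": (_wb_ratio, "min"),
    "pbm": (_pbm_index, "max"),
    "c_index": (_c_index, "min"),
}


def internal_index(m: ExpressionMatrix | np.ndarray, p: Partition, index_name: str) -> float:
    """Evaluate one internal validity index on a partition (registry-based;
    orientation is documented per index in INDEX_REGISTRY)."""
    if index_name not in INDEX_REGISTRY:
        raise KeyError(f"unknown index {index_name!r}; known: {sorted(INDEX_REGISTRY)}")
    x = _sample_coords(m) if isinstance(m, ExpressionMatrix) else np.asarray(m)
    labels = p.as_array()
    if len(np.unique(labels)) < 2:
        raise ValueError(f"index {index_name!r} requires >= 2 clusters")
    fn, _ = INDEX_REGISTRY[index_name]
    return float(fn(x, labels))


def vote_k(
    m: ExpressionMatrix,
    candidate_ks: list[int],
    indexes: list[str] | None = None,
    seed: int = 0,
    sigma: float | str = "auto",
) -> KVoteResult:
    """Ensemble vote for the number of subgroups.

    Each index scores every candidate k on the spectral partition for that k
    and votes its own optimum (respecting orientation); the majority k wins,
    ties toward smaller k.  Indexes are evaluated in a shared spectral
    embedding of dimension max(candidate_ks) — the geometry the clusterings
    were actually made in — so scores are comparable across k.
    """
    if not candidate_ks:
        raise ValueError("no candidate ks")
    indexes = indexes or sorted(INDEX_REGISTRY)
    if len(indexes) < 1:
        raise ValueError("need at least one index")
    aff = rbf_affinity(m, sigma)
    x = spectral_embedding(aff, max(candidate_ks))
    parts = {k: spectral_cluster(aff, k, seed=seed + k) for k in sorted(candidate_ks)}
    scores: dict[str, dict[int, float]] = {name: {} for name in indexes}
    votes: dict[str, int] = {}
    for name in indexes:
        fn, orientation = INDEX_REGISTRY[name]
        for k, p in parts.items():
            scores[name][k] = float(fn(x, p.as_array()))
        ks = sorted(scores[name])
        vals = [scores[name][k] for k in ks]
        pick = ks[int(np.argmax(vals))] if orientation == "max" else ks[int(np.argmin(vals))]
        votes[name] = pick
    tally: dict[int, int] = {}
    for v in votes.values():
        tally[v] = tally.get(v, 0) + 1
    top = max(tally.values())
    majority = min(k for k, c in tally.items() if c == top)
    return KVoteResult(scores=scores, votes=votes, tally=tally, majority_k=majority)
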