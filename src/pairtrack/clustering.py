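"""Identity clustering in the learned representation space.

All embedded images of the video are clustered into N groups with k-means;
each image then receives a soft assignment probability that increases the
closer it is to a cluster center, and cluster quality is scored with the
mean Silhouette coefficient (1 = ideal clustering).  Fragments take the
identity preferred by their images, with temporally coexisting fragments
forced onto distinct identities by optimal one-to-one matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from .errors import DataInconsistencyError, InvalidInputError
from .fragments import FragmentGraph

__all__ = [
    "EmbeddingSpace",
    "kmeans_cluster",
    "assignment_probability",
    "mean_silhouette",
    "silhouette_by_cluster",
    "assign_identities",
    "build_embedding_space",
]


def kmeans_cluster(
    points: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Standard k-means (k-means++ init, ``n_init`` restarts, fixed seed).

    Degenerate inputs (fewer distinct points than k) are handled by
    scikit-learn's re-seeding of empty clusters; duplicate centers are
    allowed in that case.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise InvalidInputError("points must be a 2-D (n, M) array")
    n = points.shape[0]
    if k < 2 or n < k:
        raise InvalidInputError(f"need n >= k >= 2, got n={n}, k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**32))
    labels = km.fit_predict(points)
    return km.cluster_centers_, labels


def assignment_probability(
    point: np.ndarray, centers: np.ndarray, temperature: float
) -> np.ndarray:
    """Soft assignment over clusters: ``p_c ∝ exp(-||x - mu_c||^2 / tau)``.

    Strictly decreasing in the distance to each center; rows sum to 1.
    Accepts a single point or an (n, M) batch.
    """
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    point = np.atleast_2d(np.asarray(point, dtype=np.float64))
    d2 = np.square(point[:, None, :] - centers[None, :, :]).sum(axis=2)
    logits = -d2 / temperature
    logits -= logits.max(axis=1, keepdims=True)   # stable softmax
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if p.shape[0] == 1 else p


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean Silhouette coefficient, in [-1, 1].

    Per point: ``(b - a) / max(a, b)`` with ``a`` the mean intra-cluster
    distance and ``b`` the smallest mean distance to another cluster;
    singleton clusters score 0 by convention.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("silhouette needs at least two clusters")
    return float(silhouette_score(points, labels))


def silhouette_by_cluster(points: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    """Mean Silhouette plus a per-cluster-label mean, for sampling priorities."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InvalidInputError("silhouette needs at least two clusters")
    s = silhouette_samples(points, labels)
    per_cluster = {int(c): float(s[labels == c].mean()) for c in np.unique(labels)}
    return float(s.mean()), per_cluster


@dataclass
class EmbeddingSpace:
    """Embedded images of the video with their clustering.

    ``image_refs`` maps each row of ``points`` back to its source image as
    ``(fragment_id, frame_index)``.
    """

    points: np.ndarray                  # (n, M)
    image_refs: list                    # [(fragment_id, frame), ...]
    centers: np.ndarray = None          # (k, M)
    labels: np.ndarray = None           # (n,)
    probabilities: np.ndarray = None    # (n, k)
    mean_silhouette: float = float("nan")
    temperature: float = float("nan")

    @property
    def n_clusters(self) -> int:
        return 0 if self.centers is None else self.centers.shape[0]


def build_embedding_space(
    graph: FragmentGraph,
    net,
    n_clusters: int,
    seed: int = 0,
    *,
    n_init: int = 10,
    silhouette_cap: int = 8000,
    batch_size: int = 4096,
) -> EmbeddingSpace:
    """Embed every fragment image, cluster with k-means, attach probabilities.

    The temperature of the soft assignment is data-driven: the mean
    within-cluster squared distance to the assigned center.  The Silhouette
    is computed on a seeded subsample of at most ``silhouette_cap`` points
    (the full statistic is quadratic in n).
    """
    refs, stacks = [], []
    for frag in graph.fragments:
        stacks.append(frag.image_stack())
        refs.extend(
            (frag.fragment_id, frag.start_frame + i) for i in range(frag.n_images)
        )
    if not stacks:
        raise InvalidInputError("no fragment images to embed")
    images = np.concatenate(stacks)
    points = np.concatenate(
        [net.embed(images[i:i + batch_size]) for i in range(0, len(images), batch_size)]
    )
    centers, labels = kmeans_cluster(points, n_clusters, seed=seed, n_init=n_init)

    within = np.square(points - centers[labels]).sum(axis=1)
    tau = float(max(within.mean(), 1e-6))
    probabilities = assignment_probability(points, centers, tau)
    probabilities = np.atleast_2d(probabilities)

    rng = np.random.default_rng(seed)
    if len(points) > silhouette_cap:
        idx = rng.choice(len(points), size=silhouette_cap, replace=False)
        s = mean_silhouette(points[idx], labels[idx])
    else:
        s = mean_silhouette(points, labels)

    return EmbeddingSpace(
        points=points,
        image_refs=refs,
        centers=centers,
        labels=labels,
        probabilities=probabilities,
        mean_silhouette=s,
        temperature=tau,
    )


def assign_identities(graph: FragmentGraph, space: EmbeddingSpace) -> dict:
    """Assign one identity (cluster index) per fragment, exclusively per frame.

    Each fragment's preferred identity is the argmax of the mean per-image
    assignment probability of its images; its confidence is that mean.
    Fragments that coexist must carry distinct identities: within every set
    of mutually coexisting fragments the assignment maximizing the summed
    confidence is chosen (optimal one-to-one matching), with earlier-fixed
    fragments constraining later cliques.

    Returns ``{fragment_id: (identity, confidence)}`` and writes the result
    onto the fragments.
    """
    k = space.n_clusters
    # mean probability row per fragment
    frag_rows: dict[int, np.ndarray] = {}
    ref_fids = np.array([fid for fid, _ in space.image_refs])
    for frag in graph.fragments:
        mask = ref_fids == frag.fragment_id
        if not mask.any():
            continue
        frag_rows[frag.fragment_id] = space.probabilities[mask].mean(axis=0)

    assigned: dict[int, int] = {}
    out: dict[int, tuple[int, float]] = {}

    # sweep over elementary intervals: every alive set is a coexistence clique
    frags = [f for f in graph.fragments if f.fragment_id in frag_rows]
    boundaries = sorted({f.start_frame for f in frags} | {f.end_frame for f in frags})
    for left, right in zip(boundaries[:-1], boundaries[1:]):
        alive = [f for f in frags if f.start_frame <= left and f.end_frame >= right]
        if not alive:
            continue
        if len(alive) > graph.n_animals:
            raise DataInconsistencyError(
                f"{len(alive)} fragments coexist in frames [{left}, {right}) "
                f"but only {graph.n_animals} animals are declared"
            )
        fixed_ids = {assigned[f.fragment_id] for f in alive if f.fragment_id in assigned}
        free = [f for f in alive if f.fragment_id not in assigned]
        if not free:
            continue
        avail = [c for c in range(k) if c not in fixed_ids]
        if len(avail) < len(free):
            raise DataInconsistencyError(
                "more coexisting fragments than available identities"
            )
        cost = np.array(
            [[-frag_rows[f.fragment_id][c] for c in avail] for f in free]
        )
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            fid = free[r].fragment_id
            assigned[fid] = avail[c]

    for frag in frags:
        identity = assigned[frag.fragment_id]
        confidence = float(frag_rows[frag.fragment_id][identity])
        frag.identity = identity
        frag.confidence = confidence
        frag.cluster = identity
        out[frag.fragment_id] = (identity, confidence)
    return out
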