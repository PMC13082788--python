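"""Label-free positive/negative pair mining from the fragment graph.

The video's temporal structure supplies supervision without identity
labels: two images from the *same* individual fragment show the same animal
(positive pair), and images from two fragments that *coexist in time* show
different animals (negative pair) — two fragments alive in the same frame
cannot be the same individual.

Batches mix a baseline distribution (fragments weighted by image count)
with a priority distribution that up-weights fragments whose current
cluster has a poor Silhouette score, so training focuses on identities that
are still fuzzy while every fragment keeps a non-zero sampling floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientConnectivityError, InvalidInputError
from .fragments import Fragment, FragmentGraph, coexist

__all__ = [
    "PairBatch",
    "SamplingWeights",
    "sample_positive_pair",
    "sample_negative_pair",
    "make_batch",
]


@dataclass
class PairBatch:
    """Index-level batch: pairs reference (fragment_id, image_index)."""

    positives: list   # [((fid, i), (fid, j)), ...] same fragment, i != j
    negatives: list   # [((fid_a, i), (fid_b, j)), ...] coexisting fragments

    @property
    def images_total(self) -> int:
        return 2 * (len(self.positives) + len(self.negatives))


@dataclass
class SamplingWeights:
    """Mixture of baseline (fragment-size) and cluster-priority weights.

    ``mix_fraction`` is the probability mass drawn from the baseline
    distribution; ``1 - mix_fraction`` comes from cluster priority.  Until a
    clustering exists (``cluster_silhouettes`` is None) only the baseline is
    used.
    """

    fragment_ids: list
    baseline: np.ndarray
    mix_fraction: float = 0.5
    cluster_silhouettes: dict | None = None   # cluster label -> mean s
    fragment_clusters: dict | None = None     # fragment_id -> cluster label

    @classmethod
    def from_graph(
        cls,
        graph: FragmentGraph,
        *,
        min_fragment_length: int = 3,
        mix_fraction: float = 0.5,
    ) -> "SamplingWeights":
        eligible = [
            f for f in graph.fragments
            if f.n_images >= max(2, min_fragment_length)
        ]
        if not eligible:
            raise InsufficientConnectivityError(
                "no fragment is long enough for pair mining"
            )
        counts = np.array([f.n_images for f in eligible], dtype=float)
        return cls(
            fragment_ids=[f.fragment_id for f in eligible],
            baseline=counts / counts.sum(),
            mix_fraction=mix_fraction,
        )

    def update_priorities(self, fragment_clusters: dict, cluster_silhouettes: dict) -> None:
        self.fragment_clusters = dict(fragment_clusters)
        self.cluster_silhouettes = dict(cluster_silhouettes)

    def fragment_distribution(self) -> np.ndarray:
        """Effective per-fragment sampling probabilities (sums to 1)."""
        if self.cluster_silhouettes is None or self.fragment_clusters is None:
            return self.baseline
        priority = np.array(
            [
                max(0.0, 1.0 - self.cluster_silhouettes.get(
                    self.fragment_clusters.get(fid, -1), 1.0))
                for fid in self.fragment_ids
            ]
        )
        if priority.sum() <= 0:
            return self.baseline
        priority = priority / priority.sum()
        beta = self.mix_fraction
        mixed = beta * self.baseline + (1.0 - beta) * priority
        return mixed / mixed.sum()


def sample_positive_pair(fragment: Fragment, rng: np.random.Generator) -> tuple[int, int]:
    """Two distinct image indices from one fragment (same unknown identity)."""
    if fragment.n_images < 2:
        raise InvalidInputError("positive pairs need a fragment with >= 2 images")
    i, j = rng.choice(fragment.n_images, size=2, replace=False)
    return int(i), int(j)


def sample_negative_pair(
    a: Fragment, b: Fragment, rng: np.random.Generator
) -> tuple[int, int]:
    """One image index from each of two coexisting fragments.

    Coexistence is the only label-free guarantee that the two images show
    different animals, so non-coexisting fragments are a contract violation.
    """
    if not coexist(a, b):
        raise InvalidInputError(
            f"fragments {a.fragment_id} and {b.fragment_id} do not coexist; "
            "a negative pair is only guaranteed cross-identity for coexisting fragments"
        )
    return int(rng.integers(a.n_images)), int(rng.integers(b.n_images))


def make_batch(
    graph: FragmentGraph,
    weights: SamplingWeights,
    n_pos: int,
    n_neg: int,
    rng: np.random.Generator,
) -> PairBatch:
    """Compose a training batch of ``n_pos`` positive and ``n_neg`` negative pairs.

    Fragment selection follows the mixed baseline/priority distribution;
    each negative pair picks its second fragment uniformly among the first
    fragment's coexisting partners (restricted to eligible fragments).
    """
    eligible = set(weights.fragment_ids)
    partners = {
        fid: [n for n in graph.neighbors(fid) if n in eligible]
        for fid in weights.fragment_ids
    }
    connected = [fid for fid, p in partners.items() if p]
    if not connected:
        raise InsufficientConnectivityError(
            "no coexisting fragment pair available for negative mining"
        )
    dist = weights.fragment_distribution()

    pos_fids = rng.choice(weights.fragment_ids, size=n_pos, p=dist)
    positives = []
    for fid in pos_fids:
        frag = graph.by_id(int(fid))
        i, j = sample_positive_pair(frag, rng)
        positives.append(((frag.fragment_id, i), (frag.fragment_id, j)))

    # renormalise the distribution over fragments that have partners
    mask = np.array([fid in set(connected) for fid in weights.fragment_ids])
    neg_dist = dist * mask
    neg_dist = neg_dist / neg_dist.sum() if neg_dist.sum() > 0 else mask / mask.sum()
    neg_fids = rng.choice(weights.fragment_ids, size=n_neg, p=neg_dist)
    negatives = []
    for fid in neg_fids:
        a = graph.by_id(int(fid))
        b = graph.by_id(int(rng.choice(partners[int(fid)])))
        i, j = sample_negative_pair(a, b, rng)
        negatives.append(((a.fragment_id, i), (b.fragment_id, j)))

    return PairBatch(positives=positives, negatives=negatives)
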