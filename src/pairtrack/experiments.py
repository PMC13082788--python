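"""Reproducible benchmark protocols on synthetic videos.

:func:`tracking_experiment` runs the full pipeline on a generated video and
reports the quantities the method is judged by: the mean Silhouette at
which training stopped, the per-image identification error against ground
truth under the best cluster-to-identity bijection, and IDF1 with and
without crossings.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import TrackingConfig
from .evaluate import idf1
from .model import ContrastiveTracker
from .synthetic import GeneratorConfig, generate_dataset

__all__ = ["per_image_error", "tracking_experiment"]


def per_image_error(space, graph) -> tuple[float, int]:
    """Fraction of individual images misassigned under the best bijection.

    Compares raw k-means labels of every embedded image against the
    generator's ground-truth identity, maximizing agreement over all
    cluster-to-identity bijections (Hungarian on the contingency table).
    Returns (error fraction, number of images).
    """
    frag = {f.fragment_id: f for f in graph.fragments}
    true = np.array(
        [
            frag[fid].blobs[frame - frag[fid].start_frame].true_identity
            for fid, frame in space.image_refs
        ]
    )
    if np.any(true == None):  # noqa: E711 - object array check
        raise ValueError("ground-truth identities missing on the blobs")
    labels = space.labels
    k = space.n_clusters
    n_ids = int(true.max()) + 1
    contingency = np.zeros((k, n_ids), dtype=np.int64)
    for c, g in zip(labels, true.astype(int)):
        contingency[c, g] += 1
    rows, cols = linear_sum_assignment(-contingency)
    correct = int(contingency[rows, cols].sum())
    n = len(labels)
    return 1.0 - correct / n, n


def tracking_experiment(
    seed: int,
    n_animals: int = 8,
    n_frames: int = 3000,
    separability: float = 0.9,
    config: TrackingConfig | None = None,
) -> dict:
    """Generate, track, and score one synthetic video.

    All randomness derives from ``seed``.  Returns a dict with the stop
    reason, training-time and final Silhouette, per-image error (percent),
    the number of images scored, and IDF1 with/without crossings.
    """
    gen_cfg = GeneratorConfig(
        n_animals=n_animals,
        n_frames=n_frames,
        separability=separability,
        seed=seed,
    )
    dataset = generate_dataset(gen_cfg)
    if config is None:
        config = TrackingConfig(n_animals=n_animals)
    tracker = ContrastiveTracker.from_dataset(dataset, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = tracker.fit(seed=seed)
    error, n_images = per_image_error(results.space, tracker.graph)
    radius = config.match_radius or gen_cfg.body_radius
    scores = {
        label: idf1(
            results.trajectories,
            dataset.positions,
            match_radius=radius,
            include_crossings=include,
            gt_crossing_mask=dataset.in_crossing,
        ).idf1
        for label, include in (("idf1_excl", False), ("idf1_incl", True))
    }
    return {
        "stop_reason": results.history.stop_reason,
        "silhouette_at_stop": results.history.silhouettes[-1][1]
        if results.history.silhouettes else float("nan"),
        "mean_silhouette": results.mean_silhouette,
        "error_percent": 100.0 * error,
        "n_images": n_images,
        "estimated_accuracy": results.estimated_accuracy,
        "connectivity": tracker.graph.connectivity,
        **scores,
    }
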