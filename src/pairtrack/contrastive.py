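"""Double-margin contrastive training of the image embedding.

For an image pair with embedding distance ``d`` the squared-hinge loss is

    positive pair:  max(0, d - D_pos)^2
    negative pair:  max(0, D_neg - d)^2

so positive pairs are pulled together until they are within ``D_pos`` of
each other (preventing collapse of a fragment to a single point) and
negative pairs are pushed apart until they are ``D_neg`` apart (preventing
unbounded scatter).  Defaults ``D_pos = 1`` and ``D_neg = 10`` (ratio 10).

Training stops when the mean Silhouette score of a k-means clustering of a
fixed evaluation subsample reaches the stopping criterion (default 0.91) on
two consecutive evaluations, or at ``max_batches``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import TrackingConfig
from .errors import InvalidInputError
from .network import EmbeddingNetwork
from .pairs import SamplingWeights, make_batch

__all__ = ["contrastive_loss", "TrainingHistory", "train"]


def contrastive_loss(d: float | np.ndarray, is_positive: bool, cfg: TrackingConfig) -> float | np.ndarray:
    """Squared-hinge contrastive loss for a pair at embedding distance ``d``.

    Zero exactly when the margin is satisfied: ``d <= D_pos`` for positive
    pairs, ``d >= D_neg`` for negative pairs.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise InvalidInputError("pair distance must be finite and non-negative")
    if is_positive:
        out = np.square(np.maximum(0.0, d - cfg.d_pos))
    else:
        out = np.square(np.maximum(0.0, cfg.d_neg - d))
    return float(out) if out.ndim == 0 else out


@dataclass
class TrainingHistory:
    losses: list = field(default_factory=list)            # per-batch mean loss
    silhouettes: list = field(default_factory=list)       # (batch, mean s)
    stop_reason: str = "max_batches"

    @property
    def n_batches(self) -> int:
        return len(self.losses)


def _gather(frag_images: dict, refs: list) -> np.ndarray:
    return np.stack([frag_images[fid][i] for fid, i in refs])


def train(
    graph,
    config: TrackingConfig,
    seed: int | None = None,
    *,
    log_fn=None,
) -> tuple[EmbeddingNetwork, TrainingHistory]:
    """Train the embedding on pairs mined from ``graph``.

    Every ``config.eval_every`` batches a fixed subsample of images is
    embedded, clustered with k-means (k = N), and scored with the mean
    Silhouette; per-cluster Silhouettes feed back into the pair-sampling
    priorities.  Returns the trained network and the training history with
    ``stop_reason`` set to ``"silhouette_reached"`` or ``"max_batches"``.
    """
    from .clustering import kmeans_cluster, silhouette_by_cluster

    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    weights = SamplingWeights.from_graph(
        graph,
        min_fragment_length=config.min_fragment_length,
        mix_fraction=config.priority_mix,
    )
    frag_images = {
        fid: graph.by_id(fid).image_stack() for fid in weights.fragment_ids
    }

    net = EmbeddingNetwork(
        input_side=config.crop_size,
        output_dim=config.embedding_dim,
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        seed=int(rng.integers(2**31 - 1)),
    )

    # fixed evaluation subsample: (fragment_id, image_index) references
    all_refs = [
        (fid, i) for fid in weights.fragment_ids
        for i in range(frag_images[fid].shape[0])
    ]
    n_eval = min(config.silhouette_subsample, len(all_refs))
    eval_idx = rng.choice(len(all_refs), size=n_eval, replace=False)
    eval_refs = [all_refs[i] for i in eval_idx]
    eval_images = _gather(frag_images, eval_refs)
    eval_fids = np.array([fid for fid, _ in eval_refs])

    history = TrainingHistory()
    consecutive_hits = 0

    for step in range(config.max_batches):
        batch = make_batch(
            graph, weights, config.n_pos_pairs, config.n_neg_pairs, rng
        )
        refs1 = [p[0] for p in batch.positives] + [p[0] for p in batch.negatives]
        refs2 = [p[1] for p in batch.positives] + [p[1] for p in batch.negatives]
        z1, acts1 = net.forward(_gather(frag_images, refs1))
        z2, acts2 = net.forward(_gather(frag_images, refs2))

        diff = z1 - z2
        dist = np.sqrt(np.sum(np.square(diff), axis=1) + 1e-12)
        n_pos = len(batch.positives)
        n_pairs = len(refs1)
        hinge = np.empty(n_pairs, dtype=np.float32)
        hinge[:n_pos] = np.maximum(0.0, dist[:n_pos] - config.d_pos)
        hinge[n_pos:] = np.maximum(0.0, config.d_neg - dist[n_pos:])
        loss = float(np.mean(np.square(hinge)))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite contrastive loss at batch {step}; "
                "lower the learning rate or check the input images"
            )
        history.losses.append(loss)

        # d(loss)/d(z1): positive +2h * u, negative -2h * u, u = diff/dist
        sign = np.ones(n_pairs, dtype=np.float32)
        sign[n_pos:] = -1.0
        coeff = (2.0 * hinge * sign / (dist * n_pairs)).astype(np.float32)
        grad_z1 = coeff[:, None] * diff
        gw1, gb1 = net.backward(acts1, grad_z1)
        gw2, gb2 = net.backward(acts2, -grad_z1)
        net.adam_step(
            [a + b for a, b in zip(gw1, gw2)],
            [a + b for a, b in zip(gb1, gb2)],
        )

        if (step + 1) % config.eval_every == 0:
            points = net.embed(eval_images)
            _, labels = kmeans_cluster(
                points, config.n_animals,
                seed=int(rng.integers(2**31 - 1)),
                n_init=config.kmeans_restarts,
            )
            mean_s, per_cluster = silhouette_by_cluster(points, labels)
            history.silhouettes.append((step + 1, mean_s))
            # fragment -> majority cluster over its subsampled images
            frag_cluster = {}
            for fid in weights.fragment_ids:
                mask = eval_fids == fid
                if mask.any():
                    frag_cluster[fid] = int(np.bincount(labels[mask]).argmax())
            weights.update_priorities(frag_cluster, per_cluster)
            if log_fn is not None:
                log_fn({"batch": step + 1, "loss": loss, "silhouette": mean_s})
            if mean_s >= config.silhouette_stop:
                consecutive_hits += 1
                if consecutive_hits >= 2:
                    history.stop_reason = "silhouette_reached"
                    break
            else:
                consecutive_hits = 0

    return net, history
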