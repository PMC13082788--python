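"""Model-level API: :class:`ContrastiveTracker` and :class:`TrackingResults`.

The tracker is a model fitted to a video: ``fit()`` mines image pairs from
the fragment structure, trains the contrastive embedding until the
Silhouette stopping criterion, clusters the representation space into N
identities, and post-processes fragment identities into trajectories.  The
returned :class:`TrackingResults` carries the trajectories, the per-frame
assignment probabilities, the Silhouette score, the estimated accuracy and
diagnostics, with a ``summary()`` table in the spirit of statistical
modelling packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import EmbeddingSpace, assign_identities, build_embedding_space
from .config import TrackingConfig
from .contrastive import TrainingHistory, train
from .errors import InsufficientConnectivityError, InvalidInputError
from .fragments import FragmentGraph, build_fragments, find_global_fragments
from .postprocess import TrajectorySet, assemble_trajectories

__all__ = ["ContrastiveTracker", "TrackingResults", "LowConnectivityWarning"]


class LowConnectivityWarning(UserWarning):
    """Fragment connectivity below the warning threshold; accuracy may degrade."""


class ContrastiveTracker:
    """Tracking-by-identification model over a fragment graph.

    Parameters
    ----------
    blobs_per_frame:
        Per-frame blob lists (from :func:`pairtrack.blobs.segment_frame`,
        from a detection table, or from the synthetic generator).
    n_animals:
        Number N of animals in the video; also the number of identity
        clusters.
    config:
        Full pipeline configuration; defaults encode the published
        operating point.
    classify_blobs:
        Whether to run the area/overlap crossing classifier; disable for
        pre-classified tables.
    """

    def __init__(
        self,
        blobs_per_frame: list,
        n_animals: int,
        config: TrackingConfig | None = None,
        *,
        classify_blobs: bool = True,
    ) -> None:
        if config is None:
            config = TrackingConfig(n_animals=n_animals)
        elif config.n_animals != n_animals:
            raise InvalidInputError("config.n_animals disagrees with n_animals")
        self.config = config
        self.n_animals = n_animals
        self.graph: FragmentGraph = build_fragments(
            blobs_per_frame,
            n_animals,
            max_displacement=config.max_displacement,
            crossing_area_factor=config.crossing_area_factor,
            classify=classify_blobs,
            connectivity_warning=config.connectivity_warning,
        )

    @classmethod
    def from_dataset(cls, dataset, config: TrackingConfig | None = None) -> "ContrastiveTracker":
        """Build from a synthetic dataset (pre-classified blob table)."""
        if config is None:
            config = TrackingConfig(n_animals=dataset.n_animals)
        return cls(
            dataset.blobs_per_frame,
            dataset.n_animals,
            config,
            classify_blobs=False,
        )

    @classmethod
    def from_frames(
        cls, frames, n_animals: int, config: TrackingConfig | None = None,
        roi_mask=None, occlusion_mask=None,
    ) -> "ContrastiveTracker":
        """Segment an iterable of grayscale frames, then build the graph."""
        from .blobs import segment_frame

        if config is None:
            config = TrackingConfig(n_animals=n_animals)
        blobs_per_frame = [
            segment_frame(
                frame,
                config.intensity_threshold,
                roi_mask=roi_mask,
                occlusion_mask=occlusion_mask,
                min_blob_area=config.min_blob_area,
                crop_size=config.crop_size,
                frame_index=i,
            )
            for i, frame in enumerate(frames)
        ]
        return cls(blobs_per_frame, n_animals, config, classify_blobs=True)

    # ---------------------------------------------------------------------

    def connectivity_report(self) -> dict:
        g = self.graph
        globals_ = find_global_fragments(g)
        return {
            "n_fragments": len(g.fragments),
            "n_frames": g.n_frames,
            "connectivity": g.connectivity,
            "low_connectivity_warning": g.low_connectivity_warning,
            "n_global_fragments": len(globals_),
            "has_global_fragments": bool(globals_),
        }

    def fit(self, seed: int | None = None, log_fn=None) -> "TrackingResults":
        """Train, cluster, assign and post-process; return the results object."""
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        if not self.graph.fragments:
            raise InsufficientConnectivityError("no fragments detected in the video")
        if self.graph.low_connectivity_warning:
            warnings.warn(
                f"fragment connectivity {self.graph.connectivity:.3f} is below "
                f"{cfg.connectivity_warning}; identification accuracy may degrade",
                LowConnectivityWarning,
                stacklevel=2,
            )

        net, history = train(self.graph, cfg, seed=seed, log_fn=log_fn)
        rng = np.random.default_rng(seed + 101)
        space = build_embedding_space(
            self.graph,
            net,
            cfg.n_animals,
            seed=int(rng.integers(2**31 - 1)),
            n_init=cfg.kmeans_restarts,
            silhouette_cap=cfg.silhouette_final_cap,
        )
        identities = assign_identities(self.graph, space)
        estimated_accuracy = float(
            np.mean([space.probabilities[i].max() for i in range(len(space.points))])
        )
        trajectories = assemble_trajectories(
            self.graph,
            identities,
            jump_factor=cfg.jump_mad_factor,
            estimated_accuracy=estimated_accuracy,
            mean_silhouette=space.mean_silhouette,
        )
        return TrackingResults(
            model=self,
            network=net,
            history=history,
            space=space,
            identities=identities,
            trajectories=trajectories,
            seed=seed,
        )


@dataclass
class TrackingResults:
    """Fitted tracking model: trajectories, probabilities and diagnostics."""

    model: ContrastiveTracker
    network: object
    history: TrainingHistory
    space: EmbeddingSpace
    identities: dict
    trajectories: TrajectorySet
    seed: int

    @property
    def mean_silhouette(self) -> float:
        return self.space.mean_silhouette

    @property
    def estimated_accuracy(self) -> float:
        return self.trajectories.estimated_accuracy

    @property
    def connectivity(self) -> float:
        return self.model.graph.connectivity

    def cluster_report(self) -> dict:
        labels = self.space.labels
        sizes = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
        return {
            "n_clusters": self.space.n_clusters,
            "cluster_sizes": sizes,
            "mean_silhouette": self.mean_silhouette,
            "temperature": self.space.temperature,
        }

    def fragment_table(self):
        import pandas as pd

        rows = [
            (
                f.fragment_id, f.start_frame, f.end_frame, f.n_images,
                f.identity, round(f.confidence, 6),
            )
            for f in self.model.graph.fragments
        ]
        return pd.DataFrame(
            rows,
            columns=["fragment_id", "start", "end", "n_images", "identity", "confidence"],
        )

    def summary(self) -> str:
        g = self.model.graph
        h = self.history
        last_s = h.silhouettes[-1][1] if h.silhouettes else float("nan")
        lines = [
            "                    Contrastive Tracking Results",
            "=" * 66,
            f"No. animals (N):         {self.model.n_animals:>8}",
            f"No. frames:              {g.n_frames:>8}",
            f"No. fragments:           {len(g.fragments):>8}",
            f"No. crossing events:     {len(g.crossing_runs):>8}",
            f"Fragment connectivity:   {g.connectivity:>8.3f}"
            + ("   [LOW-CONNECTIVITY WARNING]" if g.low_connectivity_warning else ""),
            f"Global fragments:        {len(find_global_fragments(g)):>8}",
            "-" * 66,
            f"Training batches:        {h.n_batches:>8}",
            f"Stop reason:             {h.stop_reason:>18}",
            f"Silhouette (training):   {last_s:>8.3f}",
            f"Silhouette (final):      {self.mean_silhouette:>8.3f}",
            f"Estimated accuracy:      {self.estimated_accuracy:>8.4f}",
            "=" * 66,
        ]
        return "\n".join(lines)

    def plot_trajectories(self, ax=None):
        """Trajectory overview plot; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        for i in range(self.trajectories.n_animals):
            xy = self.trajectories.positions[i]
            ax.plot(xy[:, 0], xy[:, 1], lw=0.8, label=f"id {i}")
        ax.set_aspect("equal")
        ax.invert_yaxis()
        ax.set_xlabel("x [px]")
        ax.set_ylabel("y [px]")
        ax.legend(fontsize=7, ncol=2)
        return ax
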