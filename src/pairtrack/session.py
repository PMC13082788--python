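"""On-disk session layout and dataset IO.

A *dataset directory* (written by ``pairtrack generate``) holds:
``detections.csv`` (frame, x, y, area, kind, crop_index), ``crops.npz``
(the image crops referenced by index), ``groundtruth.csv``
(frame, id, x, y, in_crossing) and ``config.toml``.

A *session directory* (written by ``pairtrack track``) holds
``config.toml``, ``fragments.csv``, ``model.npz``, ``cluster_report.json``,
``trajectories.csv``, ``trajectories.h5``, ``metrics.json`` and
``log.jsonl``.  Re-running with the same config and seed reproduces
``metrics.json`` on a fixed device; every warning appears both on stderr
and in the metrics file.
"""

from __future__ import annotations

import json
import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .blobs import Blob, CROSSING, INDIVIDUAL
from .config import TrackingConfig
from .errors import InvalidInputError
from .evaluate import idf1
from .model import ContrastiveTracker
from .postprocess import TrajectorySet
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

__all__ = [
    "write_dataset", "load_dataset_blobs", "load_groundtruth",
    "read_frame_directory", "read_mask_png", "write_frames_png",
    "run_generate", "run_track", "run_evaluate",
]


def read_frame_directory(frames_dir: Path):
    """Grayscale frames from a directory of PNG/TIFF files, sorted by name.

    Returns a list of float32 arrays scaled to [0, 1].
    """
    import imageio.v3 as iio

    frames_dir = Path(frames_dir)
    paths = sorted(
        p for p in frames_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise InvalidInputError(f"no PNG/TIFF frames in {frames_dir}")
    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = img.mean(axis=2)
        if img.dtype.kind in "ui":
            img = img.astype(np.float32) / np.iinfo(img.dtype).max
        frames.append(img.astype(np.float32))
    return frames


def read_mask_png(path: Path) -> np.ndarray:
    """Binary mask from a PNG: nonzero pixels are True."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(Path(path))) > 0


def write_frames_png(dataset: SyntheticDataset, out_dir: Path) -> Path:
    """Rasterise and save every frame of a synthetic dataset as PNG."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = len(str(dataset.n_frames - 1))
    for ti, frame in dataset.render_frames():
        iio.imwrite(
            out_dir / f"frame_{ti:0{width}d}.png",
            (frame * 255).astype(np.uint8),
        )
    return out_dir


def write_dataset(dataset: SyntheticDataset, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, crops = [], []
    for frame_blobs in dataset.blobs_per_frame:
        for b in frame_blobs:
            rows.append(
                (
                    b.frame_index, b.centroid[0], b.centroid[1], b.pixel_count,
                    b.kind, len(crops),
                    -1 if b.true_identity is None else b.true_identity,
                )
            )
            crops.append(b.crop.astype(np.float16))
    pd.DataFrame(
        rows, columns=["frame", "x", "y", "area", "kind", "crop_index", "true_identity"]
    ).to_csv(out_dir / "detections.csv", index=False)
    np.savez_compressed(out_dir / "crops.npz", crops=np.stack(crops))
    dataset.groundtruth_dataframe().to_csv(out_dir / "groundtruth.csv", index=False)
    (out_dir / "config.toml").write_text(dataset.config.to_toml())
    return out_dir


def load_dataset_blobs(dataset_dir: Path) -> tuple[list, int]:
    """Detection table -> per-frame blob lists; returns (blobs, n_frames)."""
    dataset_dir = Path(dataset_dir)
    det_path = dataset_dir / "detections.csv"
    if not det_path.exists():
        raise InvalidInputError(f"no detections.csv in {dataset_dir}")
    table = pd.read_csv(det_path)
    with np.load(dataset_dir / "crops.npz") as data:
        crops = data["crops"].astype(np.float32)
    n_frames = int(table["frame"].max()) + 1
    blobs_per_frame: list[list[Blob]] = [[] for _ in range(n_frames)]
    half = crops.shape[1] / 2.0
    for row in table.itertuples(index=False):
        blobs_per_frame[int(row.frame)].append(
            Blob(
                frame_index=int(row.frame),
                centroid=(float(row.x), float(row.y)),
                pixel_count=int(row.area),
                bounding_box=(
                    int(np.floor(row.x - half)), int(np.floor(row.y - half)),
                    int(np.ceil(row.x + half)) + 1, int(np.ceil(row.y + half)) + 1,
                ),
                crop=crops[int(row.crop_index)],
                kind=row.kind if row.kind in (INDIVIDUAL, CROSSING) else INDIVIDUAL,
                true_identity=None if row.true_identity < 0 else int(row.true_identity),
            )
        )
    return blobs_per_frame, n_frames


def load_groundtruth(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """groundtruth.csv -> ((N, T, 2) positions, (N, T) crossing mask)."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"ground-truth file {path} does not exist")
    gt = pd.read_csv(path)
    n = int(gt["id"].max()) + 1
    t = int(gt["frame"].max()) + 1
    positions = np.full((n, t, 2), np.nan)
    crossing = np.zeros((n, t), dtype=bool)
    positions[gt["id"], gt["frame"], 0] = gt["x"]
    positions[gt["id"], gt["frame"], 1] = gt["y"]
    crossing[gt["id"], gt["frame"]] = gt["in_crossing"].astype(bool)
    return positions, crossing


def run_generate(config_path: Path, out_dir: Path, seed: int | None = None) -> Path:
    cfg = GeneratorConfig.from_toml(Path(config_path))
    if seed is not None:
        cfg.seed = seed
    return write_dataset(generate_dataset(cfg), out_dir)


def run_track(
    config_path: Path | None,
    dataset_dir: Path,
    session_dir: Path,
    seed: int | None = None,
) -> dict:
    """Full pipeline on a dataset directory; writes the session layout."""
    if config_path is not None:
        config = TrackingConfig.from_toml(Path(config_path))
    else:
        config = TrackingConfig()
    if seed is not None:
        config.seed = seed
    blobs_per_frame, _ = load_dataset_blobs(dataset_dir)
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    log_path = session_dir / "log.jsonl"
    log_file = open(log_path, "w")

    def log_fn(record: dict) -> None:
        log_file.write(json.dumps(record) + "\n")

    captured: list[str] = []
    try:
        tracker = ContrastiveTracker(
            blobs_per_frame, config.n_animals, config, classify_blobs=False
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            results = tracker.fit(seed=config.seed, log_fn=log_fn)
        for w in caught:
            captured.append(str(w.message))
            print(f"warning: {w.message}", file=sys.stderr, flush=True)
    finally:
        log_file.close()

    (session_dir / "config.toml").write_text(config.to_toml())
    results.fragment_table().to_csv(session_dir / "fragments.csv", index=False)
    results.network.save(session_dir / "model.npz")
    (session_dir / "cluster_report.json").write_text(
        json.dumps(results.cluster_report(), indent=2)
    )
    results.trajectories.to_csv(session_dir / "trajectories.csv")
    results.trajectories.to_hdf5(session_dir / "trajectories.h5")
    metrics = {
        "seed": config.seed,
        "n_animals": config.n_animals,
        "n_frames": tracker.graph.n_frames,
        "n_fragments": len(tracker.graph.fragments),
        "connectivity": tracker.graph.connectivity,
        "estimated_accuracy": results.estimated_accuracy,
        "mean_silhouette": results.mean_silhouette,
        "training_batches": results.history.n_batches,
        "stop_reason": results.history.stop_reason,
        "warnings": captured,
    }
    (session_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    return metrics


def run_evaluate(session_dir: Path, groundtruth_path: Path, out_path: Path | None = None):
    """IDF1 of a tracked session against ground truth, with and without crossings."""
    session_dir = Path(session_dir)
    traj_path = session_dir / "trajectories.h5"
    if not traj_path.exists():
        raise InvalidInputError(f"no trajectories.h5 in {session_dir}")
    pred = TrajectorySet.from_hdf5(traj_path)
    gt_positions, gt_crossing = load_groundtruth(groundtruth_path)
    if pred.n_frames != gt_positions.shape[1]:
        raise InvalidInputError(
            f"frame-count mismatch: session has {pred.n_frames}, "
            f"ground truth has {gt_positions.shape[1]}"
        )
    config = TrackingConfig.from_toml(session_dir / "config.toml")
    radius = config.match_radius or 7.0
    rows = []
    for label, include in (("excluding_crossings", False), ("including_crossings", True)):
        r = idf1(
            pred, gt_positions, match_radius=radius,
            include_crossings=include, gt_crossing_mask=gt_crossing,
        )
        rows.append((label, r.idf1, r.idtp, r.idfp, r.idfn))
    table = pd.DataFrame(rows, columns=["variant", "idf1", "idtp", "idfp", "idfn"])
    if out_path is not None:
        table.to_csv(out_path, index=False)
    return table
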