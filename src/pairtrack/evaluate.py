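"""Tracking evaluation: IDF1 and the sector-occlusion experiment.

IDF1 = IDTP / (IDTP + 0.5 IDFP + 0.5 IDFN) under the single global
predicted-to-ground-truth identity bijection that maximizes IDTP, so a
consistent relabelling of predicted identities never changes the score.
Detections are matched per frame by greedy nearest neighbour within a
match radius.

The occlusion harness masks an angular sector of the arena — all
information inside the sector is discarded before tracking — and measures
how fragment connectivity, global-fragment existence and IDF1 degrade as
the sector widens.  Ground-truth positions inside the sector or within an
exclusion margin of its boundary are left out of the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InsufficientConnectivityError, InvalidInputError
from .postprocess import INTERPOLATED, MISSING, TrajectorySet

__all__ = [
    "IDF1Result",
    "OcclusionSpec",
    "idf1",
    "apply_sector_mask",
    "sector_mask_array",
    "points_in_sector",
    "distance_to_sector",
    "occlusion_experiment",
]


@dataclass
class IDF1Result:
    idf1: float
    idtp: int
    idfp: int
    idfn: int
    matching: dict   # predicted identity -> ground-truth identity

    def __post_init__(self) -> None:
        denom = self.idtp + 0.5 * self.idfp + 0.5 * self.idfn
        expected = self.idtp / denom if denom > 0 else 1.0
        assert abs(self.idf1 - expected) < 1e-9


def idf1(
    pred: TrajectorySet | np.ndarray,
    gt: TrajectorySet | np.ndarray,
    match_radius: float,
    include_crossings: bool = True,
    gt_crossing_mask: np.ndarray | None = None,
    gt_eval_mask: np.ndarray | None = None,
) -> IDF1Result:
    """Identification F1 between predicted and ground-truth trajectories.

    ``include_crossings=False`` drops interpolated predicted frames and
    ground-truth frames flagged in ``gt_crossing_mask`` from the counts.
    ``gt_eval_mask`` (N_gt, T) restricts which ground-truth entries are
    evaluated at all (used by the occlusion protocol); predicted detections
    matching an excluded ground-truth position are dropped alongside rather
    than counted as false positives.
    """
    pred_pos, pred_prov = _as_arrays(pred)
    gt_pos, gt_prov = _as_arrays(gt)
    if pred_pos.shape[1] != gt_pos.shape[1]:
        raise InvalidInputError("predicted and ground-truth frame counts differ")
    n_pred, t = pred_pos.shape[:2]
    n_gt = gt_pos.shape[0]

    pred_ok = ~np.isnan(pred_pos[:, :, 0]) & (pred_prov != MISSING)
    gt_ok = ~np.isnan(gt_pos[:, :, 0]) & (gt_prov != MISSING)
    gt_excluded = np.zeros_like(gt_ok)
    if not include_crossings:
        pred_ok &= pred_prov != INTERPOLATED
        if gt_crossing_mask is not None:
            # crossing images are excluded from the counts on both sides:
            # predictions near an excluded GT entry are absorbed, not FPs
            cross = gt_crossing_mask.astype(bool)
            gt_excluded |= gt_ok & cross
            gt_ok &= ~cross
    if gt_eval_mask is not None:
        gt_excluded |= gt_ok & ~gt_eval_mask.astype(bool)
        gt_ok &= gt_eval_mask.astype(bool)

    counts = np.zeros((n_pred, n_gt), dtype=np.int64)
    total_pred = 0
    total_gt = int(gt_ok.sum())
    for f in range(t):
        p_ids = np.flatnonzero(pred_ok[:, f])
        g_ids = np.flatnonzero(gt_ok[:, f])
        x_ids = np.flatnonzero(gt_excluded[:, f])
        n_p = p_ids.size
        if n_p == 0:
            continue
        # greedy nearest-neighbour matching within match_radius; excluded GT
        # entries participate so that predictions near them are absorbed
        # (dropped) instead of counted as false positives
        g_all = np.concatenate([g_ids, x_ids])
        n_absorbed = 0
        if g_all.size:
            d = np.linalg.norm(
                pred_pos[p_ids, f][:, None, :] - gt_pos[g_all, f][None, :, :],
                axis=2,
            )
            order = np.argsort(d, axis=None)
            used_p: set[int] = set()
            used_g: set[int] = set()
            for flat in order:
                pi, gi = divmod(int(flat), g_all.size)
                if d[pi, gi] > match_radius:
                    break
                if pi in used_p or gi in used_g:
                    continue
                used_p.add(pi)
                used_g.add(gi)
                if gi < g_ids.size:   # matched an evaluated GT entry
                    counts[p_ids[pi], g_ids[gi]] += 1
                else:                  # matched an excluded entry
                    n_absorbed += 1
        total_pred += n_p - n_absorbed

    rows, cols = linear_sum_assignment(-counts)
    idtp_matrix = counts
    matching = {int(r): int(c) for r, c in zip(rows, cols) if idtp_matrix[r, c] > 0}
    idtp = int(idtp_matrix[rows, cols].sum())
    idfp = total_pred - idtp
    idfn = total_gt - idtp
    denom = idtp + 0.5 * idfp + 0.5 * idfn
    score = idtp / denom if denom > 0 else 1.0
    return IDF1Result(idf1=score, idtp=idtp, idfp=idfp, idfn=idfn, matching=matching)


def _as_arrays(traj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(traj, TrajectorySet):
        return traj.positions, traj.provenance
    pos = np.asarray(traj, dtype=float)
    prov = np.where(np.isnan(pos[:, :, 0]), MISSING, 1).astype(np.int8)
    return pos, prov


@dataclass
class OcclusionSpec:
    """Angular sector occlusion mask.

    The sector spans polar angles ``[anchor_deg, anchor_deg + sector_angle)``
    around ``arena_center`` (degrees, x-axis reference, y down).
    """

    sector_angle: float                  # theta, degrees in [0, 360]
    arena_center: tuple[float, float]
    anchor_deg: float = 0.0
    exclusion_margin: float = 15.0       # px (75 for mouse-scale bodies)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sector_angle <= 360.0):
            raise InvalidInputError("sector angle must lie in [0, 360] degrees")


def points_in_sector(points: np.ndarray, spec: OcclusionSpec) -> np.ndarray:
    """Boolean mask: which (x, y) points fall inside the masked sector."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if spec.sector_angle <= 0:
        return np.zeros(points.shape[0], dtype=bool)
    if spec.sector_angle >= 360:
        return np.ones(points.shape[0], dtype=bool)
    rel = points - np.asarray(spec.arena_center)
    ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))
    ang = (ang - spec.anchor_deg) % 360.0
    return ang < spec.sector_angle


def distance_to_sector(points: np.ndarray, spec: OcclusionSpec) -> np.ndarray:
    """Euclidean distance from each point to the masked sector region.

    Points inside the sector have distance 0; outside, the distance to the
    nearer boundary ray (both rays start at the arena center).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if spec.sector_angle <= 0:
        return np.full(points.shape[0], np.inf)
    if spec.sector_angle >= 360:
        return np.zeros(points.shape[0])
    inside = points_in_sector(points, spec)
    rel = points - np.asarray(spec.arena_center)
    ray_dists = []
    for angle in (spec.anchor_deg, spec.anchor_deg + spec.sector_angle):
        u = np.array([np.cos(np.radians(angle)), np.sin(np.radians(angle))])
        proj = rel @ u
        d_ray = np.linalg.norm(rel - np.clip(proj, 0.0, None)[:, None] * u, axis=1)
        ray_dists.append(d_ray)
    out = np.minimum(*ray_dists)
    out[inside] = 0.0
    return out


def sector_mask_array(shape: tuple[int, int], spec: OcclusionSpec) -> np.ndarray:
    """H x W boolean occlusion mask (True = masked) for frame-level input."""
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    return points_in_sector(pts, spec).reshape(h, w)


def apply_sector_mask(blobs_per_frame: list, spec: OcclusionSpec) -> list:
    """Drop every blob whose centroid lies inside the masked sector.

    No information crosses the mask: blobs inside it vanish entirely, so
    fragments terminate at the mask edge and are never artificially
    bridged.  Works on the detection-table representation; frame-level
    masking goes through :func:`sector_mask_array` + segmentation.
    """
    out = []
    for frame_blobs in blobs_per_frame:
        if not frame_blobs:
            out.append([])
            continue
        centroids = np.array([b.centroid for b in frame_blobs])
        hidden = points_in_sector(centroids, spec)
        out.append([b for b, h in zip(frame_blobs, hidden) if not h])
    return out


def occlusion_experiment(
    dataset,
    theta_grid,
    config=None,
    seed: int = 0,
    anchor_deg: float = 0.0,
    exclusion_margin: float | None = None,
):
    """Track the dataset under a sweep of sector occlusions.

    Returns a DataFrame with one row per theta: fragment connectivity,
    global-fragment existence, and IDF1 (excluding and including
    crossings) evaluated only on ground-truth positions outside the mask
    and farther than the exclusion margin from its boundary.  Runs where
    tracking is impossible (no coexisting fragments) report NaN scores.
    """
    import pandas as pd

    from .config import TrackingConfig
    from .fragments import build_fragments, find_global_fragments
    from .model import ContrastiveTracker

    cfg = config if config is not None else TrackingConfig(n_animals=dataset.n_animals)
    margin = cfg.exclusion_margin if exclusion_margin is None else exclusion_margin
    center = dataset.config.arena_center
    match_radius = cfg.match_radius or dataset.config.body_radius

    rows = []
    for theta in theta_grid:
        spec = OcclusionSpec(
            sector_angle=float(theta),
            arena_center=center,
            anchor_deg=anchor_deg,
            exclusion_margin=margin,
        )
        masked = apply_sector_mask(dataset.blobs_per_frame, spec)
        graph = build_fragments(
            masked, dataset.n_animals,
            max_displacement=cfg.max_displacement,
            classify=False,
            connectivity_warning=cfg.connectivity_warning,
        )
        has_globals = bool(find_global_fragments(graph)) if graph.fragments else False
        connectivity = graph.connectivity if graph.fragments else 0.0

        flat = dataset.positions.reshape(-1, 2)
        keep = (distance_to_sector(flat, spec) > margin).reshape(
            dataset.positions.shape[:2]
        )
        row = {
            "theta": float(theta),
            "connectivity": connectivity,
            "has_global_fragments": has_globals,
            "low_connectivity_warning": bool(
                graph.fragments and graph.low_connectivity_warning
            ),
            "idf1_excl": float("nan"),
            "idf1_incl": float("nan"),
        }
        try:
            tracker = ContrastiveTracker(
                masked, dataset.n_animals, cfg, classify_blobs=False
            )
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res = tracker.fit(seed=seed)
            for label, include in (("idf1_excl", False), ("idf1_incl", True)):
                row[label] = idf1(
                    res.trajectories,
                    dataset.positions,
                    match_radius=match_radius,
                    include_crossings=include,
                    gt_crossing_mask=dataset.in_crossing,
                    gt_eval_mask=keep,
                ).idf1
        except (InsufficientConnectivityError, InvalidInputError):
            pass
        rows.append(row)
    return pd.DataFrame(rows)
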