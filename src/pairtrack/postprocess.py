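"""From per-fragment identities to per-frame trajectories.

Three deterministic corrections follow identity assignment: (1) every image
of a fragment inherits the fragment-level identity (single-image
misassignments are overwritten); (2) impossible abrupt changes in location
— displacements far beyond the identity's robust speed scale — mark the
offending fragment as unreliable, reverting it to missing or re-assigning
it; (3) positions during crossings are filled by linear interpolation
between the identity's last detection before and first detection after the
crossing.  No extrapolation: an identity present on only one side of a gap
stays missing there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .fragments import CrossingRun, FragmentGraph

__all__ = [
    "MISSING", "DETECTED", "INTERPOLATED",
    "TrajectorySet",
    "enforce_fragment_identity",
    "correct_impossible_jumps",
    "interpolate_crossings",
    "assemble_trajectories",
]

MISSING, DETECTED, INTERPOLATED = 0, 1, 2
_PROVENANCE_NAMES = {MISSING: "missing", DETECTED: "detected", INTERPOLATED: "interpolated"}


@dataclass
class TrajectorySet:
    """N x T trajectory container.

    ``positions`` is (N, T, 2) in pixels with NaN for missing entries;
    ``probabilities`` (N, T) holds the per-frame assignment probability
    (0 where missing); ``provenance`` (N, T) is 0=missing, 1=detected,
    2=interpolated.
    """

    positions: np.ndarray
    probabilities: np.ndarray
    provenance: np.ndarray
    estimated_accuracy: float = float("nan")
    mean_silhouette: float = float("nan")
    fragment_map: np.ndarray | None = None   # (N, T) fragment id or -1
    corrections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, t, two = self.positions.shape
        if two != 2 or self.probabilities.shape != (n, t) or self.provenance.shape != (n, t):
            raise InvalidInputError("inconsistent trajectory array shapes")

    @property
    def n_animals(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            positions=self.positions.copy(),
            probabilities=self.probabilities.copy(),
            provenance=self.provenance.copy(),
            estimated_accuracy=self.estimated_accuracy,
            mean_silhouette=self.mean_silhouette,
            fragment_map=None if self.fragment_map is None else self.fragment_map.copy(),
            corrections=dict(self.corrections),
        )

    # --- writers ---------------------------------------------------------

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i in range(self.n_animals):
            for t in range(self.n_frames):
                rows.append(
                    (
                        t, i,
                        self.positions[i, t, 0], self.positions[i, t, 1],
                        self.probabilities[i, t],
                        _PROVENANCE_NAMES[int(self.provenance[i, t])],
                    )
                )
        return pd.DataFrame(rows, columns=["frame", "id", "x", "y", "probability", "provenance"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path, extra_metadata: dict | None = None) -> None:
        import h5py

        meta = {
            "n_animals": self.n_animals,
            "n_frames": self.n_frames,
            "estimated_accuracy": self.estimated_accuracy,
            "mean_silhouette": self.mean_silhouette,
        }
        if extra_metadata:
            meta.update(extra_metadata)
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f.create_dataset("probabilities", data=self.probabilities)
            f.create_dataset("provenance", data=self.provenance)
            f.attrs["metadata"] = json.dumps(meta, default=float)

    @classmethod
    def from_hdf5(cls, path) -> "TrajectorySet":
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            return cls(
                positions=f["positions"][()],
                probabilities=f["probabilities"][()],
                provenance=f["provenance"][()],
                estimated_accuracy=meta.get("estimated_accuracy", float("nan")),
                mean_silhouette=meta.get("mean_silhouette", float("nan")),
            )


def enforce_fragment_identity(
    fragment_identity: int, per_image_identities: np.ndarray
) -> tuple[np.ndarray, int]:
    """Overwrite per-image identities with the fragment-level identity.

    All images between two crossings show the same animal, so any per-image
    disagreement is a misidentification; returns the corrected identities
    and the number of corrections made.
    """
    per_image = np.asarray(per_image_identities)
    corrections = int(np.sum(per_image != fragment_identity))
    return np.full_like(per_image, fragment_identity), corrections


def _identity_jumps(
    positions_row: np.ndarray, factor: float
) -> tuple[np.ndarray, float]:
    """Frames at which the per-frame speed of one identity is impossible.

    Speed at a transition is displacement divided by the frame gap; the
    gate is ``median + factor * MAD`` over all of the identity's speeds.
    Returns (array of arrival frames flagged, threshold).
    """
    det = np.flatnonzero(~np.isnan(positions_row[:, 0]))
    if det.size < 3:
        return np.empty(0, dtype=int), float("inf")
    deltas = np.diff(positions_row[det], axis=0)
    gaps = np.diff(det)
    speeds = np.hypot(deltas[:, 0], deltas[:, 1]) / gaps
    med = float(np.median(speeds))
    mad = float(np.median(np.abs(speeds - med)))
    threshold = med + factor * max(mad, 1e-9)
    flagged = det[1:][speeds > threshold]
    return flagged, threshold


def correct_impossible_jumps(
    traj: TrajectorySet,
    speed_threshold_factor: float = 4.0,
    graph: FragmentGraph | None = None,
) -> TrajectorySet:
    """Detect and repair impossible abrupt changes in location.

    A fragment whose first frame arrives with a speed above the robust gate
    (median + factor * MAD of that identity's speeds) is unreliable: its
    frames revert to missing and the fragment is re-assigned to the best
    non-conflicting identity — the one whose surrounding detections it
    joins with the smallest jump — when one exists.  Detected jump frames
    are recorded in ``corrections["jump_frames"]`` per identity.
    """
    out = traj.copy()
    jump_frames: dict[int, list[int]] = {}
    thresholds: dict[int, float] = {}
    for i in range(out.n_animals):
        flagged, thr = _identity_jumps(out.positions[i], speed_threshold_factor)
        jump_frames[i] = [int(f) for f in flagged]
        thresholds[i] = thr
    out.corrections["jump_frames"] = jump_frames

    if out.fragment_map is None:
        return out  # no fragment provenance: detection only

    # fragments whose first frame is a flagged arrival are unreliable
    unreliable: list[tuple[int, int]] = []   # (identity, fragment_id)
    for i, frames in jump_frames.items():
        for f in frames:
            fid = int(out.fragment_map[i, f])
            if fid >= 0:
                span = np.flatnonzero(out.fragment_map[i] == fid)
                if span.size and span[0] == f:
                    unreliable.append((i, fid))
    unreliable = sorted(set(unreliable), key=lambda p: (p[0], p[1]))

    # phase 1: detach every unreliable fragment before re-assigning any,
    # so that mutually swapped fragments free each other's slots
    segments: list[tuple[int, int, np.ndarray, np.ndarray, np.ndarray]] = []
    for identity, fid in unreliable:
        span = np.flatnonzero(out.fragment_map[identity] == fid)
        if span.size == 0:
            continue
        seg_pos = out.positions[identity, span].copy()
        seg_prob = out.probabilities[identity, span].copy()
        out.positions[identity, span] = np.nan
        out.probabilities[identity, span] = 0.0
        out.provenance[identity, span] = MISSING
        out.fragment_map[identity, span] = -1
        segments.append((identity, fid, span, seg_pos, seg_prob))

    # phase 2: greedy re-assignment to the best non-conflicting identity
    moved: list[dict] = []
    for identity, fid, span, seg_pos, seg_prob in segments:
        best: tuple[float, int] | None = None
        for cand in range(out.n_animals):
            row = out.positions[cand]
            if np.any(~np.isnan(row[span, 0])):
                continue  # conflicting: candidate already present there
            before = np.flatnonzero(~np.isnan(row[: span[0], 0]))
            after_idx = np.flatnonzero(~np.isnan(row[span[-1] + 1:, 0]))
            speeds = []
            if before.size:
                f0 = before[-1]
                speeds.append(
                    float(np.hypot(*(seg_pos[0] - row[f0])) / (span[0] - f0))
                )
            if after_idx.size:
                f1 = span[-1] + 1 + after_idx[0]
                speeds.append(
                    float(np.hypot(*(row[f1] - seg_pos[-1])) / (f1 - span[-1]))
                )
            if not speeds:
                continue
            score = max(speeds)
            if score <= thresholds.get(cand, float("inf")) and (
                best is None or score < best[0]
            ):
                best = (score, cand)

        if best is not None:
            cand = best[1]
            out.positions[cand, span] = seg_pos
            out.probabilities[cand, span] = seg_prob
            out.provenance[cand, span] = DETECTED
            out.fragment_map[cand, span] = fid
            moved.append({"fragment": fid, "from": identity, "to": cand})
        else:
            moved.append({"fragment": fid, "from": identity, "to": None})
    out.corrections["reassigned_fragments"] = moved
    return out


def interpolate_crossings(
    traj: TrajectorySet, crossings: list[CrossingRun]
) -> TrajectorySet:
    """Fill positions during crossings by linear interpolation.

    A gap in an identity's trajectory is filled only when (a) the identity
    is detected immediately before and after the gap and (b) at least one
    crossing blob run overlaps the gap (the animal was inside a crossing,
    not absent).  Interpolated probabilities inherit the minimum of the two
    anchors.
    """
    out = traj.copy()
    runs = [(r.start_frame, r.end_frame) for r in crossings]
    for i in range(out.n_animals):
        det = np.flatnonzero(out.provenance[i] != MISSING)
        if det.size < 2:
            continue
        for f0, f1 in zip(det[:-1], det[1:]):
            if f1 - f0 <= 1:
                continue
            gap = (int(f0) + 1, int(f1))
            if not any(s < gap[1] and e > gap[0] for s, e in runs):
                continue
            p0 = out.positions[i, f0]
            p1 = out.positions[i, f1]
            for t in range(*gap):
                w = (t - f0) / (f1 - f0)
                out.positions[i, t] = (1 - w) * p0 + w * p1
                out.probabilities[i, t] = min(
                    out.probabilities[i, f0], out.probabilities[i, f1]
                )
                out.provenance[i, t] = INTERPOLATED
    return out


def assemble_trajectories(
    graph: FragmentGraph,
    identities: dict,
    n_frames: int | None = None,
    *,
    jump_factor: float = 4.0,
    estimated_accuracy: float = float("nan"),
    mean_silhouette: float = float("nan"),
) -> TrajectorySet:
    """Build the final trajectory set from assigned fragments.

    Detected positions come from blob centroids grouped by identity; then
    impossible jumps are corrected and crossings interpolated.
    ``identities`` maps fragment_id -> (identity, confidence).
    """
    n = graph.n_animals
    t_total = n_frames if n_frames is not None else graph.n_frames
    positions = np.full((n, t_total, 2), np.nan)
    probabilities = np.zeros((n, t_total))
    provenance = np.zeros((n, t_total), dtype=np.int8)
    fragment_map = np.full((n, t_total), -1, dtype=np.int64)

    for frag in graph.fragments:
        if frag.fragment_id not in identities:
            continue
        identity, confidence = identities[frag.fragment_id]
        sl = slice(frag.start_frame, frag.end_frame)
        positions[identity, sl] = frag.positions()
        probabilities[identity, sl] = confidence
        provenance[identity, sl] = DETECTED
        fragment_map[identity, sl] = frag.fragment_id

    traj = TrajectorySet(
        positions=positions,
        probabilities=probabilities,
        provenance=provenance,
        estimated_accuracy=estimated_accuracy,
        mean_silhouette=mean_silhouette,
        fragment_map=fragment_map,
    )
    traj = correct_impossible_jumps(traj, jump_factor, graph)
    traj = interpolate_crossings(traj, graph.crossing_runs)
    traj.estimated_accuracy = estimated_accuracy
    traj.mean_silhouette = mean_silhouette
    return traj
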