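"""Ground-truthed synthetic multi-animal videos.

Animals are discs with identity-specific procedural textures performing
smooth correlated random walks in a circular arena, reflecting at the wall.
When two animals come within ``crossing_distance`` their blobs merge into a
crossing blob, exactly the event that breaks individual fragments in real
videos.  ``separability`` in [0, 1] scales how different the identity
textures are: 0 makes identities indistinguishable in expectation, 1 makes
each animal's texture fully its own.

The generator emits both rasterised frames (for the segmentation layer)
and a pre-segmented blob table (to bypass segmentation in fast tests), in
lock step with per-frame ground-truth identities.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .blobs import Blob, CROSSING, INDIVIDUAL
from .errors import InvalidConfigError, InvalidInputError

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate_trajectories", "render_dataset"]


@dataclass
class GeneratorConfig:
    n_animals: int = 8
    n_frames: int = 3000
    arena_radius: float = 120.0        # px
    body_radius: float = 7.0           # px
    crossing_distance: float | None = None   # default: 2 * body_radius
    separability: float = 0.9          # 0 = identical appearance, 1 = fully distinct
    pattern_contrast: float = 0.25
    base_intensity: float = 0.55
    speed_mean: float = 2.5            # px / frame
    speed_sd: float = 0.8
    turn_sd: float = 0.4               # radians / frame
    noise_sd: float = 0.03             # pixel-intensity noise
    centroid_jitter: float = 0.3       # detection-noise on centroids, px
    crop_size: int = 24
    margin: float = 10.0               # frame border beyond the arena, px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crossing_distance is None:
            self.crossing_distance = 2.0 * self.body_radius
        if self.n_animals < 2:
            raise InvalidConfigError("need at least two animals")
        if self.n_frames < 1:
            raise InvalidConfigError("need at least one frame")
        if not (0.0 <= self.separability <= 1.0):
            raise InvalidConfigError("separability must lie in [0, 1]")
        # packing check: animals must plausibly fit without permanent contact
        body_area = np.pi * self.body_radius**2
        if self.n_animals * body_area * 4 > np.pi * self.arena_radius**2:
            raise InvalidInputError(
                "arena too small for this many animals of this body size"
            )

    @property
    def arena_center(self) -> tuple[float, float]:
        s = self.arena_radius + self.margin
        return (s, s)

    @property
    def frame_shape(self) -> tuple[int, int]:
        side = int(np.ceil(2 * (self.arena_radius + self.margin)))
        return (side, side)

    def to_toml(self) -> str:
        lines = ["[generator]"]
        for key, value in dataclasses.asdict(self).items():
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            else:
                lines.append(f"{key} = {value!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, source: str | Path) -> "GeneratorConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        data = tomllib.loads(text)
        table = data.get("generator", data)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(table) - names
        if unknown:
            raise InvalidConfigError(f"unknown generator keys: {sorted(unknown)}")
        return cls(**table)


def generate_trajectories(cfg: GeneratorConfig):
    """Correlated random walks in the arena.

    Returns ``(positions, in_crossing)``: positions is (N, T, 2) in pixel
    coordinates, ``in_crossing`` a boolean (N, T) mask marking frames where
    an animal is within ``crossing_distance`` of another.  Deterministic
    given the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n, t = cfg.n_animals, cfg.n_frames
    cx, cy = cfg.arena_center
    r_max = cfg.arena_radius - cfg.body_radius

    # non-overlapping start positions by rejection
    pos = np.empty((n, 2))
    placed = 0
    for _ in range(10000):
        cand = (rng.uniform(-1, 1, 2)) * r_max
        if np.hypot(*cand) > r_max:
            continue
        cand = cand + (cx, cy)
        if placed and np.min(np.hypot(*(pos[:placed] - cand).T)) < cfg.crossing_distance:
            continue
        pos[placed] = cand
        placed += 1
        if placed == n:
            break
    if placed < n:
        raise InvalidInputError("could not place animals without contact; arena too small")

    heading = rng.uniform(0, 2 * np.pi, n)
    positions = np.empty((n, t, 2))
    positions[:, 0] = pos
    turns = rng.normal(0.0, cfg.turn_sd, (t, n))
    speeds = np.clip(rng.normal(cfg.speed_mean, cfg.speed_sd, (t, n)), 0.0, None)

    for ti in range(1, t):
        heading = heading + turns[ti]
        step = np.stack(
            [speeds[ti] * np.cos(heading), speeds[ti] * np.sin(heading)], axis=1
        )
        new = positions[:, ti - 1] + step
        # reflect at the arena wall
        rel = new - (cx, cy)
        r = np.hypot(rel[:, 0], rel[:, 1])
        outside = r > r_max
        if outside.any():
            nhat = rel[outside] / r[outside, None]
            new[outside] = (cx, cy) + nhat * (2 * r_max - r[outside])[:, None]
            v = step[outside]
            v_ref = v - 2 * (v * nhat).sum(axis=1, keepdims=True) * nhat
            heading[outside] = np.arctan2(v_ref[:, 1], v_ref[:, 0])
            rel2 = new[outside] - (cx, cy)
            r2 = np.hypot(rel2[:, 0], rel2[:, 1])
            big = r2 > r_max   # double bounce in a corner case: clamp
            if big.any():
                idx = np.flatnonzero(outside)[big]
                new[idx] = (cx, cy) + rel2[big] / r2[big, None] * (r_max * 0.98)
        positions[:, ti] = new

    # crossing mask from pairwise distances
    in_crossing = np.zeros((n, t), dtype=bool)
    for ti in range(t):
        p = positions[:, ti]
        d = np.hypot(*(p[:, None, :] - p[None, :, :]).transpose(2, 0, 1))
        close = (d < cfg.crossing_distance) & ~np.eye(n, dtype=bool)
        in_crossing[:, ti] = close.any(axis=1)
    return positions, in_crossing


def _smooth_field(rng: np.random.Generator, side: int) -> np.ndarray:
    """Zero-mean smooth random texture field on a side x side grid."""
    coarse = rng.standard_normal((6, 6))
    fine = ndimage.zoom(coarse, side / 6.0, order=1)
    fine = fine[:side, :side]
    fine -= fine.mean()
    scale = np.abs(fine).max()
    return fine / scale if scale > 0 else fine


def _contact_groups(points: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected groups of animals within contact distance (union-find)."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) < threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    positions: np.ndarray            # (N, T, 2) ground truth
    in_crossing: np.ndarray          # (N, T) bool
    blobs_per_frame: list            # pre-segmented detection table
    textures: np.ndarray             # (N, L, L) identity texture patches
    body_mask: np.ndarray            # (L, L) disc support

    @property
    def n_animals(self) -> int:
        return self.config.n_animals

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def groundtruth_dataframe(self):
        import pandas as pd

        n, t = self.positions.shape[:2]
        frames = np.tile(np.arange(t), n)
        ids = np.repeat(np.arange(n), t)
        return pd.DataFrame(
            {
                "frame": frames,
                "id": ids,
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "in_crossing": self.in_crossing.ravel().astype(int),
            }
        )

    def render_frames(self, frame_indices=None):
        """Yield (frame_index, H x W grayscale frame) with all animals drawn."""
        cfg = self.config
        h, w = cfg.frame_shape
        rng = np.random.default_rng(cfg.seed + 987654321)
        rr = int(np.ceil(cfg.body_radius))
        yy, xx = np.mgrid[-rr:rr + 1, -rr:rr + 1]
        disc = (xx**2 + yy**2) <= cfg.body_radius**2
        l_half = self.textures.shape[1] // 2
        if frame_indices is None:
            frame_indices = range(cfg.n_frames)
        for ti in frame_indices:
            frame = np.zeros((h, w), dtype=np.float32)
            for i in range(cfg.n_animals):
                x, y = self.positions[i, ti]
                cxi, cyi = int(round(x)), int(round(y))
                y0, x0 = cyi - rr, cxi - rr
                tex = self.textures[i][
                    l_half - rr:l_half + rr + 1, l_half - rr:l_half + rr + 1
                ]
                patch = frame[y0:y0 + disc.shape[0], x0:x0 + disc.shape[1]]
                np.maximum(patch, np.where(disc, tex, 0.0), out=patch)
            frame += rng.normal(0.0, cfg.noise_sd, frame.shape).astype(np.float32)
            yield ti, np.clip(frame, 0.0, 1.0)


def render_dataset(positions: np.ndarray, cfg: GeneratorConfig,
                   in_crossing: np.ndarray | None = None) -> SyntheticDataset:
    """Render the detection table (blobs with crops) for given trajectories.

    Individual blobs get the animal's identity texture plus fresh pixel
    noise and a small centroid jitter; contact groups of two or more
    animals merge into one crossing blob.  Ground-truth identities ride
    along on the blobs for evaluation only.
    """
    n, t = positions.shape[:2]
    if n != cfg.n_animals:
        raise InvalidInputError("positions do not match config n_animals")
    rng = np.random.default_rng(cfg.seed + 1)
    l_px = cfg.crop_size

    # identity textures: common field blended with per-identity fields
    common = _smooth_field(np.random.default_rng(cfg.seed + 2), l_px)
    textures = np.empty((n, l_px, l_px), dtype=np.float32)
    yy, xx = np.mgrid[:l_px, :l_px] - (l_px - 1) / 2.0
    body_mask = (xx**2 + yy**2) <= cfg.body_radius**2
    for i in range(n):
        own = _smooth_field(np.random.default_rng(cfg.seed + 10 + i), l_px)
        field = (1.0 - cfg.separability) * common + cfg.separability * own
        tex = cfg.base_intensity + cfg.pattern_contrast * field
        textures[i] = np.clip(np.where(body_mask, tex, 0.0), 0.05, 0.95)

    if in_crossing is None:
        in_crossing = np.zeros((n, t), dtype=bool)

    jitter = rng.normal(0.0, cfg.centroid_jitter, (n, t, 2))
    noise = rng.normal(0.0, cfg.noise_sd, (n, t, l_px, l_px)).astype(np.float32)
    body_area = int(body_mask.sum())
    half = l_px / 2.0

    blobs_per_frame: list[list[Blob]] = []
    for ti in range(t):
        frame_blobs: list[Blob] = []
        groups = _contact_groups(positions[:, ti], cfg.crossing_distance)
        for group in groups:
            if len(group) == 1:
                i = group[0]
                c = positions[i, ti] + jitter[i, ti]
                crop = np.clip(
                    np.where(body_mask, textures[i] + noise[i, ti], 0.0), 0.0, 1.0
                )
                frame_blobs.append(
                    Blob(
                        frame_index=ti,
                        centroid=(float(c[0]), float(c[1])),
                        pixel_count=body_area,
                        bounding_box=(
                            int(np.floor(c[0] - half)), int(np.floor(c[1] - half)),
                            int(np.ceil(c[0] + half)), int(np.ceil(c[1] + half)),
                        ),
                        crop=crop,
                        kind=INDIVIDUAL,
                        true_identity=i,
                    )
                )
            else:
                c = positions[group, ti].mean(axis=0)
                merged = np.clip(
                    np.where(
                        body_mask,
                        textures[group].mean(axis=0) + noise[group[0], ti],
                        0.0,
                    ),
                    0.0, 1.0,
                )
                frame_blobs.append(
                    Blob(
                        frame_index=ti,
                        centroid=(float(c[0]), float(c[1])),
                        pixel_count=int(body_area * 0.9 * len(group)),
                        bounding_box=(
                            int(np.floor(c[0] - half * len(group))),
                            int(np.floor(c[1] - half * len(group))),
                            int(np.ceil(c[0] + half * len(group))),
                            int(np.ceil(c[1] + half * len(group))),
                        ),
                        crop=merged,
                        kind=CROSSING,
                    )
                )
        blobs_per_frame.append(frame_blobs)

    return SyntheticDataset(
        config=cfg,
        positions=positions,
        in_crossing=in_crossing,
        blobs_per_frame=blobs_per_frame,
        textures=textures,
        body_mask=body_mask,
    )


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Trajectories plus rendered detection table in one call."""
    positions, in_crossing = generate_trajectories(cfg)
    return render_dataset(positions, cfg, in_crossing)
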