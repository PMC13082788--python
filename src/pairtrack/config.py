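"""Tracking configuration: every tunable of the pipeline in one place.

The defaults encode the published operating point of the method: an
eight-dimensional representation space, contrastive margins ``d_pos=1`` and
``d_neg=10`` (ratio 10), batches of 400 positive + 400 negative image pairs
(1600 images), a mean-Silhouette stopping criterion of 0.91, and a fragment
connectivity warning threshold of 0.5.

Configs round-trip through TOML: :func:`TrackingConfig.from_toml` /
:meth:`TrackingConfig.to_toml`.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidConfigError

__all__ = ["TrackingConfig"]


@dataclass
class TrackingConfig:
    # --- video structure / segmentation ---
    n_animals: int = 8
    intensity_threshold: float = 0.35
    min_blob_area: int = 10
    crop_size: int = 24                # side L of the square crops, pixels
    max_displacement: float = 15.0     # centroid-link fallback radius, px
    crossing_area_factor: float = 1.5  # area > factor * median => crossing
    min_fragment_length: int = 3       # frames; shorter fragments not mined

    # --- contrastive representation learning ---
    embedding_dim: int = 8             # M
    d_pos: float = 1.0
    d_neg: float = 10.0
    n_pos_pairs: int = 400
    n_neg_pairs: int = 400
    backbone: str = "mlp"              # compact numpy MLP backbone
    hidden_sizes: tuple[int, ...] = (128, 64)
    learning_rate: float = 1e-3
    max_batches: int = 4000
    eval_every: int = 50               # batches between Silhouette checks
    silhouette_stop: float = 0.91
    silhouette_subsample: int = 4000   # points for in-training Silhouette
    silhouette_final_cap: int = 8000   # cap for the end-of-run Silhouette
    priority_mix: float = 0.5          # beta: baseline fraction of sampling

    # --- clustering / assignment ---
    kmeans_restarts: int = 10

    # --- post-processing ---
    jump_mad_factor: float = 4.0       # median + factor*MAD speed gate

    # --- evaluation ---
    connectivity_warning: float = 0.5
    exclusion_margin: float = 15.0     # px from mask boundary (75 for mice)
    match_radius: float | None = None  # default: body length / 2 at eval

    # --- reproducibility ---
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        self.validate()

    def validate(self) -> None:
        if self.n_animals < 2:
            raise InvalidConfigError("tracking requires n_animals >= 2")
        if not (self.d_neg > self.d_pos > 0):
            raise InvalidConfigError("margins must satisfy d_neg > d_pos > 0")
        if not (0.0 <= self.priority_mix <= 1.0):
            raise InvalidConfigError("priority_mix must lie in [0, 1]")
        if self.n_pos_pairs < 1 or self.n_neg_pairs < 1:
            raise InvalidConfigError("batch must contain at least one pair of each sign")
        if not (-1.0 <= self.silhouette_stop <= 1.0):
            raise InvalidConfigError("silhouette_stop must lie in [-1, 1]")
        if self.crop_size < 4:
            raise InvalidConfigError("crop_size too small")

    @property
    def images_per_batch(self) -> int:
        """Total image slots per training batch (two per pair)."""
        return 2 * (self.n_pos_pairs + self.n_neg_pairs)

    # --- TOML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrackingConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("match_radius") == "none":
            d["match_radius"] = None
        return cls(**d)

    def to_toml(self) -> str:
        lines = ["[tracking]"]
        for key, value in self.to_dict().items():
            lines.append(f"{key} = {_toml_value(value)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, source: str | Path) -> "TrackingConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        try:
            data = tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise InvalidConfigError(f"malformed TOML: {exc}") from exc
        table = data.get("tracking", data)
        if not isinstance(table, dict):
            raise InvalidConfigError("expected a [tracking] table")
        return cls.from_dict(table)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if value is None:
        return '"none"'
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise InvalidConfigError(f"cannot serialize config value {value!r}")
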