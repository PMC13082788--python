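"""Shared fixtures: constructed blob/fragment helpers and a small fitted run."""

import numpy as np
import pytest

from pairtrack import (
    Blob,
    ContrastiveTracker,
    Fragment,
    FragmentGraph,
    GeneratorConfig,
    TrackingConfig,
    generate_dataset,
)

CROP_SIDE = 24


def make_blob(frame, x=10.0, y=10.0, area=50, kind="individual", crop=None,
              pixels=None, true_identity=None):
    if crop is None:
        crop = np.zeros((CROP_SIDE, CROP_SIDE), dtype=np.float32)
    half = max(5, int(np.ceil(np.sqrt(area))) // 2 + 1)
    return Blob(
        frame_index=frame,
        centroid=(x, y),
        pixel_count=area,
        bounding_box=(int(x) - half, int(y) - half, int(x) + half + 1, int(y) + half + 1),
        crop=crop,
        kind=kind,
        pixels=pixels,
        true_identity=true_identity,
    )


def make_fragment(fid, start, end, x=10.0, y=10.0, images=None):
    blobs = []
    for k, f in enumerate(range(start, end)):
        crop = None if images is None else images[k]
        blobs.append(make_blob(f, x=x, y=y, crop=crop))
    return Fragment(fragment_id=fid, start_frame=start, end_frame=end, blobs=blobs)


def graph_from_intervals(intervals, n_animals):
    """FragmentGraph from a list of (fid, start, end) tuples."""
    frags = [make_fragment(fid, s, e) for fid, s, e in intervals]
    n_frames = max(e for _, _, e in intervals)
    return FragmentGraph(fragments=frags, n_animals=n_animals, n_frames=n_frames)


@pytest.fixture(scope="session")
def small_dataset():
    """Separable 4-animal synthetic video, 600 frames."""
    return generate_dataset(GeneratorConfig(n_animals=4, n_frames=600, arena_radius=90.0, seed=3))


@pytest.fixture(scope="session")
def small_config():
    return TrackingConfig(n_animals=4, max_batches=600, eval_every=25)


@pytest.fixture(scope="session")
def fitted_results(small_dataset, small_config):
    """One fitted tracking run shared by the read-only tests."""
    tracker = ContrastiveTracker.from_dataset(small_dataset, small_config)
    return tracker.fit(seed=1)
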