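"""Fragments, global fragments and the coexistence graph.

An *individual fragment* is the maximal run of images of a single animal
between two crossings; it is the unit of pair mining and identity
assignment.  A *global fragment* is a set of N fragments that coexist in at
least one common frame.  *Fragment connectivity* — the mean number of other
fragments each fragment coexists with, divided by N-1 — predicts whether
the contrastive identification can succeed: below 0.5 accuracy is expected
to degrade, and the pipeline emits a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blobs import Blob, classify_blob
from .errors import InvalidInputError

__all__ = [
    "Fragment",
    "GlobalFragment",
    "CrossingRun",
    "FragmentGraph",
    "coexist",
    "build_fragments",
    "find_global_fragments",
    "fragment_connectivity",
]


@dataclass
class Fragment:
    """Maximal single-animal track between two crossings.

    Holds exactly one individual blob per frame of the half-open range
    ``[start_frame, end_frame)``.
    """

    fragment_id: int
    start_frame: int
    end_frame: int
    blobs: list[Blob]
    identity: int | None = None     # set by clustering assignment
    confidence: float = 0.0
    cluster: int | None = None      # most recent per-fragment cluster label

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise InvalidInputError("fragment frame range must be non-empty")
        if len(self.blobs) != self.end_frame - self.start_frame:
            raise InvalidInputError("fragment needs exactly one blob per frame")
        for offset, blob in enumerate(self.blobs):
            if blob.frame_index != self.start_frame + offset:
                raise InvalidInputError("fragment blobs out of frame order")
            if blob.is_crossing:
                raise InvalidInputError("fragments cannot contain crossing blobs")

    @property
    def n_images(self) -> int:
        return len(self.blobs)

    @property
    def images(self) -> list[np.ndarray]:
        return [b.crop for b in self.blobs]

    def image_stack(self) -> np.ndarray:
        return np.stack([b.crop for b in self.blobs]).astype(np.float32)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids."""
        return np.array([b.centroid for b in self.blobs], dtype=float)


@dataclass
class GlobalFragment:
    member_fragment_ids: frozenset
    common_frame_range: tuple[int, int]


@dataclass
class CrossingRun:
    """A temporally linked run of crossing blobs, with the fragments that
    entered it at its first frame and exited it at its last."""

    start_frame: int
    end_frame: int
    blobs: list[Blob]
    entering: list[int] = field(default_factory=list)
    exiting: list[int] = field(default_factory=list)


def coexist(a: Fragment, b: Fragment) -> bool:
    """True iff the two (distinct) fragments share at least one frame."""
    if a is b or a.fragment_id == b.fragment_id:
        raise InvalidInputError("coexistence is defined for distinct fragments")
    return a.start_frame < b.end_frame and b.start_frame < a.end_frame


@dataclass
class FragmentGraph:
    fragments: list[Fragment]
    n_animals: int
    crossing_runs: list[CrossingRun] = field(default_factory=list)
    n_frames: int = 0
    coexistence_edges: set = field(default_factory=set)
    connectivity: float = float("nan")
    low_connectivity_warning: bool = False

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise InvalidInputError("need at least two animals")
        if not self.coexistence_edges and self.fragments:
            self.coexistence_edges = _coexistence_edges(self.fragments)
        if self.fragments and np.isnan(self.connectivity):
            self.connectivity = fragment_connectivity(self)

    def by_id(self, fragment_id: int) -> Fragment:
        return self._index()[fragment_id]

    def _index(self) -> dict:
        if not hasattr(self, "_id_index"):
            self._id_index = {f.fragment_id: f for f in self.fragments}
        return self._id_index

    def _adjacency(self) -> dict:
        if not hasattr(self, "_adj"):
            adj: dict[int, list[int]] = {f.fragment_id: [] for f in self.fragments}
            for edge in self.coexistence_edges:
                a, b = tuple(edge)
                adj[a].append(b)
                adj[b].append(a)
            for v in adj.values():
                v.sort()
            self._adj = adj
        return self._adj

    def neighbors(self, fragment_id: int) -> list[int]:
        return self._adjacency()[fragment_id]

    def degree(self, fragment_id: int) -> int:
        return len(self._adjacency()[fragment_id])


def _coexistence_edges(fragments: list[Fragment]) -> set:
    """Sweep-line over fragment intervals; edge iff frame ranges overlap."""
    events = sorted(fragments, key=lambda f: f.start_frame)
    edges: set = set()
    active: list[Fragment] = []
    for frag in events:
        active = [a for a in active if a.end_frame > frag.start_frame]
        for other in active:
            edges.add(frozenset((other.fragment_id, frag.fragment_id)))
        active.append(frag)
    return edges


def fragment_connectivity(graph: FragmentGraph, warning_threshold: float | None = None) -> float:
    """Mean fragment degree divided by N-1.

    Values can exceed 1 when long fragments outlive several partner
    fragments in sequence; the diagnostically relevant regime is the low
    end, where too few coexisting fragments remain to mine negative pairs.
    Sets ``graph.low_connectivity_warning`` when a threshold is given and
    the value falls below it.
    """
    if not graph.fragments:
        raise InvalidInputError("connectivity is undefined without fragments")
    degrees = np.zeros(len(graph.fragments))
    idx = {f.fragment_id: i for i, f in enumerate(graph.fragments)}
    for edge in graph.coexistence_edges:
        for fid in edge:
            degrees[idx[fid]] += 1
    value = float(degrees.mean() / (graph.n_animals - 1))
    if warning_threshold is not None:
        graph.low_connectivity_warning = value < warning_threshold
    return value


def find_global_fragments(graph: FragmentGraph) -> list[GlobalFragment]:
    """All maximal frame intervals during which exactly N fragments coexist.

    Sweep-line over fragment start/end events; elementary intervals with a
    constant alive set of size N are merged when their membership matches.
    An empty result is valid — the pipeline does not require global
    fragments to exist.
    """
    n = graph.n_animals
    boundaries = sorted(
        {f.start_frame for f in graph.fragments} | {f.end_frame for f in graph.fragments}
    )
    out: list[GlobalFragment] = []
    for left, right in zip(boundaries[:-1], boundaries[1:]):
        alive = frozenset(
            f.fragment_id
            for f in graph.fragments
            if f.start_frame <= left and f.end_frame >= right
        )
        if len(alive) != n:
            continue
        if out and out[-1].member_fragment_ids == alive and out[-1].common_frame_range[1] == left:
            prev = out.pop()
            out.append(GlobalFragment(alive, (prev.common_frame_range[0], right)))
        else:
            out.append(GlobalFragment(alive, (left, right)))
    return out


def _link_score(prev: Blob, cur: Blob, max_displacement: float):
    """(overlap, -distance) score for linking, or None if not linkable."""
    ov = prev.overlap(cur)
    dist = prev.distance_to(cur)
    if ov > 0:
        return (ov, -dist)
    if dist <= max_displacement:
        return (0, -dist)
    return None


def _touches(prev: Blob, cur: Blob, max_displacement: float) -> bool:
    return prev.overlap(cur) > 0 or prev.distance_to(cur) <= max_displacement


def build_fragments(
    blobs_per_frame: list[list[Blob]],
    n_animals: int,
    *,
    max_displacement: float = 15.0,
    crossing_area_factor: float = 1.5,
    classify: bool = True,
    connectivity_warning: float = 0.5,
) -> FragmentGraph:
    """Link per-frame blobs into individual fragments and crossing runs.

    Individual blobs are linked frame-to-frame by maximal pixel overlap,
    falling back to nearest centroid within ``max_displacement``; ties break
    toward larger overlap then smaller distance.  A fragment terminates when
    its blob disappears or touches a crossing blob; links are never bridged
    across a frame gap.  When ``classify`` is true, blobs are first labelled
    individual/crossing from the median blob area and the multi-overlap
    rule; pass ``classify=False`` for pre-classified detection tables.
    """
    if classify:
        areas = [b.pixel_count for frame in blobs_per_frame for b in frame]
        if areas:
            median_area = float(np.median(areas))
            prev_frame: list[Blob] = []
            for frame_blobs in blobs_per_frame:
                for blob in frame_blobs:
                    blob.kind = classify_blob(
                        blob, median_area, crossing_area_factor, prev_frame
                    )
                prev_frame = frame_blobs

    fragments: list[Fragment] = []
    next_id = 0
    # open fragments: list of (blob list, start_frame); parallel to their last blob
    open_frags: list[list[Blob]] = []
    open_runs: list[list[Blob]] = []   # open crossing runs
    closed_runs: list[CrossingRun] = []
    # map: crossing-run object id -> entering fragment ids
    run_entering: dict[int, list[int]] = {}
    run_exit_pending: list[tuple[CrossingRun, Blob]] = []

    def close_fragment(blob_list: list[Blob], touched_runs: list[list[Blob]]) -> None:
        nonlocal next_id
        frag = Fragment(
            fragment_id=next_id,
            start_frame=blob_list[0].frame_index,
            end_frame=blob_list[-1].frame_index + 1,
            blobs=blob_list,
        )
        fragments.append(frag)
        for run in touched_runs:
            run_entering.setdefault(id(run), []).append(frag.fragment_id)
        next_id += 1

    n_frames = len(blobs_per_frame)
    for f in range(n_frames):
        frame_blobs = blobs_per_frame[f]
        individuals = [b for b in frame_blobs if not b.is_crossing]
        crossings = [b for b in frame_blobs if b.is_crossing]

        # --- link individual blobs to open fragments (greedy best-first) ---
        scored = []
        for fi, blob_list in enumerate(open_frags):
            prev = blob_list[-1]
            for bi, cur in enumerate(individuals):
                s = _link_score(prev, cur, max_displacement)
                if s is not None:
                    scored.append((s, fi, bi))
        scored.sort(key=lambda t: t[0], reverse=True)
        frag_taken: set[int] = set()
        blob_taken: set[int] = set()
        links: dict[int, int] = {}
        for _, fi, bi in scored:
            if fi in frag_taken or bi in blob_taken:
                continue
            frag_taken.add(fi)
            blob_taken.add(bi)
            links[fi] = bi

        # --- extend crossing runs ---
        new_open_runs: list[list[Blob]] = []
        run_matched: set[int] = set()
        for cur in crossings:
            best = None
            for ri, run in enumerate(open_runs):
                if ri in run_matched:
                    continue
                s = _link_score(run[-1], cur, max_displacement)
                if s is not None and (best is None or s > best[0]):
                    best = (s, ri)
            if best is not None:
                ri = best[1]
                run_matched.add(ri)
                open_runs[ri].append(cur)
                new_open_runs.append(open_runs[ri])
            else:
                new_open_runs.append([cur])

        # --- close fragments that were not extended ---
        still_open: list[list[Blob]] = []
        for fi, blob_list in enumerate(open_frags):
            if fi in links:
                blob_list.append(individuals[links[fi]])
                still_open.append(blob_list)
            else:
                touched = [
                    run for run in new_open_runs
                    if _touches(blob_list[-1], run[-1], max_displacement)
                    and run[-1].frame_index == f
                ]
                close_fragment(blob_list, touched)

        # --- close crossing runs that were not extended ---
        for ri, run in enumerate(open_runs):
            if ri not in run_matched:
                closed_runs.append(
                    CrossingRun(
                        start_frame=run[0].frame_index,
                        end_frame=run[-1].frame_index + 1,
                        blobs=run,
                        entering=run_entering.get(id(run), []),
                    )
                )
        open_runs = new_open_runs

        # --- new fragments from unmatched individual blobs ---
        for bi, blob in enumerate(individuals):
            if bi not in blob_taken:
                new_list = [blob]
                still_open.append(new_list)
                # record exit from a crossing run that ended at frame f
                for run in closed_runs:
                    if run.end_frame == f and _touches(run.blobs[-1], blob, max_displacement):
                        run_exit_pending.append((run, blob))
        open_frags = still_open

    # flush remaining open fragments and runs
    for blob_list in open_frags:
        close_fragment(blob_list, [])
    for run in open_runs:
        closed_runs.append(
            CrossingRun(
                start_frame=run[0].frame_index,
                end_frame=run[-1].frame_index + 1,
                blobs=run,
                entering=run_entering.get(id(run), []),
            )
        )

    # resolve exiting fragment ids from their first blob
    first_blob_to_fid = {id(fr.blobs[0]): fr.fragment_id for fr in fragments}
    for run, blob in run_exit_pending:
        fid = first_blob_to_fid.get(id(blob))
        if fid is not None:
            run.exiting.append(fid)

    graph = FragmentGraph(
        fragments=fragments,
        n_animals=n_animals,
        crossing_runs=sorted(closed_runs, key=lambda r: r.start_frame),
        n_frames=n_frames,
    )
    if graph.fragments:
        fragment_connectivity(graph, warning_threshold=connectivity_warning)
    return graph
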