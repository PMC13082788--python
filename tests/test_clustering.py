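"""k-means identity clustering, Silhouette scoring, soft assignment, exclusivity."""

import itertools

import numpy as np
import pytest

from pairtrack import (
    DataInconsistencyError,
    InvalidInputError,
    assign_identities,
    assignment_probability,
    kmeans_cluster,
    mean_silhouette,
)
from pairtrack.clustering import EmbeddingSpace

from conftest import graph_from_intervals


def silhouette_oracle(points, labels):
    """Direct-formula Silhouette: per point (b-a)/max(a,b), singletons 0."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    scores = []
    for i in range(len(points)):
        same = (labels == labels[i])
        same[i] = False
        if not same.any():
            scores.append(0.0)
            continue
        a = np.mean(np.linalg.norm(points[same] - points[i], axis=1))
        b = min(
            np.mean(np.linalg.norm(points[labels == c] - points[i], axis=1))
            for c in np.unique(labels) if c != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestKMeans:
    def test_separated_blobs_recovered_up_to_permutation(self):
        rng = np.random.default_rng(0)
        truth = np.repeat(np.arange(3), 40)
        centers_true = np.array([[0, 0], [30, 0], [0, 30]], dtype=float)
        pts = centers_true[truth] + rng.normal(0, 0.5, (120, 2))
        centers, labels = kmeans_cluster(pts, 3, seed=1)
        # brute-force nearest-center assignment must agree with labels
        d = np.linalg.norm(pts[:, None] - centers[None], axis=2)
        assert np.array_equal(labels, d.argmin(axis=1))
        # one cluster per true blob
        for c in range(3):
            assert len(np.unique(labels[truth == c])) == 1
        assert len(np.unique(labels)) == 3

    def test_identical_points_degenerate_but_handled(self):
        pts = np.zeros((10, 2))
        centers, labels = kmeans_cluster(pts, 2, seed=0)
        assert centers.shape == (2, 2)
        assert labels.shape == (10,)

    def test_same_seed_identical_centers(self):
        pts = np.random.default_rng(1).normal(size=(50, 4))
        c1, _ = kmeans_cluster(pts, 3, seed=7)
        c2, _ = kmeans_cluster(pts, 3, seed=7)
        assert np.array_equal(c1, c2)

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(InvalidInputError):
            kmeans_cluster(np.zeros((2, 3)), 4)


class TestAssignmentProbability:
    def test_equidistant_point_gets_uniform_probabilities(self):
        centers = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        p = assignment_probability(np.zeros(2), centers, temperature=0.5)
        assert p == pytest.approx(np.full(4, 0.25))

    def test_point_at_a_center_with_far_others_is_nearly_certain(self):
        centers = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        p = assignment_probability(np.zeros(2), centers, temperature=1.0)
        assert p[0] > 0.9999

    def test_swapping_centers_permutes_probabilities(self):
        rng = np.random.default_rng(2)
        centers = rng.normal(size=(4, 3))
        x = rng.normal(size=3)
        p = assignment_probability(x, centers, 1.3)
        p_swapped = assignment_probability(x, centers[[1, 0, 2, 3]], 1.3)
        assert p_swapped == pytest.approx(p[[1, 0, 2, 3]])

    def test_rows_sum_to_one_for_batches(self):
        rng = np.random.default_rng(3)
        p = assignment_probability(rng.normal(size=(200, 8)), rng.normal(size=(5, 8)), 2.0)
        assert p.sum(axis=1) == pytest.approx(np.ones(200), abs=1e-9)

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            assignment_probability(np.zeros(2), np.zeros((2, 2)), 0.0)


class TestMeanSilhouette:
    def test_ideal_clustering_scores_exactly_one(self):
        pts = np.array([[0.0, 0.0]] * 5 + [[10.0, 10.0]] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        assert mean_silhouette(pts, labels) == 1.0

    def test_crossed_labels_score_negative(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([0, 1, 0, 1])
        got = mean_silhouette(pts, labels)
        assert got < 0
        assert got == pytest.approx(silhouette_oracle(pts, labels))

    def test_matches_direct_formula_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pts = rng.normal(size=(40, 3))
            labels = rng.integers(0, 3, size=40)
            if len(np.unique(labels)) < 2:
                continue
            got = mean_silhouette(pts, labels)
            assert -1.0 <= got <= 1.0
            assert got == pytest.approx(silhouette_oracle(pts, labels), abs=1e-8)

    def test_single_cluster_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_silhouette(np.zeros((5, 2)), np.zeros(5, dtype=int))


def _space_for(graph, prob_rows):
    """EmbeddingSpace stub: one image per fragment frame, fixed prob rows."""
    refs, probs = [], []
    for frag in graph.fragments:
        for k in range(frag.n_images):
            refs.append((frag.fragment_id, frag.start_frame + k))
            probs.append(prob_rows[frag.fragment_id])
    probs = np.array(probs, dtype=float)
    k = probs.shape[1]
    return EmbeddingSpace(
        points=np.zeros((len(refs), 2)),
        image_refs=refs,
        centers=np.zeros((k, 2)),
        labels=probs.argmax(axis=1),
        probabilities=probs,
        mean_silhouette=1.0,
    )


class TestAssignIdentities:
    def test_fragment_at_cluster_center_gets_that_identity(self):
        graph = graph_from_intervals([(0, 0, 5), (1, 0, 5)], 2)
        space = _space_for(graph, {0: [0.99, 0.01], 1: [0.02, 0.98]})
        out = assign_identities(graph, space)
        assert out[0][0] == 0 and out[1][0] == 1
        assert out[0][1] == pytest.approx(0.99)

    def test_conflict_resolved_by_optimal_matching(self):
        """Both fragments prefer cluster 1; the higher-confidence one wins
        and the other takes its best remaining cluster — exactly the
        brute-force-optimal one-to-one assignment."""
        graph = graph_from_intervals([(0, 0, 5), (1, 0, 5)], 2)
        rows = {0: [0.1, 0.9], 1: [0.4, 0.6]}
        space = _space_for(graph, rows)
        out = assign_identities(graph, space)
        assert out[0][0] == 1 and out[1][0] == 0
        # brute force over all one-to-one assignments
        best = max(
            itertools.permutations(range(2)),
            key=lambda pi: rows[0][pi[0]] + rows[1][pi[1]],
        )
        assert (out[0][0], out[1][0]) == best

    def test_permuting_cluster_indices_permutes_identities(self):
        graph = graph_from_intervals([(0, 0, 5), (1, 0, 5)], 2)
        space = _space_for(graph, {0: [0.9, 0.1], 1: [0.2, 0.8]})
        out = assign_identities(graph, space)
        graph2 = graph_from_intervals([(0, 0, 5), (1, 0, 5)], 2)
        space2 = _space_for(graph2, {0: [0.1, 0.9], 1: [0.8, 0.2]})
        out2 = assign_identities(graph2, space2)
        assert out2[0][0] == 1 - out[0][0]
        assert out2[1][0] == 1 - out[1][0]

    def test_more_coexisting_fragments_than_animals_is_inconsistent(self):
        graph = graph_from_intervals([(0, 0, 5), (1, 0, 5), (2, 0, 5)], 2)
        space = _space_for(graph, {0: [0.9, 0.1], 1: [0.2, 0.8], 2: [0.5, 0.5]})
        with pytest.raises(DataInconsistencyError):
            assign_identities(graph, space)

    def test_coexisting_fragments_never_share_identity(self, fitted_results):
        graph = fitted_results.model.graph
        for frag in graph.fragments:
            for nid in graph.neighbors(frag.fragment_id):
                other = graph.by_id(nid)
                if frag.identity is not None and other.identity is not None:
                    assert frag.identity != other.identity

    def test_probability_rows_sum_to_one(self, fitted_results):
        rows = fitted_results.space.probabilities.sum(axis=1)
        assert rows == pytest.approx(np.ones_like(rows), abs=1e-9)
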