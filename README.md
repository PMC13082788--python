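# pairtrack

Multi-animal tracking by identification, reframed as **contrastive
representation learning** on image pairs mined from the video's own
temporal structure — no identity labels, and no need for video segments
where all animals are simultaneously visible.

## Who this is for

Researchers in collective animal behaviour who need per-individual
trajectories of N visually similar animals (fish, flies, mice, …) from a
single overhead grayscale video, including videos with heavy occlusion
where classification-based trackers cannot find the "global fragments"
they require.

## The method

The video is segmented into blobs and linked into **individual
fragments** — maximal runs of single-animal images between two crossings.
The fragment structure supplies supervision for free:

- two images from the *same* fragment show the same animal → positive pair;
- images from two fragments that *coexist in time* show different
  animals → negative pair.

A network f maps each crop to R^M (M = 8).  With pair distance
d = ‖f(x₁) − f(x₂)‖, training minimizes the double-margin contrastive loss

    L = max(0, d − D_pos)²   for positive pairs     (D_pos = 1)
    L = max(0, D_neg − d)²   for negative pairs     (D_neg = 10)

on batches of 400 + 400 pairs (1600 images).  Images then cluster by
identity in the embedding space: **k-means with k = N** assigns each image
to an identity with probability p_c ∝ exp(−‖x−μ_c‖²/τ), and the **mean
Silhouette score** s̄ gates training — it stops once s̄ ≥ 0.91, the
operating point where the per-image identification error drops below 1%.
Deterministic post-processing enforces one identity per fragment, repairs
impossible jumps, and interpolates positions through crossings.  Output:
x, y per animal per frame, per-frame assignment probabilities, the
Silhouette score, and an internal accuracy estimate.  Tracking quality is
scored with **IDF1** = IDTP / (IDTP + ½IDFP + ½IDFN) under the best
identity bijection.

The package also ships a **fragment connectivity** diagnostic (mean
coexisting partners per fragment / (N−1); a warning fires below 0.5), a
sector-occlusion experiment harness, and a ground-truthed synthetic video
generator used throughout the tests.

## Worked example

```python
from pairtrack import (ContrastiveTracker, GeneratorConfig, TrackingConfig,
                       generate_dataset, idf1)

dataset = generate_dataset(GeneratorConfig(n_animals=4, n_frames=600,
                                           arena_radius=90.0, seed=3))
config = TrackingConfig(n_animals=4, max_batches=600, eval_every=25)
results = ContrastiveTracker.from_dataset(dataset, config).fit(seed=1)
print(results.summary())
score = idf1(results.trajectories, dataset.positions,
             match_radius=dataset.config.body_radius,
             include_crossings=False, gt_crossing_mask=dataset.in_crossing)
print(f"IDF1 (excluding crossings): {score.idf1:.4f}")
```

```
                    Contrastive Tracking Results
==================================================================
No. animals (N):                4
No. frames:                   600
No. fragments:                 36
No. crossing events:           16
Fragment connectivity:      1.593
Global fragments:              17
------------------------------------------------------------------
Training batches:             100
Stop reason:             silhouette_reached
Silhouette (training):      0.919
Silhouette (final):         0.919
Estimated accuracy:        1.0000
==================================================================
IDF1 (excluding crossings): 1.0000
```

The 600-frame video of 4 textured animals breaks into 36 fragments at 16
crossings.  Training hits the 0.91 Silhouette stopping criterion after
100 batches; k-means then separates the four identities cleanly
(estimated accuracy 1.0), and the assembled trajectories match the
generator's ground truth exactly on every non-crossing frame
(IDF1 = 1.0).  `results.trajectories` holds the (N, T, 2) positions with
per-frame probabilities and provenance (detected / interpolated /
missing).

There is also a CLI mirroring the library:

```bash
pairtrack generate --config gen.toml --output dataset/
pairtrack track    --input dataset/ --output session/ --seed 5
pairtrack evaluate --session session/ --groundtruth dataset/groundtruth.csv
pairtrack occlusion-sweep --input dataset/ --thetas 0,90,180,270 --output sweep.csv
```

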