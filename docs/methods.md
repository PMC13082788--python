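# Methods

## The tracking-by-identification model

pairtrack tracks N visually similar animals in a grayscale video by
*identification*: instead of propagating identities frame to frame, it
learns what each animal looks like and assigns every image independently.
The supervision is label-free and comes from the video's temporal
structure:

- an **individual fragment** — the maximal run of single-animal images
  between two crossings — contains images of one (unknown) identity, so
  any two of its images form a **positive pair**;
- two fragments that **coexist in time** for at least one frame cannot be
  the same animal, so images drawn from them form a **negative pair**.

A compact embedding network f maps each L×L crop to a point in R^M
(M = 8).  For a pair with embedding distance d the double-margin
squared-hinge contrastive loss is

    positive:  max(0, d − D_pos)²        D_pos = 1
    negative:  max(0, D_neg − d)²        D_neg = 10

The lower margin D_pos stops a fragment from collapsing to a single point;
the upper margin D_neg stops negatives from scattering without bound; the
ratio D_neg/D_pos = 10 is the operating point adopted throughout.  Batches
contain 400 positive and 400 negative pairs (1600 images).

After training, **k-means with k = N** clusters all embedded images; each
image receives a soft assignment p_c ∝ exp(−‖x−μ_c‖²/τ) and clustering
quality is the **mean Silhouette score** s̄ ∈ [−1, 1] (1 = ideal).
Training stops when s̄ ≥ 0.91 on two consecutive evaluations — the
operating point at which the per-image identification error is below 1%
on separable data — or at `max_batches`.

Identity assignment is per fragment (argmax of the mean per-image
probability), with temporally coexisting fragments forced onto distinct
identities by Hungarian matching per coexistence clique.  Post-processing
is deterministic: one identity per fragment, removal/re-assignment of
fragments arriving with impossible speeds, and linear interpolation of
positions through crossings.

## Fragment connectivity

Connectivity = mean fragment degree in the coexistence graph divided by
N−1.  It measures whether enough fragments coexist to mine negative
pairs; below 0.5 the method is expected to degrade and the pipeline
warns.  Note the raw statistic can exceed 1 on videos where long
fragments outlive several shorter partners in sequence; the low end is
the regime that matters.  Global fragments (N fragments coexisting in one
frame) are detected and reported but are *not required* — the pipeline
runs and tracks correctly without any.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `embedding_dim` (M) | 8 | – | fastest convergence to low error at this output width |
| `d_pos`, `d_neg` | 1, 10 | embedding distance | double margin, ratio 10 |
| `n_pos_pairs`, `n_neg_pairs` | 400, 400 | pairs/batch | 1600 images per batch |
| `silhouette_stop` | 0.91 | – | s̄ at which per-image error < 1% |
| `connectivity_warning` | 0.5 | – | empirical degradation threshold |
| `exclusion_margin` | 15 | px | occlusion-evaluation margin (75 for mouse-scale bodies) |
| `crossing_area_factor` | 1.5 | – | blob area above this multiple of the median ⇒ crossing |
| `jump_mad_factor` | 4 | – | speed gate median + 4·MAD flags impossible jumps |
| `priority_mix` (β) | 0.5 | – | baseline fraction of pair sampling |
| `eval_every` | 50 | batches | Silhouette evaluation stride |
| `learning_rate` | 1e-3 | – | Adam |
| `crop_size` (L) | 24 | px | within the 20–100 px regime typical of group videos |

## Design choices where the design was open

- **Backbone.**  The embedding network is a dense ReLU network
  (576→128→64→8) written directly in numpy with hand-derived gradients
  and Adam.  At the 24-px crop scale the identity signal is a stable
  textured appearance pattern, which a dense network separates reliably
  in seconds on one CPU core; the backbone sits behind a single class so
  a convolutional replacement slots in without touching the trainer.
- **Crossing detection** is heuristic: area > 1.5× the median blob area,
  or pixel overlap with ≥2 fragments alive in the previous frame.  A
  learned detector is out of scope.
- **Linking** is pixel-overlap first, centroid-distance fallback (radius
  `max_displacement`), ties broken by larger overlap then smaller
  distance; deterministic.  Links are never bridged across a frame gap.
- **Sampling priorities.**  Cluster priority ∝ max(0, 1 − s̄_c) from the
  most recent evaluation clustering, mixed β/1−β with the
  fragment-size baseline; pure baseline before the first clustering.
  Negatives pick partners uniformly among coexisting fragments to keep
  coverage broad.
- **Silhouette cost control.**  The statistic is O(n²): during training
  it is computed on a fixed seeded subsample (≤ 4000 images); the final
  report uses a seeded subsample capped at 8000.  Stopping requires two
  consecutive evaluations over threshold to resist subsample noise.
- **Soft-assignment temperature** τ is the mean within-cluster squared
  distance — the only stated requirement is monotonicity in distance.
- **Estimated accuracy** is the mean over images of the maximum
  assignment probability; it is an internal approximation, not a
  ground-truth accuracy.
- **Jump repair** detaches all flagged fragments before re-assigning any,
  so two fragments swapped at a crossing can trade places.
- **Interpolation** fills a gap only when the identity is detected on
  both sides and a crossing blob overlaps the gap; no extrapolation.
- Per-fragment identity exclusivity is resolved clique-by-clique in frame
  order (Hungarian within each clique, earlier assignments fixed), which
  is exact per clique and deterministic.

## The synthetic generator

`pairtrack.synthetic` emulates the features the algorithm actually
consumes: N textured bodies (discs with smooth procedural patterns),
identity-specific appearance scaled by `separability` ∈ [0, 1]
(0 = identities indistinguishable in expectation), correlated random-walk
motion reflected at a circular arena wall, pixel noise, detection jitter,
and — crucially — merged crossing blobs whenever two animals come within
`crossing_distance`, which is what breaks fragments in real videos.
Defaults: N = 8, T = 3000 frames, arena radius 120 px, body radius 7 px,
speed 2.5 ± 0.8 px/frame, turning SD 0.4 rad, separability 0.9, pixel
noise SD 0.03.

It does **not** emulate deformable bodies, pose/orientation variation,
lighting drift, reflections, or appearance change over time.  Passing
tests therefore demonstrate the correctness of the machinery (pair
mining, loss, clustering, assignment, post-processing, scoring) and the
behaviour of the method under controlled separability/occlusion, not
performance on any real species.

## Problem sizes used in the checks

Batch-composition and analytic checks are instant.  The
Silhouette↔error experiments use N = 8, T = 3000, separability 0.9
(~22k individual images; training stops around 1–2k batches, ≈ 30–60 s
per seed on one CPU core).  End-to-end recovery uses N = 5, T = 2000.
The occlusion sweep uses N = 4, T = 800 over six sector angles with a
500-batch training budget per angle.  These sizes are the package's
desk-scale operating points; all scale linearly in T and in the number
of images.

## Known limitations

- Identities cannot be resolved *inside* a crossing blob; positions there
  are linear interpolations.
- The IDF1 matcher is greedy nearest-neighbour within a radius; at
  densities where two animals sit within the radius of one prediction the
  per-frame matching can be ambiguous (the identity bijection itself is
  exact Hungarian).
- The accuracy estimate is a model-internal confidence, biased upward
  when clusters are tight but wrong.
- With `separability` near 0 the contrastive signal vanishes by
  construction and training cannot reach the Silhouette criterion; the
  run ends at `max_batches` with a diagnostic stop reason.
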