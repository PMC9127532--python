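# Methods

This note documents what `qwpso` computes, the choices made where the
method leaves room, and what the tests do and do not demonstrate.

## The segmentation procedure

The engine (`qwpso.engine`) maintains M continuous particle positions
over the image. One particle acts per update (round-robin), and the
budget counts position updates. A particle's role is decided by the
pixel under it (positions are rounded half-up and clipped):

1. **Pixel particle** (unlabeled pixel). Its meeting partner is the
   spatially nearest entity — another particle or a cluster centroid,
   ties to the lower id, particles before clusters. If the partner is
   another unlabeled particle and the two pixels pass the entanglement
   test (gray difference ≤ TH_f **and** Euclidean distance ≤ TH_o, both
   inclusive), they form a new seed cluster. Otherwise the pixel is
   absorbed by the reachable cluster — one with a member within TH_o —
   whose running mean best matches its gray, provided the difference is
   ≤ TH_f. If no cluster admits it, the particle founds a new singleton
   seed at its pixel. It then moves by the QPSO update.
2. **Seed particle** (labeled pixel). Its wormhole partner is chosen in
   the *hidden* similarity metric: the foreign cluster with the most
   similar mean gray among clusters whose centroid is farther than TH_o
   (spatial neighbors belong to the entanglement domain), ties to the
   farther cluster, then the lower id. The particle moves by the
   wormhole update with Δθ measured between the two clusters' disc
   embeddings, and the clusters merge if the wormhole-existence test
   passes (both sizes ≥ 2; mean difference ≤ TH_f with centroid distance
   > TH_o; connection probability ≥ `connect_prob_min`). With the
   wormhole branch disabled — which *is* the QPSO baseline — the
   particle moves by the QPSO update instead and no long-range merge can
   ever occur.

**Anti-stagnation.** As personal bests converge, |Mbest − x| → 0 and
both update rules collapse below one pixel, freezing the swarm on its
current pixels. A seed particle whose move does not change its pixel is
therefore re-dispersed uniformly at random. This keeps pixel-particle
traffic (and hence absorption) alive until the image is covered, and is
applied identically in both engines so the reduction property is
untouched.

**Finalization.** When all pixels are labeled or the budget is spent:
leftover pixels are attached to the cluster minimizing (gray difference,
then centroid distance, then id) lexicographically, against means frozen
at loop exit; then clusters whose pre-merge means differ by ≤ TH_f and
whose member sets come within TH_o are united transitively (the
cluster-level closure of the entanglement test — it makes a constant
image end as exactly one cluster and removes any dependence on founding
order). Final cluster statistics are recomputed exactly from the members.

**Foreground rule.** Cluster means are split by a between-class-variance
threshold (Otsu over the per-pixel mean image); under bright-object
polarity the foreground is the **single largest** cluster on the bright
side (dark-object mirrors this). Choosing one cluster rather than the
union of all bright clusters is deliberate: it makes long-range linking
observable in the output mask — an object split into two distant parts
is recovered in full only if something merged the parts — at the cost of
never emitting multiple disconnected objects. A degenerate image (a
single cluster, or all means equal) yields an empty foreground.

**Fitness.** The method's clustering steps do not need an objective
function, but the QPSO machinery does. Before any cluster exists the
fitness of a position is the negative local 3×3 intensity standard
deviation (homogeneous regions make good seed sites); afterwards it is
−|g − f̄| against the nearest cluster's mean. Personal/global bests
maximize it. This only steers exploration; correctness of the final
labeling rests on the admission tests above.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `th_f` | 10 | gray-similarity threshold, 8-bit intensity units |
| `th_o` | 3 | spatial neighborhood radius, pixels |
| `alpha` | 0.75 | contraction–expansion coefficient of the QPSO move |
| `L` | 0.1·max(H, W) | Delta-well characteristic length, pixels |
| `swarm_size` | 40 | roaming particles M |
| `max_iter` | 200·M | budget of position updates |
| `zeta` | 1.0 | distance coefficient of the wormhole measure |
| `disc_radius` | 10 | hyperbolic disc radius R |
| `avg_degree_c` | 1.0 | the c in N = c·e^(R/2); parameter semantics only |
| `delta_theta_policy` | measured | Δθ from the disc embedding (or `fixed`) |
| `delta_theta_fixed` | 0.6 | degrees, used under the `fixed` policy |
| `connect_prob_min` | 0.5 | acceptance threshold for a wormhole |

Intensities stay on the native 0–255 scale, so `th_f` is an 8-bit gray
difference. Angles are degrees; the admissible separation is clamped to
[0.01, 57.32], the upper value being the printed form of 360/(2π) that
the efficiency argument (57.32/360 ≈ 15.9%) is stated with, the lower a
floor that keeps ln(Δθ/2) finite for angularly coincident nodes.

## Numerical and convention choices

* Coordinates are 0-based (row, col), row increasing downward;
  continuous positions round half-up and clip to bounds.
* The disc embedding takes r as the centroid's distance from the image
  midpoint ((H−1)/2, (W−1)/2) normalized by the distance to the
  *continuous* image corner (hypot(H/2, W/2)) and scaled to R, so r ≤ R
  always; θ is the polar angle about the midpoint.
* The connection probability e^(ζ(x−R)/2) exceeds 1 for x > R and is
  clamped — longer hidden paths connect with certainty. Wormholes
  therefore preferentially link *distant* similar clusters, while
  adjacent ones are handled by entanglement.
* The logarithm in the wormhole update is kept signed: for Δθ ≤ 2 the
  added term is ≤ 0, mirroring the μ ≤ 0.5 branch of the QPSO update;
  both branches coincide exactly at Δθ = 2 (and μ = 1 collapses the
  QPSO move to its attractor exactly).
* The ± sign of the one-shot position samplers is a fair coin; the
  random draws u, μ are taken in (0, 1] so ln(1/u) is finite.
* All randomness flows from one `numpy.random.default_rng(seed)`
  stream; runs are bit-reproducible, and `pytest` plus the acceptance
  script derive every draw from explicit seeds.
* Float ties in the leftover attachment are resolved by exact
  comparison (means of noiseless clusters are exact), then id.

## The phantom generator

`qwpso.phantoms` emulates the qualitative structure of the target
images: a bright object (default gray 200) on a darker background
(default 50) with additive zero-mean Gaussian noise (suite levels: sd 0
and 10), 64×64 by default. Shapes: a disc of radius size/4; a
*bottleneck* of two lobes joined by a neck whose width grows
quadratically away from the central row (a rasterizable stand-in for a
hyperbolic throat profile; the central-row width equals `neck_width`
exactly); a *dualtail* disc with two horizontal tails whose half-width
tapers linearly to no less than half a pixel. `neck_gap` carves a
horizontal band out of the neck, producing two disjoint lobes — the
configuration that requires long-range linking. The ground-truth mask is
always the exact noiseless silhouette and never depends on the noise.

What the phantoms do **not** model: MRI/CT physics (bias fields, partial
volume, structured noise), anatomy-scale intensity gradients, multiple
objects, or 3-D continuity. Perfect scores on noiseless phantoms show
the clustering rules and the wormhole linkage are implemented coherently;
they do not predict performance on real scanner data.

## Problem sizes

The default study conditions — 64×64 phantoms, M = 40 particles,
200·M = 8000 position updates — were chosen as the smallest scale at
which all phantom shapes are comfortably resolved (the narrowest
structure, a 2-pixel neck, spans several entanglement radii); a run
takes well under a second, and the full suite of behavioural checks
runs in tens of seconds.

## Known limitations

* The foreground is a single cluster by design; images with several
  disconnected objects of the same class are reported as the largest
  one unless wormholes merge them.
* The fitness function is a heuristic the method itself never defines;
  other choices would change the exploration pattern (not the admission
  rules).
* With strong noise relative to TH_f the running means drift and
  absorption can leak across faint boundaries, as in any
  region-growing scheme.
* The published F values of the method's own evaluation tables cannot
  be reconciled with any standard F-measure computed from their printed
  precision and recall; this package uses the standard F1 = 2PR/(P+R).
* Only 2-D, single-channel, two-class segmentation is supported.
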