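# Methods

## The problem

Post-stroke hemiplegic patients walk with heterogeneous impairment
patterns; rehabilitation planning benefits from grouping patients by how
they actually move rather than by scalar clinical scores.  The raw
observable is a time-normalized gait cycle: sagittal-plane joint angle and
angular velocity trajectories for the hip, knee and ankle of the affected
side, each resampled to T points over 0–100% of the cycle.  `dtcgait`
clusters such cycles end to end — feature learning and cluster assignment
are optimized jointly, with no hand-crafted features.

## Model

**Input.** Each instance is one row of an N × 6T matrix: the six channels
(hip/knee/ankle angle, then the corresponding angular velocities, in that
recorded layout order) concatenated.  With the default T = 100 this is 600
features per instance.  The network consumes the row as a single channel
of length 6T; a 6-channel × T presentation is available as a config
switch.  Optional per-feature z-scoring is exposed (`standardize_tensor`)
and used in the package's own reference runs: angle channels are O(10 deg)
while velocity channels are O(100 deg/s), and without standardization the
reconstruction objective is dominated by velocity amplitude.

**Temporal autoencoder (TAE).** Encoder: one 1D convolution (kernel 10,
stride 1, same padding, 50 output channels, leaky-ReLU slope 0.01), max
pooling with pool size 10, then two bidirectional LSTM layers with hidden
widths 50 and 1.  The latent representation z of one instance is the
second Bi-LSTM's output sequence: (6T / pool) steps × 2 values, i.e.
60 × 2 = 120 latent dimensions at default sizes.  Decoder:
nearest-neighbour upsampling by the pool size followed by a transposed
convolution (kernel 10, stride 1, same padding) with a linear output.
Reconstruction quality is measured by the mean squared error
J_MSE = mean_i mean_f (x_if − x̂_if)².

**Clustering layer.** K centroids c_j live in the flattened latent space.
Dissimilarity is Pearson-based: sim(z, c) = 2(1 − ρ_{z,c}) ∈ [0, 4], with
ρ the Pearson correlation of the two vectors (population normalization;
the choice cancels in ρ).  Soft assignments use a Student's-t style
kernel, exactly q_ij ∝ (1 + sim(z_i, c_j))⁻¹, row-normalized — without a
squaring or degrees-of-freedom exponent.  The target distribution
p_ij ∝ q_ij² / f_j (f_j = Σ_i q_ij), row-normalized, sharpens confident
assignments and discounts crowded clusters; the clustering loss is
J_KL = Σ_ij p_ij log(p_ij / q_ij), and the joint objective is the
unweighted sum J_total = J_MSE + J_KL.

**Training.**
1. *Pretraining*: Adam, learning rate 1e-3, 10 epochs, minibatches of 32
   on the reconstruction loss alone.  The batch size is the smallest
   value of the commonly swept grid {32, 64, 128}; at desk-scale cohorts
   (N ≈ 120) an epoch is only a few minibatches, so the smallest batch
   gives the optimizer enough steps inside the fixed 10-epoch budget.
2. *Centroid initialization*: complete-linkage agglomerative clustering
   (Euclidean) of the pretrained latents into K groups; centroid =
   group mean.
3. *Joint phase*: full-batch gradient descent for 600 epochs (default) on
   J_total, autoencoder weights at 1e-3 and centroids at 1e-5 — the
   centroid rate is the midpoint of the usual 1e-4…1e-6 sweep.  P is
   recomputed from the full-data Q once per epoch (configurable interval)
   and treated as a constant between refreshes, so gradients flow through
   Q only — the standard convention for this loss family.  Full-batch
   updates keep runs bit-reproducible for a seed; the target refresh also
   needs full-data cluster frequencies anyway.  Labels are the argmax of
   the final Q, ties to the lowest cluster index.

Because sim ≤ 4, every q_ij ≥ 1/(5K) > 0, so soft cluster mass can never
vanish exactly; a numerically dead cluster (f_j < 1e-12) would be reseeded
to the worst-fit latent and logged, but is unreachable in practice.

All network computation runs in float64 on an in-repo reverse-mode
autodiff tape over numpy.  Gradient correctness is pinned by central
finite-difference checks (relative error ≲ 1e-5 at h = 1e-6) in the test
suite, and seeded runs are bit-reproducible independent of threading.

## Cluster-count selection

The model is trained at every k in 3…15 (configurable) from one shared
pretrained state, and each solution is scored with the silhouette index
SS = mean_i (b_i − a_i)/max(a_i, b_i) using Euclidean distances; members
of singleton clusters score 0 (the index is undefined for a_i otherwise).
Scoring happens in the flattened latent space — the space the clustering
actually operates in — with an input-space option for comparison.
Selection prefers fine-grained partitions: among k whose SS is a local
peak over the sweep, the largest k with SS ≥ 90% of the global maximum
wins (tolerance configurable).  Clusters below `min_cluster_size` (default
2, i.e. singletons) are treated as outliers: their instances are excluded
and listed, never reassigned, and the remaining groups are relabeled
consecutively.

## Post-hoc characterization

Per instance, eight kinematic peaks in degrees: hip flexion/extension
(max/min over the full cycle), knee flexion/extension within stance and
swing separately, ankle dorsiflexion (cycle max) and plantarflexion
(positive magnitude of the cycle min).  The stance/swing boundary defaults
to the canonical 60% of the cycle and uses the instance's measured stance
percentage when present in the metadata.  Sign convention: flexion and
dorsiflexion positive; peak extension is a signed minimum and may be
positive in a collapsed arc.

Group tables report mean ± sd (sample, n−1) per retained group and
overall, for kinematic peaks and any pass-through metadata
(spatiotemporal and clinical scores are lab measurements, not derived
from trajectories).  Group differences are tested with classical one-way
ANOVA, F = (SSB/df_B)/(SSW/df_W), upper-tail p; p-values are reported raw
(a Bonferroni flag exists).  Deviation from normal gait is RMSE of the
group-mean hip/knee/ankle *angle* trajectories against a normative
reference, pooled over all 3T points — velocities are excluded.

## Synthetic cohorts

Clinical gait datasets of this kind are IRB-restricted, so the package
ships a generator whose defaults define its reference test conditions:

- **Normative reference**: deterministic hip/knee/ankle angle curves
  built from landmark control points (hip 30° → −10° arc, knee loading
  response near 15% and ~55–60° swing flexion near 72%, ankle
  dorsi/plantarflexion arc) via a periodic spline, kept to the first five
  Fourier harmonics.
- **Archetypes**: K cluster templates, each the reference perturbed by a
  vocabulary of hemiplegic morphologies (collapsed hip arc, absent
  loading response, reduced dorsiflexion, near-normal, exaggerated hip
  extension), scaled by a severity in [0, 1]; severity 0 reproduces the
  reference exactly.  Entries beyond the six-item vocabulary get seeded
  random low-order perturbations.  At severity 1 the templates satisfy a
  separation margin of at least 10 × noise_sd × √(6T) in tensor space.
- **Instances**: template + amplitude jitter (sd 5%), phase jitter
  (sd 1% of the cycle), and smooth periodic noise (8 random harmonics,
  pointwise sd 1°).  Angular velocities are derived by periodic central
  differences with the cycle duration implied by the instance's sampled
  cadence (two steps per cycle).  Metadata (walking velocity, cadence,
  stride/step lengths, SLS/stance %, FMA, FAC) are drawn from
  archetype-specific normal profiles graded with deviance, so group
  tables and ANOVA are exercised meaningfully; the profiles are package
  fixtures, not population estimates.
- **Reference cohort** for tests and the acceptance script: K = 4,
  30 instances per archetype, T = 100 (120 × 600 matrix), severity 1,
  z-scored before the network.

What the generator does *not* emulate: measurement artifacts and marker
noise, within-subject correlation across repeated weeks, asymmetric
stance-dependent noise, coronal/transverse planes, or genuinely
continuous severity spectra — real cohorts have no exact cluster
structure.  Passing recovery tests therefore demonstrates that the
pipeline's optimization and bookkeeping are correct on data of the
intended shape and scale, not that clinical cohorts contain k clean
clusters.

## Baselines

The benchmark harness scores k-means (Euclidean / DTW / soft-DTW) and
k-Shape on the same N × 6T matrix, silhouettes computed in input space
(the baselines have no latent space; the deep model's row comes from its
sweep and is scored in latent space — the report documents the
asymmetry).  Euclidean k-means delegates to scikit-learn; DTW k-means
uses exact dynamic-programming DTW with DTW-barycenter-averaging updates;
soft-DTW k-means uses the soft-min recursion (γ = 1) with centroid
updates by the soft-alignment fixed point of the barycenter objective;
k-Shape uses the shape-based distance (max normalized cross-correlation
via FFT) with spectral shape extraction.  Empty clusters are reseeded to
the worst-fit series.

## Problem sizes and numerical choices

- Reference runs use 120 joint-training epochs (the fixture cohort's loss
  plateaus well before that at N = 120); the config default remains 600.
- Row-stochasticity of Q and P is maintained to 1e-9 throughout training;
  KL uses the 0·log 0 := 0 convention.
- Pearson similarity raises on constant vectors (zero variance) rather
  than guessing.
- The silhouette sweep shares a single pretrained state across k, and one
  seed per sweep; multi-seed sweeps report per-seed records.
- Finite-difference tolerance for gradient checks: 1e-4 relative at
  h = 1e-6, float64.
- ANOVA with zero within-group variance and unequal means reports
  p = 0 with a degeneracy flag.

## Known limitations

- Full-batch joint training is quadratic-free but keeps the whole graph
  in memory; cohorts beyond a few thousand instances would need
  minibatched KL with stale frequencies.
- The decoder is the simplest structural inverse of the encoder front end
  (upsample + transposed convolution, linear output); no attempt is made
  to match encoder nonlinearity layer by layer.
- Soft-DTW centroid updates use a fixed-point iteration rather than full
  quasi-Newton barycenters; for well-separated series this converges in a
  few iterations but is not guaranteed to reach the exact barycenter.
- The selection rule formalizes a "largest k among high peaks" preference
  with a 90% tolerance; on sweeps with plateaus rather than peaks the
  choice degenerates to the global maximum.
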