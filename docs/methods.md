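# Methods

## Model

The classifier grades fundus photographs into the five clinical DR
severity levels (0 normal … 4 proliferative) from two complementary
views of the same image.

The **convolutional branch** is a modified VGG-19: the five
convolutional blocks (2, 2, 4, 4, 4 layers; 64–512 channels; all 3×3,
stride 1, ReLU) are kept, the pool after the last block is removed, and
the fully connected head is replaced by a channel-wise global max-pool.
At the reference scale (224×224 input, full width) the final map is
14×14×512 and the feature vector f_k has length 512; a
`width_multiplier` shrinks every channel count proportionally so the
same architecture trains on a CPU. No pretrained weights are used.

The **graph branch** treats detector-proposed candidate-lesion regions
as nodes. Each region is a box {m, n, w, h} with centre
y = (m + w/2, n + h/2). Two nodes are joined only when each lies in the
other's K-nearest-neighbour set (K = 8, Euclidean distance, distance
ties broken by lower node index), and a joined pair receives the
Gaussian weight exp(−d²/2ω²) with ω = 1.6 px. Because the bandwidth is
much smaller than typical inter-lesion distances, most surviving edges
are weak and the renormalised operator Â = D̃^(−1/2)(A + I)D̃^(−1/2)
(self-loops on by default; a flag gives the raw D^(−1/2)AD^(−1/2) form
with a zero-degree guard) is close to the identity except for tight
lesion clusters. When n − 1 ≤ K the mutual condition is vacuous and the
graph is complete. Graph convolutions H⁽ʲ⁺¹⁾ = ReLU(Â H⁽ʲ⁾ W_j) run for
j = 2 hops at width k (default 64; 16 in the desk profile). Per-hop
features are combined with attention weights on the probability simplex,
γ_v = Σᵢ aᵢ H_v⁽ⁱ⁾; the default parameterisation is a global softmax
over learnable per-hop logits, with an optional node-conditioned variant
whose scorer uses a leaky activation with negative slope α = 0.2. A
permutation-invariant readout (mean‖max over nodes) gives the graph
vector h_k; the whole branch is therefore invariant to node order, which
the tests assert at the logit level.

**Fusion and classification.** z_k = ρ(f_k) + μ·σ(h_k) with linear
projections ρ, σ to a common dimension (default 512; 64 in the desk
profile) and fusion ratio μ = 1; μ = 0 ablates the graph branch exactly,
and z_k is linear in μ by construction. The classifier applies a leaky
activation (slope α = 0.2) and a linear layer to five scores; class
probabilities are the softmax. The leaky (rather than hard) rectifier
here is a numerical-safety choice: a hard one can silence every gradient
when all fused coordinates go negative early in training.

## Semi-supervised objective

A labeling rate splits the train set into a labeled part S (stratified
per class, at least one labeled sample per class, seeded) and an
unlabeled part U whose ground truth is hidden. Both loss terms are the
binary cross-entropy summed over the K classes and the samples —
L_label over S with true one-hot labels, L_unl over U with the model's
own one-hot argmax pseudo labels (argmax ties go to the lowest class
index) — combined as L = L_label + λ·L_unl, λ = 0.1. Pseudo labels are
refreshed once per epoch by default (a per-step mode exists), and only
after a warm-up (default 5 epochs) during which U is excluded entirely:
pseudo labels from an untrained model are noise. With λ = 0, or at
labeling rate 100%, training uses labeled data only and is bit-identical
to a run with the semi-supervised machinery disabled.

The exported loss functions implement the summed binary-CE form exactly,
with probabilities clipped at ε = 1e−7 against log 0. Inside the
training loop the same quantity is (a) scaled by 1/|batch| — a pure
re-scaling of the learning rate that keeps step sizes independent of
batch size — and (b) computed against smoothed probabilities
p′ = ε + (1 − 2ε)·softmax(z) instead of hard clipping, because a hard
clip has zero gradient in the saturated region and can freeze a run that
momentarily becomes confidently wrong.

## Optimisation profiles

The full-scale profile is SGD with momentum 0.9, weight decay 1e−4,
learning rate 1e−4 divided by 10 every 20 epochs, 60 epochs, batch 32,
with stratified seeded 10-fold cross-validation available. The
desk-scale profile (`TrainConfig.desk_scale()`) — the configuration used
throughout the tests — trains a width-1/8 backbone on 64×64 images with
Adam at 1e−3 under the same staircase schedule shape. The switch is
deliberate: at ~300 total gradient steps, a from-scratch 16-layer
backbone without normalisation layers, feeding a summed binary-CE
objective, is outside the regime where plain momentum SGD at any fixed
rate makes progress (we observed either stalling or saturation collapse
across two orders of magnitude of rates); Adam's per-parameter scaling
is the standard remedy. An optional global gradient-norm clip and a
linear warm-up ramp are available but off by default.

Two further numerical choices matter at this scale. Node features are
standardised per column with statistics calibrated once on the training
set (stored as buffers in the checkpoint; near-constant columns keep
unit scale). And the engine (a small reverse-mode autodiff over NumPy,
float32, written for this package) is fully deterministic: max-pool ties
take the first index, batches and splits derive from seeded generators,
so identical seeds reproduce loss trajectories exactly.

## Region detectors and node features

Detectors are pluggable: `log` (default) runs multiscale
Laplacian-of-Gaussian blob detection on both polarities, matching the
two lesion families (bright exudate-like, dark hemorrhage-like);
`hessian` is determinant-of-Hessian detection, the interest-point
principle behind fast-Hessian/SURF-style detectors; `orb` uses ORB
keypoints with their binary descriptors; `grid` is a deterministic
uniform grid, also the automatic fallback when a detector proposes fewer
than `min_nodes` regions (so every image yields a graph). Detections are
ranked by local contrast and capped at `max_nodes` (64 by default, 32 in
the desk profile) to bound the per-image graph cost.

Node features are a descriptor block plus geometry: 12 patch intensity
statistics (per-channel mean and spread, range, gradient energy,
bright- and dark-pixel fractions, luminance extremes — ORB contributes
its own descriptors instead), the centre and size normalised by the
image dimensions, and two spatial-arrangement cues (fraction of other
regions within a 1/6-image radius, nearest-neighbour distance). The
density cues exist because a mean/max readout is invariant to node
count: they re-inject how crowded the lesion field is, which is exactly
the severity signal the graph branch is meant to carry.

## Synthetic data

The generator emulates the APTOS layout at desk scale: a warm-toned
retinal disc with radial falloff on a black background (optionally with
lateral black bars to exercise cropping), an optic-disc analogue,
vessel-like correlated random walks, and two lesion families drawn as
Gaussian-profile blobs with Poisson counts whose means rise with the
grade — (0,0), (4,5), (10,12), (19,23), (32,38) bright/dark per grade —
plus a mild grade-dependent size factor (up to 1.65×) standing in for
lesion confluence in severe disease. Per-image streams are seeded by
(dataset seed, class, index), so images are independent and bit-exactly
reproducible. The ramp is calibrated so that the desk-scale model
reaches ~0.9 held-out accuracy with full labels, i.e. the same operating
regime as published full-scale results on real data; with adjacent
grades separated by several Poisson standard deviations the grading task
is learnable from tens of images per class.

What the generator does **not** model: real fundus optics (illumination
gradients, color temperature spread, blur), ungradable images, lesion
taxonomy beyond two intensity families, inter-grader label noise, and
the class imbalance of clinical data (the balancing utility is exercised
on synthetic imbalanced sets instead). Passing tests therefore
demonstrate that the architecture, losses, and training loop behave as
specified and that the pipeline can learn a monotone lesion-load signal
at small scale — not that this configuration reaches any particular
accuracy on real retinas.

## Preprocessing

Cropping takes the fundus diameter as the square side and the fundus
centre as the crop centre, estimated from the bounding box of pixels
above a darkness threshold (default 10/255), padding with black where
the square leaves the frame. Resizing is bilinear to 224×224 (identity
when already at target). Enhancement applies optional
brightness/colour/contrast factors (defaults 1.0) followed by the
Gaussian-blur difference blend w₁·I + w₂·blur(I) + bias with defaults
(4, −4, 128) and σ = 7 px — the widely used fundus high-pass recipe; a
constant image maps to the bias. Class balancing hits an exact per-class
target (default 1800): surplus classes are subsampled without
replacement, deficit classes are topped up with seeded flip / rotation
(uniform in ±180°) / shift (uniform within ±10% of the side) variants
whose ids derive from their parents.

## Evaluation

All metrics derive from the K×K confusion matrix (rows true, columns
predicted): accuracy = trace/n; precision and recall per class one-vs-
rest, combined micro (pooled counts — under which precision = recall =
accuracy for single-label data; the default, matching how published DR
tables show recall equal to accuracy) or macro (unweighted mean, empty
classes excluded with a warning); Cohen's kappa = (p₀ − p_e)/(1 − p_e)
with p_e = Σ a_k b_k / n², undefined (and flagged) for a single-cell
matrix. A sweep-report utility aggregates per-seed/per-fold metric dicts
over a swept parameter (labeling rate or λ) into a tidy CSV with means
and standard deviations. t-SNE embedding and gradient-saliency helpers
live in `gacnn.viz` as qualitative hooks returning arrays.

## Study problem sizes

The test suite and the acceptance script run everything at desk scale:
64×64 images, width-1/8 backbone, GCN width 16, fused dimension 64,
graphs capped at 32 nodes. The supervised reference run uses 60
images/class for 30 epochs; the labeling-rate sweep (5/25/100%) uses 32
images/class for 20 epochs; the λ ∈ {0, 0.1} comparison at 10% labeling
uses 60 images/class for 20 epochs with an 8-epoch warm-up (at 32
images/class a 10% rate leaves only ~3 labeled samples per class, too
few for pseudo-labels to be better than noise). Held-out evaluation uses
an independently seeded 12-images/class set. The architecture ledger
additionally builds the full-width backbone and pushes one 224×224×3
input through it.

## Known limitations

Pseudo-label self-training amplifies the model's own systematic errors
when the base model is weak; below roughly 55–60% base accuracy the
λ = 0.1 objective degrades performance rather than helping, so the
semi-supervised benefit should not be extrapolated to very small labeled
budgets. The binary-CE-over-softmax objective saturates more readily
than categorical CE; the smoothing described above mitigates but does
not remove this. The graph uses a fixed ω = 1.6 px bandwidth regardless
of image side, so at 64×64 the weighted adjacency is sparse and
propagation is mostly local; this follows the reference configuration
rather than any tuning of our own.
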