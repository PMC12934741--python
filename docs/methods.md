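# Methods

This document describes the model, the synthetic cohort generator, the
evaluation protocol and the deliberate numerical choices made in this
package. The package studies one question: when a conditional graph
variational autoencoder (C-GVAE) is trained on static functional
network connectivity (sFNC) matrices, how faithfully do its
reconstructions preserve subject-level structure, group-level edge
effects, graph topology and condition information in the latent space?

## Data representation

An sFNC matrix is a symmetric 53×53 correlation matrix over intrinsic
connectivity components grouped into seven functional subdomains
(subcortical, auditory, sensorimotor, visual, cognitive control,
default mode, cerebellar). A matrix becomes a graph by zeroing the
diagonal and keeping every off-diagonal entry whose absolute value
*strictly* exceeds a threshold τ (default 0.1), with its sign and
weight. Nodes are the 53 components; each node's feature vector is its
row of the thresholded matrix; the edge index lists both directions of
every surviving entry. The reconstruction target is the vector of
N(N−1)/2 = 1378 strictly-upper-triangular entries of the thresholded
matrix.

The conditioning scalar is the binary sex label as a float, or the
fluid-intelligence-like score divided by its maximum (13) so that both
conditions live on a common [0, 1] scale.

## Model

**Encoder.** A stack of graph layers (GATv2 by default; GAT, GCN, GIN
and an edge-blind MLP are available for ablation), each followed by
batch normalization, LeakyReLU and dropout. Node embeddings are
additively pooled per graph. The pooled embedding, concatenated with
the condition scalar, feeds two linear heads producing the posterior
mean μ and log-variance log σ². Both heads are zero-initialized so
that training starts exactly at the prior q(z|x,c) = N(0, I); with
random head initialization the KL term dominates the first epochs and
reliably collapses the posterior before the reconstruction term can
shape it.

**Sampling.** The reparameterization z = μ + σ ⊙ ε, ε ~ N(0, I),
keeps the sampling step differentiable.

**Decoder.** An MLP on [z ‖ c] with LeakyReLU hidden layers and a
tanh output over the 1378 upper-triangle entries, mirrored into a
symmetric zero-diagonal matrix. The tanh range matches correlation
values in [−1, 1].

**Loss.** Reconstruction error (squared error over the upper
triangle) plus β · KL(q(z|x,c) ‖ N(0, I)), β = 1. The reconstruction
term is *summed* over the 1378 edges and averaged over the batch. With
a per-edge mean instead, the reconstruction term is ~1378× smaller
than the KL term at β = 1 and the optimum is a collapsed posterior
(μ ≈ 0, σ ≈ 1) with the decoder ignoring z; the summed form keeps the
two terms on the natural ELBO scale. The loss helper also exposes the
per-edge-mean form for diagnostics.

**Optimization.** Adam (lr 1e-4, weight decay 1e-5), batch size 16,
with a reduce-on-plateau learning-rate schedule on the validation
loss. The best-validation-epoch parameters are restored at the end of
training. The network stack (tensor autodiff, layers, optimizers) is
implemented on NumPy; see `src/cgvae/nn/`.

## Synthetic cohort generator

Each subject's matrix is the exact Pearson correlation of simulated
component time courses (T = 200 by default), so every generated matrix
is symmetric, unit-diagonal and positive semidefinite by construction
— no projection or repair step.

Time courses follow a latent factor model: one shared factor per
subdomain (loading 0.8), one weak global factor (loading 0.3), and
unit-variance noise. This yields within-subdomain correlations near
0.39 and cross-subdomain correlations near 0.08, plausible group-level
sFNC scales.

**Planted effects.** Thirty edges inside a designated pair of
subdomain blocks carry a sex effect; thirty edges in another pair
carry a continuous fluid-intelligence effect. Each effect edge gets
its own latent factor whose two endpoint loadings are ±√(δ·v), where
δ is the effect size (default 0.6) and v is the subject's condition
value (sex ∈ {0, 1}; score/13 ∈ [0, 1]). The loading signs set the
direction of the induced correlation change.

**A deliberate, documented side effect.** Because effect factors load
on endpoint *nodes*, they also inflate the endpoint variances and
thereby perturb the correlations of other edges incident to those
nodes. At n = 600 this produces genuine secondary group differences
off the planted mask. Recovery tests therefore assert recall of the
planted edges and a dominance ratio (mean |t| on the mask several
times the off-mask mean) rather than a strict off-mask false-positive
rate, which would test the generator's side effect rather than the
analysis code.

## Evaluation protocol

**Splits.** Subjects are split into held-out test ids and one or more
train/validation folds, all seeded. Test ids never enter a gradient
batch; the training history records the trained ids for auditing.

**Reconstruction fidelity.** Per-subject Frobenius distance, MSE over
all entries and Pearson correlation over the unique upper-triangle
edges between real and reconstructed matrices, aggregated as
mean ± sd over held-out subjects.

**Edge-wise group effects.** Welch two-sample t-tests (sex) or
Pearson correlations (fluid intelligence) per unique edge, corrected
across the 1378 edges with Benjamini–Hochberg FDR (default q < 0.01).
Preservation is summarized by recall of real-data flags on
reconstructed data and the false-positive rate
(#flagged-in-recon-only / #not-flagged-in-real).

**Cross-scenario prediction.** An RBF-kernel SVM (sex) or SVR
(score) on vectorized upper triangles. The held-out subjects are
split once, deterministically and stratified for classification, into
disjoint train/eval halves. All three scenarios share the same eval
subjects: te→te trains on the real train half, te→gen evaluates the
same model on reconstructions of the eval half, gen→te trains on
reconstructions of the train half and evaluates on real data.
This design has two exact consequences used as tests: if
reconstructions equal the real data, te→gen and te→te reports are
identical; if reconstructions are pure noise, te→gen and gen→te drop
to chance. Hyperparameters (C ∈ {0.1, 1, 10}; γ at the median
heuristic ± one decade) are chosen by seeded k-fold cross-validation
on the training half, with the fold count adapting to the smallest
class and a mid-grid fallback (with a warning) when even 2-fold CV is
impossible.

**Topology.** Fifteen graph statistics per thresholded matrix, using
absolute weights where a weighted statistic requires nonnegativity:
node and edge counts, density, max/min/mean strength, weighted degree
assortativity, average weighted (Onnela) clustering, global
clustering, triangle counts (total, per-edge average, maximum
per-node participation), maximum k-core number, Louvain community
count and the diameter of the largest connected component (among
equally largest components, the largest diameter). Real-vs-recon
error is reported per statistic as MAE, RMSE, MAE relative to the
mean real magnitude, and error normalized by the real range (signed
mean and RMSE forms); statistics with zero real range are reported as
undefined rather than silently dropped.

**Latent probing.** Held-out subjects are encoded with their own
condition; each latent dimension is tested for association with the
condition (Welch t-test or Pearson correlation) with BH-FDR across
dimensions (q < 0.05). The most discriminative dimensions are probed
by decoding the one-hot code e_d (magnitude 1.0) under condition
values 0 and 1; the difference of the decoded matrices is exported as
a ranked edge table and connectogram.

## Determinism

Every random operation traces to a named sub-seed derived from the
run seed (cohort, splits, training, latent sampling, prediction; all
below 2³¹). Rerunning an identical configuration reproduces every
CSV/JSON/YAML artifact byte for byte; the run manifest records the
configuration, its hash, the named seeds and the completed stages
(timings go to the log, not the manifest, so manifests are comparable
across reruns).

## Parameter defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| τ (threshold) | 0.1 | removes near-zero correlation noise while keeping block structure connected |
| latent dim | 16 | small enough to force compression of 1378 edges, large enough for condition + block factors |
| hidden width | 32, 2 layers | matches the 53-node scale; larger widths gain little on synthetic cohorts |
| attention heads | 4 | standard multi-head setting at this width |
| dropout | 0.1 | mild regularization; higher values slow convergence at these sample sizes |
| epochs / batch | 30 / 16 | validation loss plateaus within 30 epochs at n = 600 |
| lr / weight decay | 1e-4 / 1e-5 | stable for the summed-reconstruction loss scale |
| q (edges / latent) | 0.01 / 0.05 | stricter control over 1378 edge tests than over ≤ 16 latent tests |

## Limitations

- The generator is a factor model with exact-correlation outputs; it
  does not model site effects, motion artifacts, global signal or
  non-Gaussian tails of real sFNC cohorts.
- The planted-effect mechanism perturbs endpoint variances (see
  above); off-mask specificity of edge tests is therefore not a
  meaningful benchmark at large n on this generator.
- Louvain community count is a heuristic; its observed optimality gap
  against exhaustive modularity search on small graphs is bounded but
  nonzero, so community count is validated by invariants and
  modularity bounds, not exact equality.
- The network stack is CPU/NumPy; it is sized for 53-node graphs and
  hundreds of subjects, not for large-scale training.
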