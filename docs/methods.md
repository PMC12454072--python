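# Methods

This package simulates contribution-fair federated learning for binary
image classification across a small number of medical centers. Everything
runs on synthetic cohorts; no patient data is involved. This note records
the models, the synthetic study conditions, the numerical choices, and the
limits of what the simulations demonstrate.

## The federated model

Centers never share images. Each round, the server broadcasts the global
parameters θ; center k trains a local copy on its own pool, returning θ_k;
the server forms the next global model as the convex combination
θ ← Σ_k w_k θ_k. Four weightings are implemented:

* **FedAvg** — w_k ∝ n_k (training-pool size), the classic choice; a
  uniform variant (w_k = 1/K) is available and is the degenerate limit of
  the contribution-fair algorithm.
* **FedProx** — FedAvg weighting, plus a proximal term (μ/2)‖θ − θ_global‖²
  in each local objective (default μ = 0.1) that limits client drift.
* **MOON** — FedAvg weighting, plus a model-contrastive term on the
  penultimate-layer representation z: the local z is pulled toward the
  global model's representation and pushed from the previous-round local
  one, with cosine similarities at temperature τ = 0.5 and weight μ = 1
  (the source method's defaults).
* **Contribution-fair (fedcmc)** — core-data extraction first (below), then
  per-round weights from the two contribution metrics:
  data richness D_k = |C_k| / Σ_j |C_j| (normalized core-set size, computed
  once, since cores are static across rounds) and model quality Q_k = the
  local model's accuracy this round at cutoff 0.5 on held-out
  probe-validation samples. The default combination is the convex mix
  w_k = λ·D_k + (1−λ)·Q_k/Σ_j Q_j with λ = 0.5; a multiplicative variant
  (w_k ∝ D_k·Q_k) exists for ablations. The exact mixing rule is an open
  design choice; the convex form keeps weights on the simplex, reduces to
  uniform for symmetric federations, and exposes λ for sensitivity
  analysis. If every Q_k is zero the weights fall back to D.

After training, the global model is fine-tuned per center for a few epochs
on that center's core set (personalization). Fine-tuning on the core rather
than the full pool is the stricter reading of core-based personalization; a
switch restores full-pool tuning.

## Core-data extraction (MCDEM)

Each center partitions its training pool S into a core set C and a
redundant set R, privately (no cross-center information). A probe network
is trained on a stratified 80% split T and scored on the held-out 20% V;
a sample's error ε is its prediction error when it falls on the validation
side. Samples with ε strictly below a threshold ε̂ are redundant: the probe
predicts them almost perfectly, so the pool already represents their
content elsewhere — near-duplicates and over-represented easy regions.
Pruning them shifts the retained distribution toward under-represented
samples. The retained fraction |C|/|S| differs across centers according to
how much redundancy each pool carries, and normalized core sizes become the
richness metric D.

Numerical choices that matter:

* **Fold sweeping.** One 80/20 split scores only a fifth of the pool.
  Cycles are organized in sweeps of five stratified, disjoint validation
  folds, so after each sweep every sample has an error; ε is the mean over
  a sample's validation appearances. Default n_repeats = 15 (three sweeps):
  averaging over three independently trained probes separates sample-level
  predictability from probe-level training noise. Samples that never reach
  a validation fold (possible only for degenerate pools) default to core.
* **Probe training.** The probe is the same small CNN used federally but
  trained harder: 150 epochs at learning rate 3·10⁻³, and in the γ → 0
  limit of the focal objective (class-weighted cross-entropy). The focal
  factor (1−p_t)^γ deliberately kills the gradient of well-classified
  samples, which caps the probe's confidence on memorized samples at
  roughly the confidence it reaches on unseen easy samples — erasing
  exactly the seen-versus-unseen resolution the redundancy ranking needs.
  Measured on the default cohort, probe training cross-entropy plateaus
  near 0.03 under γ = 2 but falls below 10⁻² under γ = 0.
* **Error definition.** Default is per-sample cross-entropy (clipped at
  10⁻⁷): it resolves differences near certainty (10⁻⁴ vs 10⁻²) that the
  absolute probability error compresses; absolute error is available.
* **Threshold.** Default is the 0.4 quantile of the pooled ε values —
  scale-free across centers whose probes converge to different error
  levels. A fixed absolute threshold is available for ablations. The
  strict inequality makes ε̂ = 0 an exact no-op.
* **Floor.** A center never retains less than min_core_fraction = 0.2 of
  its pool; if the threshold would cut deeper, only the lowest-ε samples
  are removed down to the floor. Probe cycles that diverge (non-finite
  loss) are discarded and rerun with a fresh seed.

What the rule can and cannot recover: when a pool contains planted
near-duplicate families (a parent and its clones), family members are
mutually indistinguishable — the probe memorizes whichever copies fall in
T and predicts the rest perfectly, so the pruned set removes *most of each
family* but cannot preferentially remove the flagged clone rather than its
identical parent. Redundancy removal should therefore be judged at the
family level (excess copies removed), not by clone flags alone.

## The backbone network

A compact CNN in numpy: two valid 3×3 convolutions (8 and 16 kernels) each
followed by ReLU and 2×2 max-pooling, a 32-unit dense ReLU layer (the
representation used by the contrastive term), and a single-logit head.
About 2.4k parameters for 16×16 inputs; 24 conv kernels in total, each
contributing one deep feature (the spatial mean of its activation map), so
feature dimension equals the kernel count and scales with the configured
channel widths. Training uses Adam (lr 10⁻³) on the focal loss
−α_t(1−p_t)^γ ln p_t with γ = 2 and α chosen per batch as the inverse
class frequency ("auto"), 2 local epochs per round, batch 32, 20 rounds by
default — minutes-scale runs on one CPU. All gradients are exact
backpropagation (verified against finite differences); all randomness
(init, batch order) flows from a single experiment seed through named
sub-streams, so runs are bit-reproducible and algorithms that prescribe
identical computation produce bitwise-identical trajectories.

## SBELM classifier

The downstream classifier is an extreme learning machine with a sparse
Bayesian fit: a frozen random hidden layer (Gaussian weights, uniform
biases, sigmoid activation, 50 units by default) over standardized deep
features, and output weights learned by ARD-regularized Bayesian logistic
regression — per-weight Gaussian priors whose precisions are re-estimated
by the MacKay fixed point inside an iteratively reweighted Laplace
approximation. Weights whose precision exceeds 10⁶ are pruned to exactly
zero and never revived, so the active set shrinks monotonically; the fit
stops when the largest weight change is below 10⁻⁴ (200-iteration cap;
non-convergence returns the final iterate, flagged). Class imbalance is
handled by weighting each sample's log-likelihood with the same α_t class
weight used in the focal loss. Feature standardization statistics are
frozen at fit time and reused at prediction.

## Evaluation suite

AUC is the Mann–Whitney statistic; confidence intervals and paired model
comparisons use DeLong's structural-components variance (a zero-variance
degenerate case collapses the CI to a point, with a warning; identical
score vectors give p = 1). Operating points come from the Youden index
J = sensitivity + specificity − 1 maximized over observed scores, ties
broken toward the smallest threshold; everywhere a prediction is positive
iff score ≥ threshold. PR-AUC is the step-wise (interpolation-free) area.
NRI is categorical at the model's Youden threshold; IDI is the gain in
discrimination slope. Decision curves report net benefit
TP/n − (FP/n)·p_t/(1−p_t) against treat-all and treat-none references.

The fairness summary compares the contribution-fair run with each
baseline: the performance improvement is the mean (over baselines) of the
mean (over centers) relative AUC gain, in percent; the fairness
improvement is the mean relative reduction of the across-center AUC
standard deviation. A baseline with zero spread contributes no fairness
term and is reported as skipped. These two definitions are stated
explicitly because several variants exist in the fairness literature;
anything computed here is auditable from the AUC table.

The ablation grid has three rows — no pruning with uniform averaging,
pruning with uniform averaging, pruning with contribution-fair weights —
and scores each row from the global model's predicted probabilities per
center. Personalization and the SBELM stage are deliberately excluded from
the grid so the rows isolate the pruning × aggregation effect; row 1 is by
construction identical to a plain uniform-FedAvg run with the same seeds.

## Synthetic study conditions

The generator emulates a three-hospital cohort: sizes (150, 90, 30) in
roughly 5:3:1 proportion, positive prevalence (0.85, 0.88, 0.85) — heavy
imbalance, as in invasion-status cohorts — a 60/40 stratified train/test
split, center-specific intensity and lesion-scale shift (0, 0.08, 0.15),
and planted near-duplicate fractions (0.45, 0.65, 0.12) with Gaussian
pixel jitter (sd 0.02). Clones inherit their parent's label and split
membership, so test sets never contain near-copies of training images.

Images are 16×16 grayscale: a noisy background plus one lesion blob with an
irregular boundary; *every* sample shows a lesion, and the class label is
expressed only through the blob's brightness, drawn from overlapping
ranges (positives U(0.15, 0.35), negatives U(0.05, 0.25)) under pixel
noise. Two consequences are intended. First, cohort-level discrimination
is clinically plausible rather than saturated — a converged single-center
model reaches test AUC ≈ 0.8–0.9. Second, each individual sample carries
irreducible ambiguity, so a probe model stays measurably uncertain on
unseen samples; this bounded generalization confidence is a precondition
for separating memorized near-duplicates from merely easy samples, i.e.
for error-based redundancy scoring to mean anything. Real cohorts share
this property (expert image reading in invasion staging is itself ~80%
accurate); a synthetic task with deterministic labels and unbounded
confidence would not.

What the generator does **not** emulate: real MRI texture and anatomy,
patient-level correlation structure beyond literal near-duplication,
scanner batch effects beyond a scalar intensity/scale shift, multi-class
pathology, or label noise as a separate mechanism (ambiguity enters
through overlapping appearance instead). Passing results therefore show
that the pipeline's machinery behaves as specified under controlled
conditions — not that it would improve any particular clinical cohort.

## Problem sizes

Default experiments use the cohort above (~400 images including clones),
20 federated rounds, and the probe schedule described. These sizes were
chosen so a full four-algorithm comparison plus the ablation grid runs in
minutes on a single CPU while keeping per-center test sets large enough
for AUC confidence intervals to be meaningful. The acceptance script scales
some Monte-Carlo repetitions (seeds per property) accordingly; the sizes
used are printed in its output.

## Known limitations

* Clone-flag recall of the pruning rule is structurally capped: with
  uniformly drawn parents the flagged clones' identical parents occupy a
  share of the prunable low-ε mass (see the family-level note above).
* The contribution-fair benefit over plain averaging is a small effect at
  desk scale and is demonstrated directionally (orderings over seeds), not
  as a calibrated effect size.
* Q is measured on probe-validation samples that the core set may overlap;
  it is a round-level progress signal, not an unbiased generalization
  estimate.
* The MOON implementation contrasts penultimate-layer representations
  without an extra projection head, matching the small backbone.
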