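# Methods

## Model

A patient's prognosis is a latent z in R^3. Conditioned on a regimen code
r (one-hot, length 5), each observed modality emits a diagonal-Gaussian
posterior over z: features f_m (d = 256) are produced by small frozen
encoders (2-layer MLP for the clinical table; patch-pooling MLP over the
volume and its tumor mask, average-pooled onto a 4x4x4 grid; pad-masked
token-embedding average for reports, with a learned no-report vector for
blank text), and affine heads on (f_m ⊕ r) emit mu_m and a raw scale
mapped through softplus-then-square (floor 1e-6) to sigma_m^2. Variances
are stored as variances everywhere; nothing downstream interprets sigma as
a standard deviation.

Fusion is an exact Product-of-Experts with the spherical prior N(0, I)
always included; precisions add and means are precision-weighted. A
patient whose report is blank contributes no text expert: the fused
posterior is bit-identical to omitting the expert, because the inclusion
mask multiplies the expert's precision contribution by exactly 0.0.

Outcome heads (one pCR head and one risk head per source, 8 -> 16 -> 1
with tanh) read (z ⊕ r). The pCR head ends in a sigmoid; the risk head is
an unbounded log-relative-hazard. The correction factor alpha =
sigmoid(w·mu_PoE + b) blends PoE and clinical-only predictions on the
probability scale for pCR (exactly the printed convex combination; a
logit-scale option exists) and on the raw score scale for risk.

### Loss and the two KL variants

The supervised loss sums binary cross-entropy (batch mean, probabilities
clipped to [1e-7, 1-1e-7]) and the negative Cox log partial likelihood
over the five sources {tab, img, txt, PoE, correct}, plus lambda_KL
(default 1) times one KL term per emitted posterior {tab, img, txt, PoE}.

The Cox risk set is R(T_i) = {j : T_j >= T_i} with Breslow tie handling by
default. A `strict` convention (T_j > T_i, which excludes the index
patient and is undefined whenever the latest time is an event) is kept
behind `ModelConfig.risk_set` for fidelity experiments. The loss is
computed with a location-invariant log-sum-exp over sorted suffix sums,
O(n log n). For training only, Cox terms are divided by the event count
(`cox_normalization="events"`) so the three loss families have comparable
per-sample scale; `total_loss` itself assembles the unnormalized sum.

Two KL references are implemented behind `ModelConfig.posterior_variant`:

- `"elbo"` (default): a conditional-VAE reading. A small outcome expert
  g(z | y, r) on (y_pcr, log T, E, r) is fused with each source's
  p(z|x,r) to form the training-time posterior q(z|x,y,r); latents are
  sampled from q and the penalty is KL(q || p) per source. Inference
  never sees outcomes: it always uses p(z|x,r) with eps = 0.
- `"printed"`: each emitted posterior is penalized against the spherical
  prior, KL = 1/2 sum(sigma^2 + mu^2 - 1 - ln sigma^2).

The default was chosen empirically on the synthetic world: with a
2-scalar supervision signal, anchoring every posterior to N(0, I) at
lambda_KL = 1 shrinks the posterior means so strongly that held-out
ranking quality saturates well below the information ceiling of the
observables (pCR AUC ~0.78 against an achievable ~0.86), regardless of
learning rate, step count, or the number of reparameterization draws.
The outcome-conditioned variant reaches the ceiling (~0.85) at the same
lambda_KL, and is also the form the ELBO itself names. One
reparameterized draw per batch element is used in training (configurable
via `TrainConfig.n_draws`); evaluation uses the posterior mean.

### Training

AdamW (decoupled weight decay 1e-2) throughout. The contrastive stage
aligns (img, tab) and (img, txt) pairs — blank-report patients excluded
from the text pair — with symmetric InfoNCE on cosine similarities at
temperature 0.07, then freezes the encoders and caches features. The
response stage takes full-batch steps on the training split; validation
pCR AUC and C-index are evaluated every `eval_every` steps and the best
checkpoint per metric is retained (ties break to the earliest step).
Five-fold cross-validation, stratified jointly on the pCR label and the
event indicator so no fold is event-free, yields five checkpoints whose
scores are arithmetically averaged at prediction time.

Reference defaults follow the original training recipe (lr 1e-4, 100
alignment epochs at batch 16, 500 response steps); `desk_config()` is the
desk-scale operating point used by the demo pipeline and tests (3
alignment epochs, 400-1000 full-batch steps at lr 1e-2). The larger step
size is deliberate: full-batch gradients on ~10^4-parameter heads are far
less noisy than minibatch deep-net gradients, so the reference rate
underfits badly within the step budget.

## Synthetic world

The generator states one fixed world; its defaults were chosen once to
echo published neoadjuvant breast-cancer cohorts and are not tuned per
experiment:

- Subtypes HER2+/TN/HR+ with proportions 0.25/0.25/0.50; guideline menus
  HER2+: {r3 < r4}, TN: {r1 < r2}, HR+: {r5 < r1 < r2} (ladders ordered by
  toxicity).
- z ~ N(0, I3): z0 = aggressiveness (MIB-1, enhancement, report keywords),
  z1 = tumor burden (size, T stage), z2 = nodal involvement (N stage, an
  axillary nodal lesion in the volume, report keywords).
- pCR: logit = subtype intercept (0.2 / 0.0 / -3.0, matching ~62/54/7%
  marginal rates) + (1.0, 0.6, 0.3)·z + regimen effect (+0.7 logit for
  the escalated rungs r2/r4; -0.5 for hormone therapy) + an escalation
  interaction 0.75·tox(r)·z0 — aggressive tumors benefit more from
  escalation, indolent ones can be harmed, which gives the recommender a
  real decision problem.
- Survival: exponential proportional hazards, baseline 0.05/year,
  log-HR = (0.7, 0.3, 0.6)·z + subtype shift (0 / +0.4 / -0.3) + regimen
  effect (-0.25 for escalated rungs); independent exponential censoring at
  0.15/year (~25% observed deaths, median follow-up ~4.5 years).
- Modality noise (tab 0.35, img 0.2, txt 0.6 SD on unit-variance latents)
  is set so that the combined observables pin the latent down sharply
  (ridge-recovery residual SD ~0.3 per dimension): the oracle-recovery
  acceptance check presumes a world in which the multi-modal record is
  close to sufficient for the latent, and these are the defaults that
  state it. 15% of reports are missing completely at random; menopause is
  missing in 20% of records.
- Potential outcomes for all five regimens are realized with common
  random numbers (one uniform for pCR, one exponential for death, one
  censoring time per patient), so counterfactual policy comparisons are
  paired and low-variance, and the factual outcome always equals the
  table entry of the assigned regimen.
- Assignment follows the subtype menu; within-menu choice tilts toward
  the higher rung with strength `assignment_confounding` (default 0.25;
  0 gives a randomized trial).

What the generator does not emulate: real DCE-MRI appearance or report
language (volumes are noisy ellipsoids on a 16x32x32 grid at 2 mm; reports
are bags of 64 synthetic tokens), covariate correlations beyond the latent
structure, informative censoring, or non-proportional hazards. A green
end-to-end test therefore establishes that the pipeline recovers the
stated generative structure — not that it would perform comparably on real
cohorts.

## Statistics

All evaluation statistics are implemented in-package so tests can compare
them to independent oracles (exhaustive pair counting for AUC/C-index,
quadrature for KL, grid search for Cox coefficients, lifelines /
scikit-learn as external cross-checks in the test suite only):

- AUC via midranks (ties = 1/2); percentile bootstrap CIs with
  patient-level resampling, seeded; degenerate resamples skipped. A
  paired-bootstrap AUC-difference test replaces the unusual
  t-test-on-ROC comparison.
- Harrell's C counting pairs whose earlier time is an event (tied times
  count when the event precedes a censoring); tied scores earn 1/2.
- Kaplan-Meier product-limit curves; k-group log-rank via hypergeometric
  moments; univariable Cox HR by damped Newton steps with Wald CIs, with
  monotone-likelihood flagging when a group has no events.
- Youden threshold: exhaustive scan over observed scores with the
  `score >= t` positivity rule; ties resolve to the smallest qualifying
  score. Risk cutoff: linearly interpolated 25% quantile of negated risk
  scores; the boundary patient is low-risk (strict `<` for high-risk).
- Net benefit NB(p_t) = TP/n - w·(FP/n)·p_t/(1-p_t); the harm weight w
  (default 1.5, i.e. a missed pCR counts 1.5x an overtreatment) multiplies
  the false-positive term; w = 1 recovers the standard formula. The model
  policy escalates when the predicted pCR score is below p_t.

## Recommendation rule

Q1 = score of the lowest-toxicity rung; Q2 = max over the higher rungs
(the recommended escalation is the argmax — the pairwise rule extended to
the 3-rung HR+ ladder). Precedence: the clinical-trial condition
(both Q1 < t and Q2 < t) is checked first; otherwise Q1 >= Q2 (ties
included) recommends the lower rung. Thresholds are computed once on the
training split and frozen; `TrainingScores.split` enforces the provenance.
In pCR mode scores are corrected pCR probabilities with the Youden
threshold; in survival mode scores are negated corrected risk scores with
the 25%-quantile threshold, so "higher is better" in both modes. For
policy-value evaluation against the counterfactual table, the trial
category is mapped to the best available ladder rung, since the table has
no trial arm; this is conservative about what a trial could deliver.
Under the default world's pCR mode most non-trial patients are escalation
candidates (the escalation effect is positive for most tumors), so the
"lower" category is rare; it populates when escalation genuinely harms
(strongly indolent tumors) or in survival mode.

## Numerical choices

- Probabilities clipped to [1e-7, 1-1e-7] (with a warning at exact 0/1);
  log-sum-exp inside the Cox loss; softplus^2 + 1e-6 variance floor.
- Training aborts with the step index when the loss is non-finite or
  exceeds 1e6.
- Even crop offsets in volume preprocessing resolve toward the lower
  index; resampling is trilinear for intensities, nearest for masks;
  intensity normalization clips at the 99.5th percentile and divides by
  the clip value (zero-volume guard returns zeros with a warning).
- HER2 IHC 2+ is routed by SISH status (positive -> 3+, negative -> 1)
  because the 3-level code has no 2+ slot; a strict mode rejects 2+ at
  ingestion instead.
- All randomness flows from integer seeds through numpy SeedSequence
  hierarchies; identical (seed, config, cohort) reproduce identical
  histories and metrics bit-stably.

## Known limitations

- Encoders are deliberately tiny and frozen after a short contrastive
  stage; representation quality, not architecture, is the object here.
- The ELBO/printed-loss ambiguity is resolved empirically (see above);
  both variants ship, and conclusions about the "printed" variant's
  ceiling hold only for this synthetic world and scale.
- Survival modelling assumes proportional hazards with exponential
  baseline both in the generator and implicitly in evaluation; the Cox
  machinery is univariable for hazard ratios.
- Bootstrap CIs are percentile-method; no BCa correction.
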