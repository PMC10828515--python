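# Methods

## Model

`mhcgate` predicts two related quantities for a peptide–MHC-I pair: the
probability that the peptide is presented on the cell surface (the signal
measured by mass-spectrometry elution experiments) and its binding affinity
(the signal measured by quantitative binding assays). The two tasks share a
sequence-embedding stage and a shared expert, and keep task-specific experts
and prediction heads — a "customized gate control" multi-task layout in
which a learned per-task softmax gate decides, per input, how much of the
shared representation to use.

### Input encoding

* Peptides of length 8–15 are written into a 15-wide window three times —
  left-aligned, centered (odd remainder padded on the right), and
  right-aligned — and the three blocks are concatenated to 45 positions.
  This triple alignment gives the recurrent encoder simultaneous access to
  N-terminus-anchored, centered, and C-terminus-anchored registers of the
  same peptide, so anchor positions appear at predictable coordinates
  regardless of length.
* Each position carries 21 channels: the residue's row of the BLOSUM62
  substitution matrix (taken from Biopython) divided by 10 to keep inputs
  O(1), plus a dedicated padding channel. The pad symbol `X` is a one-hot
  on channel 21. The scale factor and the pad convention are package
  choices; only the 21×45 / 21×37 shapes are fixed by the architecture.
* Alleles are represented by their 37-residue pseudo-sequences (the
  peptide-contacting positions), which makes the model pan-allele: any
  allele with a known pseudo-sequence can be scored. Allele names are
  canonicalized to the `HLA-A*02:01` form by a small regex parser;
  non-HLA-shaped tokens (e.g. synthetic allele ids) pass through verbatim,
  and malformed HLA-like names are rejected rather than guessed.

### Network

Two independent 2-layer bidirectional LSTMs (hidden 32) encode the peptide
and allele matrices. Each stream is summarized by the last layer's final
forward and final backward hidden states (64 dims); the published
description leaves the reduction of "all hidden layers" to a 64-dim vector
open, and fixed-size final-state summaries are the only reading consistent
with the stated 64- and 128-dim feature sizes. The two summaries concatenate
to a 128-dim pair feature.

Three experts (MLP, hidden 128 → output 64, ReLU hidden, linear output)
process the feature: presentation expert, affinity expert, shared expert.
Per task, a dense layer + softmax over {task expert, shared expert} yields
two nonnegative weights summing to 1; the gated feature is the convex
combination. Two towers (hidden 32, ReLU; scalar sigmoid output) produce
the presentation probability and the model-scale affinity.

Model-scale affinity y ∈ [0,1] maps to nanomolar units by
`nM = 50000^(1−y)`; the inverse `y = clamp(1 − log₅₀₀₀₀(nM), 0, 1)` is used
to transform training measurements. The boundaries y=0 (50 000 nM) and y=1
(1 nM) are admitted by clamping even though a sigmoid never attains them.

The network, backpropagation (including BPTT through the BiLSTM stacks) and
the AdamW optimizer are implemented directly on numpy arrays in
`mhcgate/_nn.py`; parameters are float32, and gradient correctness is
guarded by a finite-difference test. Inference deduplicates repeated allele
matrices so scoring many peptides against few alleles runs the allele
encoder once per distinct allele.

## Training procedure

* **Losses.** Binary cross-entropy on MS hit labels; mean squared error on
  model-scale affinities. Censored measurements (`>`/`<`) are rejected at
  load time — the regression treats affinities as quantitative equalities.
* **Uncertainty weighting.** total = exp(−s_np)·L_np + s_np +
  exp(−s_ba)·L_ba + s_ba with trainable scalars s_i = log σ_i² initialized
  at 0 and updated by the same optimizer (no weight decay on s_i). With
  both s fixed at 0 the total reduces exactly to the plain sum.
* **CAGrad on shared parameters.** Per batch, the two weighted task losses
  are backpropagated separately; on shared parameters (both encoders, the
  shared expert, and the gates, whose cross-task gradients are zero) the
  two gradients are combined by the two-task CAGrad rule: with
  g₀ = (g_np + g_ba)/2, the mixture weight w ∈ [0,1] minimizing
  ⟨g_w, g₀⟩ + c‖g₀‖‖g_w‖ is found by bounded scalar minimization (the 1-D
  dual of the conflict-averse program), and the update is
  d = g₀ + c‖g₀‖·g_w/‖g_w‖, which satisfies ‖d − g₀‖ ≤ c‖g₀‖. c defaults to
  0.5, the common setting in the CAGrad literature. Branch parameters
  receive their own task's gradient unchanged. The composition order —
  uncertainty weights scale losses first, CAGrad then combines the weighted
  gradients — is a package decision. The per-task shared gradients are
  summed (equivalently, CAGrad's mean is doubled) so that c = 0 reproduces
  the gradient of the plain weighted-sum loss.
* **Synthetic decoy negatives.** Each epoch adds MS negatives: peptide
  lengths uniform on 8–15, residues drawn from the empirical residue
  distribution of all MS positives, alleles uniform over the positives'
  alleles. The default count balances classes (positives minus existing
  negatives). Fresh sets are generated for the first 40 epochs, then the
  stored sets are recycled in order.
* **Optimization.** AdamW, batch 1024, lr 1e-3, weight decay 1e-2, up to 80
  epochs with a 90/10 task-stratified train/validation split — the
  full-data defaults. Early stopping monitors the unweighted validation
  loss (patience 5 by default); the returned model is the best-validation
  snapshot. Mini-batches mix both tasks; a batch missing one task
  contributes zero loss for that task.
* **Desk scale.** `desk_scale_config()` (batch 128, lr 5e-3, ≤30 epochs,
  patience 8) is the configuration for ~5 000-example synthetic runs: the
  full-data batch size would give only four optimizer steps per epoch at
  this size, and the learning rate was chosen by validation loss. All tests
  and examples use problem sizes of a few thousand examples so the whole
  suite runs on one CPU in minutes.
* **Drop-BA ablation.** `freeze_ba_branch` marks the BA expert and BA tower
  non-trainable (bitwise frozen, verified in tests) while the forward pass
  is unchanged — the configuration used to quantify the auxiliary task's
  contribution.

## Percentile-rank calibration

Raw probabilities are not comparable across alleles. For each allele a rank
database stores the descending-sorted presentation scores of random
natural peptides — by default 50 000 per length 8–12, residues i.i.d. from
a bundled human-proteome-like amino-acid frequency table — and a query
score s maps to `100·(1 + #{db ≥ s})/(N + 1)` percent (add-one so ranks are
never exactly zero; lower = stronger). The pooled-across-lengths
distribution (rather than per-length normalization) is a package decision;
the add-one convention bounds ranks in (0, 100]. Databases are cached on
disk keyed by (model-weights hash, allele).

## Ensembling

`make_variant_configs` builds the base architecture plus nine variants over
expert width {64, 128, 256} × expert depth {1, 2} × tower width {32, 64}
(deduplicated, base first; the grid is declared here, not taken from any
external table). After training all ten, `stepwise_select` greedily adds
the member that most reduces the validation presentation loss of the
averaged prediction, stopping at five members or when no candidate
improves. Combination is the arithmetic mean of member probabilities.

## Evaluation suite

* Multi-allelic records (1–6 alleles per sample) are deconvolved by the
  maximum per-allele score.
* Per-sample metrics: AUC-ROC and AUC-PR (scikit-learn's step-wise average
  precision), and PPV 1 % — true positives among the top ceil(0.01·n)
  scores with stable-sort tie-breaking (truncation vs rounding of the top
  count is unspecified upstream; ceiling is the package's choice).
  PPV5 is the analogue over the top five.
* Predictors are compared per sample by the two-sided Wilcoxon signed-rank
  test (zero differences dropped); affinity predictions by Spearman rank
  correlation with average-rank ties.
* The leakage filter removes positive records whose (peptide, allele) pair
  — for any allele the record carries — appears in the training set, then
  drops samples left with under 0.1 % positives. Exact string match is the
  leakage key.
* `immunogenicity_two_step` ranks neoantigens by presentation score,
  removes candidates whose agretopicity (mutant nM / wild-type nM) exceeds
  0.1, and reports PPV5 on the survivors.

## Synthetic data generator

The generator is the package's study system: it plants known structure so
recovery can be measured.

* Each synthetic allele has a random 37-residue pseudo-sequence and an
  anchor motif at peptide position 2 and the C-terminus — the canonical
  MHC-I anchors. Anchor weight vectors are Dirichlet draws with
  concentration mass on 2–3 preferred residues (α = 3.0 there, 0.03
  elsewhere, floored at 1e-6), so log-weights vary continuously as in real
  position-weight matrices rather than taking two discrete values.
* `motif_score` is the sum over anchors of the log motif weight of the
  residue present — the planted ground truth.
* MS positives draw anchors from the motif and are accepted only when every
  anchor carries a preferred residue (weight ≥ 0.05): mass spectrometry
  observes peptides that actually bound, so detected ligands almost never
  carry disfavored anchors. Negatives are uniform random peptides. Default
  desk scale: 4 alleles × 500 positives, 1:1 negatives.
* BA examples use tempered anchors (weights^0.2, renormalized) so
  measurements spread across the binding range instead of clustering at
  the strong-binder extreme, as affinity panels do by design. The planted
  affinity is sigmoid(slope·(motif_score − center)) + Gaussian noise
  (sd 0.05 by default), clamped to [0,1] and converted to nM; the center is
  the midpoint between a uniform peptide's expected score and the best
  achievable score, and slope 0.2 keeps the sigmoid from saturating over
  the sampled score range. BA makes up 20 % of the training set, matching
  the minority share such data hold in real mixed corpora.
* Benchmark samples carry several alleles (≤6); positives are drawn from a
  randomly chosen allele of the sample at 1 % prevalence by default. A
  scorer using the true motif with max-deconvolution separates these
  samples at AUC-ROC ≥ 0.95 — the generator/metric consistency check.
* All sampling flows through one `numpy.random.Generator` seeded from the
  dataset spec, so a fixed seed reproduces every peptide bit for bit.

What passing recovery tests shows — and what it does not: the model
demonstrably learns allele-conditional anchor motifs and a monotone
affinity map from ~5 000 examples. The generator does not emulate MS
instrument noise, antigen-processing signals (cleavage, TAP transport,
flanking context), length-frequency biases, or inter-allele motif
correlation, so desk-scale results say nothing quantitative about
performance on real immunopeptidomes.

## Numerical choices and degenerate inputs

* Sigmoid inputs are clipped to ±60 before exponentiation; probabilities
  are clipped to [1e-7, 1−1e-7] inside cross-entropy.
* CAGrad returns g₀ unchanged when ‖g₀‖ = 0 or the optimal mixture is the
  zero vector; the bounded scalar solver's endpoint values are checked
  explicitly because the dual can be flat near w ∈ {0, 1}.
* Centering an odd pad remainder puts the extra pad on the right
  (deterministic tie-break).
* Stratified splitting guarantees at least one example of each present
  task on each side and errors below two examples per task.
* Training aborts with diagnostics on non-finite losses.
* Forward passes, training, and generation are deterministic given seeds;
  the end-to-end determinism test compares two full pipeline runs
  byte-for-byte.

## Known limitations

* Single-threaded numpy training is desk-scale only (~6 s/epoch on 5 000
  examples); the architecture is small by design, not a large-corpus tool.
* The BA head's Spearman on held-out synthetic data (~0.75–0.88) sits well
  below the generator's own consistency ceiling (~0.99): thirty epochs on
  ~850 BA examples does not exhaust the affinity signal.
* Percentile ranks pool lengths 8–12; per-length calibration may differ
  for length-biased alleles.
* The ensemble variant grid is a declared package choice; upstream variant
  tables were not available to mirror.
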