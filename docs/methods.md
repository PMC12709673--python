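# Methods

This package implements the k-binding analysis of TCR CDR3 cross-reactivity
as a tested pipeline over synthetic data: a generative model of a randomized
CDR3 library panned against seven related peptide–MHC targets, presence-based
binder calling, k-binding stratification, multi-label neural binding
classifiers with stratum-weighted sampling, residue-masking importance, and
correlation with externally supplied interface-energy changes.

## The variant space and embeddings

Variants are 6-mers over a 19-letter amino-acid alphabet (the 20 canonical
residues minus one; cysteine by default, the usual exclusion in display
libraries), three positions per CDR3 chain: a99, a100, a101, b98, b99, b100.
The full space holds 19^6 ≈ 4.7 × 10^7 variants.

Three per-residue embeddings feed the classifiers:

* **BLOSUM50** — the residue's row of the BLOSUM50 substitution matrix over
  the 20 canonical columns (raw integer scores, 20 dims/residue; any scaling
  is left to the model's first layer);
* **VHSE8** — the eight published VHSE principal-component physicochemical
  descriptors (8 dims/residue);
* **one-hot** — indicator over the 20 canonical residues.

A full variant embeds to 120 / 48 / 120 dimensions respectively; a sequence
with d residues deleted embeds to (6 − d) × (per-residue dim), with no
indicator of which positions were removed.

## The synthetic binding landscape

Affinity is a position-weighted similarity to a per-target consensus:

    affinity(v, t) = Σ_p w_p · BLOSUM50(v[p], consensus_t[p])

A variant binds target t when affinity (plus optional Gaussian noise,
`noise_sd`, default 0) reaches the target's threshold. Thresholds are
calibrated on a fixed internal random stream to the (1 − rate) quantile of
the affinity distribution over uniform variants; the default per-target
binding rate is 0.05, giving every target a usable positive class at desk
scale while keeping non-binders the overwhelming majority.

Design choices that matter:

* **Shared alpha motif.** All seven targets share the alpha consensus "DSW",
  so cross-reactivity is driven by a dominant alpha-chain motif; beta
  consensi are mutually dissimilar triplets (mostly non-positive BLOSUM50
  cross-similarities), carrying target specificity.
* **Position-weight hierarchy.** Default weights follow the strict order
  a99 > a101 > b98 > a100 > b100 > b99 (1.0, 0.40, 0.35, 0.28, 0.20, 0.12 in
  that importance order). Because BLOSUM50 columns differ roughly two-fold in
  how decisive they are (the W column is far more peaked than the D column),
  weights were chosen jointly with the consensus letters so that the
  *effective* per-position information follows the same ordering as the raw
  weights; with naive weights the recovered importance ordering would be
  dominated by column shape rather than the intended hierarchy.
* **k-distribution shape.** With these settings the true k-binding counts
  decay with k (1-binding largest) apart from an excess of 7-binders — the
  strong shared-motif variants — echoing the qualitative shape of real
  panning data, which also shows a high-k excess.

## Panning simulation

Panning is a latent-abundance chain. Round-0 abundance is uniform over the
sampled library (default 2 × 10^5 variants drawn uniformly without
replacement from the 19^6 space; analyses here run at 2 × 10^4). Each MACS
round multiplies abundance by exp(s · (affinity − threshold)), floored at a
leak rate of 10^-4 for nonspecific carryover, and renormalizes; sequencing
draws `depth` reads multinomially from the current abundance (default 10^6;
desk runs use 3 × 10^5). Replicates share the latent chain and differ only in
read sampling; per-(target, replicate) streams are spawned deterministically
from one master seed, so runs are bit-reproducible.

The enrichment sharpness default is s = 0.3. This value makes presence-based
calls (below) about 82% precise and 85% sensitive against the noise-free
ground truth at desk scale. Gentler enrichment leaves so many weakly depleted
non-binders present in round 3 that presence calls acquire near-independent
false positives across targets, which inflates the marginal rates enough that
called profiles no longer show the excess-cross-reactivity signature the
binomial test looks for; sharper enrichment collapses diversity and loses
most true binders.

What the simulator does **not** model: avidity and bead chemistry, yeast
growth competition, PCR bias, sequencing error, or nucleotide-level
redundancy. Passing tests therefore demonstrate that the analysis machinery
recovers the structure this generative model encodes, not that it would
behave identically on raw experimental reads.

## Binder calling and k-binding

A variant binds a target when it appears with at least `min_reads` reads
(default 1, i.e. presence) in the final MACS round of **both** replicates.
The evaluated universe is every variant observed anywhere in the dataset;
variants binding nothing form the k = 0 stratum. S denotes the exact bound
subset; k = |S|.

The cross-reactivity test asks whether the number of variants with k ≥ 2
exceeds what independent per-target binding at the empirical marginal rates
would produce. The null success probability P(k ≥ 2) is computed exactly
over the 2^7 outcome lattice and the one-sided upper binomial tail is
evaluated exactly at any n (scipy's survival function is exact and cheap, so
no normal approximation is used). Note that this one-sided test is a
directional claim about the data, not a generic dependence test: with very
noisy calls the observed multi-binding count can legitimately fall *below*
the independent-marginal expectation even when true binding is strongly
positively correlated, because correlation concentrates marginal probability
mass on few variants.

Sequence logos use per-position residue frequencies with information content
IC_p = log2(basis) − H_p (Shannon entropy in bits); the basis defaults to 20
(the standard protein-logo convention) although the library alphabet has 19
letters; it is configurable. No small-sample correction is applied.

## Classifier

A multilayer perceptron maps the embedded sequence through two hidden layers
of 500 ReLU units to 7 sigmoid outputs, one binding probability per target.
The loss is the sum over targets of binary cross-entropy; optimization is
Adam with learning rate 10^-4 and weight decay 5 × 10^-4 (applied as an L2
term in the gradient), 10 epochs, batch size 1028 (kept exactly as the
reference setting even though 1024 was likely intended; configurable). No
early stopping or schedule. The classification threshold for F1 is 0.5.

Class imbalance is handled by sampling training examples with replacement
with probability proportional to w_k = sqrt(n0 / n_k), where n_k is the size
of the example's k-stratum; one epoch draws as many examples as the dataset
holds. Empty strata get weight 0; the k = 0 stratum is included as all-zero
label rows (and anchors the weight formula).

The network is implemented directly on numpy (dense forward/backward passes
plus the Adam update), which makes the sampler semantics exact and training
bit-deterministic for a given seed: identical seeds give identical weights,
and rows are canonically sorted before sampling so training is invariant to
input row order. Parameters are float32; He initialization for the ReLU
layers. A non-finite loss aborts with diagnostics. At the desk scale used
here (≈ 2 × 10^4 rows, 120 inputs) one model trains in a few seconds on one
CPU core.

## Evaluation

10-fold cross-validation (9:1), two seed replicates. Folds are stratified by
k (round-robin within stratum) to reduce empty-stratum validation cells; the
same partitions are reused across embeddings, baselines and masks so
comparisons are paired cell-by-cell. A `folds_to_run` option evaluates only a
subset of the partition's folds — the split protocol is identical, just
cheaper — and is used by the masking scan and the test suite.

Metrics: F1 and area under the precision–recall curve, the latter as
step-wise average precision (no interpolation, avoiding the optimistic bias
of trapezoidal AUPRC). Both are reported overall (micro over all
variant × target cells, with the macro average alongside, since the
aggregation convention is ambiguous), per k-stratum, and per target. Cells
with no evaluable positives are recorded as missing, never zero.

Statistics: Kruskal–Wallis with tie correction and effect size
ε² = H/(n − 1); Dunn's post-hoc z tests with tie correction and
Benjamini–Hochberg FDR; Mann–Whitney U, Wilcoxon signed-rank (all-zero
differences reported as p = 1), one-sample t; exact binomial sign test.
Baselines: per-target logistic regression on the same folds and features,
and a permutation control that shuffles training-fold labels (a bijection on
rows, so the label multiset is preserved) while keeping test folds intact —
its per-target F1 should sit near the prevalence closed form 2π/(1 + π).

Two baseline behaviors are specific to this generator and worth stating
plainly. First, because the landscape's binding rule is *linear* in
per-position indicator features, per-target logistic regression on BLOSUM50
features is essentially the Bayes-optimal model family here and outperforms
the shared-weight MLP at desk scale (≈ 0.86 vs ≈ 0.77 overall F1); an MLP
advantage over logistic regression requires nonlinear structure that this
generator deliberately does not encode, so no such advantage is claimed or
tested. Second, the BLOSUM50-over-one-hot margin is real but small at desk
scale — a 500-unit MLP given 2 × 10^4 examples can largely re-learn residue
similarity from one-hot inputs — so the embedding comparison is a consistent
ordering across paired folds rather than a large mean gap, and it is tested
as a sign test on paired fold cells.

## Masking importance

Eight masks: each single position, and each whole chain. Masking deletes the
residue(s) from every sequence; colliding shortened sequences with
conflicting labels are all retained (no deduplication), and the input layer
shrinks to match. Models are retrained per mask on identical folds; the
importance statistic is ΔF1 = F1(masked) − F1(full), averaged over all
per-stratum and per-target cells (ΔAUPRC is reported alongside). Residues
are ranked by mean ΔF1, most negative first, ties broken lexicographically.
The alpha-vs-beta chain contrast is a paired one-sided Wilcoxon on the
per-cell deltas.

**Known limitation — resolution of the weak tail.** At desk scale under the
fixed 10-epoch training protocol, only the strong half of the hierarchy is
resolvable: masking a99, a101 or b98 (and either chain) deteriorates
performance clearly and in the correct order in essentially every seed, but
the three weakest positions contribute less than the metric's sampling noise
(their ΔF1 is ≈ +0.01 — removing uninformative inputs slightly *helps* a
10-epoch fit). Consequently the full 6-position ranking matches the
generator's ordering exactly in only about a third of seeds (Spearman
ρ = 0.94 otherwise, a single adjacent swap among the weakest positions).
Longer training makes all deltas negative but still does not order the tail;
resolving it requires far more data than desk scale provides. The acceptance
suite states the full-ranking property at its nominal strength and reports
this shortfall rather than weakening the check.

Interface-energy correlation consumes an external per-mask ΔI_sc table
(median interface-score change after alanine substitution; lower = more
stable) and reports Spearman's ρ between per-mask mean Δ-metrics and ΔI_sc
over shared labels (≥ 3 required; tie-degenerate input reported as ρ = 0,
p = 1). No structural modeling is performed; the packaged table
`data/delta_isc_synthetic.tsv` is a synthetic stand-in following the default
landscape's hierarchy, used to exercise the plumbing on known ground truth.

## Problem sizes and reproducibility

Default generator scale is 2 × 10^5 variants at depth 10^6. The analyses,
test suite and acceptance script run at 2 × 10^4 variants and depth
3 × 10^5 — the desk scale at which one cross-validated model trains in
seconds — with 20-seed properties checked on 2 × 10^3-variant simulations.
All randomness flows from explicit integer seeds through spawned
`numpy.random` generators; pipeline runs serialize their full configuration
and write a manifest with a checksum per artifact, and re-running a
configuration reproduces every artifact bit-exactly.
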